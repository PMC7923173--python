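"""Relapse-timing panel construction.

Prescriptions are cohorted by when (and whether) a single relapse occurred
on treatment, after truncating each prescription to its maximal run of
uninterrupted annual follow-up:

* **R0**  - no relapse at any time during the observed window,
* **R1**  - exactly one relapse during the first treatment year (onset in
  the closed window [6, 15] months: relapses are read as a treatment
  response only from month 6, and a first-year relapse may surface at the
  month-12 visit up to month 15),
* **R2**  - exactly one relapse during the second year (onset in (15, 27]),
* anything else (an early relapse, or two or more relapses) is left
  unclassified and excluded from every arm.

Derived arms: **R1+ / R1-** split R1 by relapse severity, and **R0+MRI0**
restricts R0 to prescriptions with no brain MRI activity at any follow-up
visit.  The R2 arm's month-12 row mirrors the R0 evaluation set (before the
second-year relapse occurs, R2 candidates are indistinguishable from
relapse-free prescriptions), flagged ``pre_relapse``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .events import (
    SEVERITY_HIGH_MIN,
    RelapseSeverity,
    classify_relapse_severity,
)
from .registry import VISIT_MONTHS, Registry

__all__ = [
    "PanelConfig",
    "ARM_ORDER",
    "truncate_follow_up",
    "assign_panel",
    "split_r1_by_severity",
    "restrict_mri_inactive",
    "build_panel_table",
]

logger = logging.getLogger(__name__)

ARM_ORDER = ("R0", "R1", "R1+", "R1-", "R2", "R0+MRI0")

EVAL_MONTHS = tuple(m for m in VISIT_MONTHS if m > 0)


@dataclass(frozen=True)
class PanelConfig:
    """Tunable panel-definition parameters.

    ``r1_window`` is closed on both ends; ``r2_window`` is open at the lower
    end and closed at the upper end so a month-15 relapse is counted once
    (in R1).  ``early_relapse_policy`` decides what a relapse before
    ``min_response_month`` does: ``"exclude"`` leaves the prescription
    unclassified, ``"ignore"`` discards the relapse record before panel
    assignment.
    """

    r1_window: tuple[float, float] = (6.0, 15.0)
    r2_window: tuple[float, float] = (15.0, 27.0)
    severity_high_min: float = SEVERITY_HIGH_MIN
    early_relapse_policy: str = "exclude"
    min_response_month: float = 6.0

    def __post_init__(self) -> None:
        if self.early_relapse_policy not in ("exclude", "ignore"):
            raise ValueError(
                f"early_relapse_policy must be 'exclude' or 'ignore', "
                f"got {self.early_relapse_policy!r}"
            )


def _months_between(start: pd.Series, end: pd.Series) -> pd.Series:
    """Whole months m with start + m months <= end (vectorized, NaT-safe)."""
    months = (end.dt.year - start.dt.year) * 12 + (end.dt.month - start.dt.month)
    months = months - (end.dt.day < start.dt.day).astype("float") * 1
    return months


def truncate_follow_up(
    prescription: Mapping, visits: pd.DataFrame
) -> tuple[int, int]:
    """Maximal contiguous annual window [0, m] for one prescription.

    Follow-up runs while consecutive annual visits exist (a single missing
    year ends the window; later visits after a gap are discarded) and stops
    at the prescription's end date if one is recorded.
    """
    months = set(int(m) for m in visits["month"])
    if 0 not in months:
        raise ValueError(
            f"prescription {prescription.get('prescription_id', '?')} has "
            "no month-0 baseline visit"
        )
    cap = max(VISIT_MONTHS)
    end = prescription.get("end_date")
    if end is not None and pd.notna(end):
        start = prescription["start_date"]
        elapsed = (end.year - start.year) * 12 + (end.month - start.month)
        elapsed -= int(end.day < start.day)
        cap = min(cap, elapsed)
    last = 0
    for m in VISIT_MONTHS[1:]:
        if m in months and m <= cap:
            last = m
        else:
            break
    return (0, last)


def _window_ends(registry: Registry) -> pd.Series:
    """Vectorized window end (months) for every prescription."""
    rx = registry.prescriptions
    present = (
        registry.visits.assign(flag=True)
        .pivot_table(
            index="prescription_id", columns="month", values="flag",
            aggfunc="any", fill_value=False,
        )
        .reindex(columns=list(VISIT_MONTHS), fill_value=False)
        .reindex(rx["prescription_id"], fill_value=False)
    )
    if not present[0].all():
        missing = present.index[~present[0]].tolist()[:5]
        raise ValueError(f"prescription(s) without month-0 visit: {missing}")
    cap = pd.Series(float(max(VISIT_MONTHS)), index=present.index)
    has_end = rx["end_date"].notna().to_numpy()
    if has_end.any():
        elapsed = _months_between(rx["start_date"], rx["end_date"])
        elapsed.index = rx["prescription_id"]
        cap.loc[elapsed.index[has_end]] = np.minimum(
            cap.loc[elapsed.index[has_end]], elapsed[has_end]
        )
    allowed = present.to_numpy() & (
        np.asarray(VISIT_MONTHS)[None, :] <= cap.to_numpy()[:, None]
    )
    run = np.cumprod(allowed, axis=1)  # contiguous from month 0
    window_end = run.sum(axis=1) * 12 - 12  # months 0..12k -> end 12k
    return pd.Series(window_end.astype(int), index=present.index, name="window_end")


def assign_panel(
    prescription: Mapping,
    relapses: pd.DataFrame,
    window: tuple[int, int],
    config: PanelConfig | None = None,
) -> str:
    """Panel of one prescription: ``"R0"``, ``"R1"``, ``"R2"`` or
    ``"unclassified"``; relapses outside the observed window are ignored."""
    config = config or PanelConfig()
    onsets = relapses.loc[
        (relapses["month_of_onset"] >= 0)
        & (relapses["month_of_onset"] <= window[1]),
        "month_of_onset",
    ].to_numpy(dtype=float)
    if config.early_relapse_policy == "ignore":
        onsets = onsets[onsets >= config.min_response_month]
    if len(onsets) == 0:
        return "R0"
    if len(onsets) > 1:
        return "unclassified"
    t = onsets[0]
    lo1, hi1 = config.r1_window
    lo2, hi2 = config.r2_window
    if lo1 <= t <= hi1:
        return "R1"
    if lo2 < t <= hi2:
        return "R2"
    return "unclassified"


def _assign_panels(
    registry: Registry, window_end: pd.Series, config: PanelConfig
) -> pd.DataFrame:
    """Panel and qualifying-relapse attributes per prescription."""
    rel = registry.relapses.merge(
        window_end, left_on="prescription_id", right_index=True, how="left"
    )
    rel = rel[
        (rel["month_of_onset"] >= 0)
        & (rel["month_of_onset"] <= rel["window_end"])
    ]
    if config.early_relapse_policy == "ignore":
        rel = rel[rel["month_of_onset"] >= config.min_response_month]
    grouped = rel.groupby("prescription_id")
    n_rel = grouped.size()
    first_onset = grouped["month_of_onset"].first()
    first_increase = grouped["edss_increase"].first()

    out = pd.DataFrame(index=window_end.index)
    out["window_end"] = window_end
    out["n_relapses"] = n_rel.reindex(out.index, fill_value=0).astype(int)
    out["relapse_onset"] = first_onset.reindex(out.index)
    out["relapse_increase"] = first_increase.reindex(out.index)

    lo1, hi1 = config.r1_window
    lo2, hi2 = config.r2_window
    single = out["n_relapses"] == 1
    t = out["relapse_onset"]
    panel = np.where(
        out["n_relapses"] == 0,
        "R0",
        np.where(
            single & (t >= lo1) & (t <= hi1),
            "R1",
            np.where(single & (t > lo2) & (t <= hi2), "R2", "unclassified"),
        ),
    )
    out["panel"] = panel
    return out


def split_r1_by_severity(
    assignment: pd.DataFrame, config: PanelConfig | None = None
) -> pd.Series:
    """Map each R1 prescription to "R1+"/"R1-" by its relapse severity.

    Raises if a qualifying relapse lacks its EDSS increase: the split is
    then undefined and R1+ / R1- would no longer partition R1.
    """
    config = config or PanelConfig()
    r1 = assignment[assignment["panel"] == "R1"]
    if r1["relapse_increase"].isna().any():
        bad = r1.index[r1["relapse_increase"].isna()].tolist()[:5]
        raise ValueError(
            f"R1 relapse without recorded edss_increase for prescription(s) "
            f"{bad}; cannot split by severity"
        )
    high = r1["relapse_increase"] >= config.severity_high_min - 1e-9
    return pd.Series(np.where(high, "R1+", "R1-"), index=r1.index)


def restrict_mri_inactive(
    assignment: pd.DataFrame, visits: pd.DataFrame
) -> pd.Index:
    """R0 prescriptions with no MRI activity at any post-baseline visit.

    Prescriptions with a missing lesion count at any in-window visit are
    dropped (with a logged warning), not treated as inactive.
    """
    r0 = assignment.index[assignment["panel"] == "R0"]
    v = visits[visits["prescription_id"].isin(r0) & (visits["month"] > 0)].merge(
        assignment["window_end"], left_on="prescription_id", right_index=True
    )
    v = v[v["month"] <= v["window_end"]]
    active = (v["new_t2_count"] >= 1) | (v["gd_count"] >= 1)
    missing = v["new_t2_count"].isna() | v["gd_count"].isna()
    drop_missing = set(v.loc[missing.fillna(False), "prescription_id"])
    if drop_missing:
        logger.warning(
            "dropping %d prescription(s) from R0+MRI0 for missing lesion "
            "counts", len(drop_missing),
        )
    ever_active = set(v.loc[active.fillna(False), "prescription_id"])
    keep = [p for p in r0 if p not in ever_active and p not in drop_missing]
    return pd.Index(keep, name="prescription_id")


def _evaluations(registry: Registry, assignment: pd.DataFrame) -> pd.DataFrame:
    """One row per (prescription, post-baseline month) inside the window."""
    rx = registry.prescriptions.set_index("prescription_id")
    v = registry.visits[registry.visits["month"] > 0].merge(
        assignment[["window_end", "panel"]],
        left_on="prescription_id",
        right_index=True,
    )
    v = v[v["month"] <= v["window_end"]].copy()
    v["baseline_edss"] = rx["baseline_edss"].reindex(v["prescription_id"]).to_numpy()
    base = v["baseline_edss"].to_numpy()
    threshold = np.where(base < 1.0, 1.5, np.where(base < 6.0, 1.0, 0.5))
    v["worse"] = (v["edss"] - v["baseline_edss"]) >= threshold - 1e-9
    v["mri_active"] = (
        ((v["new_t2_count"] >= 1) | (v["gd_count"] >= 1))
        .fillna(False)
        .astype(bool)
    )
    v["drug"] = rx["drug"].reindex(v["prescription_id"]).to_numpy()
    v["treatment_line"] = rx["treatment_line"].reindex(v["prescription_id"]).to_numpy()
    patients = registry.patients.set_index("patient_id")
    pid = rx["patient_id"].reindex(v["prescription_id"]).to_numpy()
    v["sex"] = patients["sex"].reindex(pid).to_numpy()
    v["age"] = patients["age_at_start"].reindex(pid).to_numpy()
    v["age_symptoms"] = patients["age_at_first_symptoms"].reindex(pid).to_numpy()
    return v


OBS_COLUMNS = [
    "prescription_id", "arm", "month", "worse", "mri_active", "pre_relapse",
    "edss", "baseline_edss", "drug", "treatment_line", "sex", "age",
    "age_symptoms",
]


def build_panel_table(
    registry: Registry, config: PanelConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-(arm, month) summary table and the observation table.

    Returns
    -------
    panel_table
        One row per (arm, month) with n > 0: counts, F:M ratio, median age,
        median age at first symptoms, median symptom duration (years),
        qualifying-relapse count, median baseline EDSS, worsening count.
    observations
        One row per (prescription, arm, month) evaluation, carrying the
        worsening and MRI-activity flags plus modelling covariates.
    """
    config = config or PanelConfig()
    window_end = _window_ends(registry)
    assignment = _assign_panels(registry, window_end, config)
    severity_arm = split_r1_by_severity(assignment, config)
    mri0 = restrict_mri_inactive(assignment, registry.visits)
    evals = _evaluations(registry, assignment)

    pieces = []
    base = evals[evals["panel"].isin(["R0", "R1", "R2"])].copy()
    base["arm"] = base["panel"]
    base["pre_relapse"] = False
    pieces.append(base)

    r1 = evals[evals["panel"] == "R1"].copy()
    r1["arm"] = severity_arm.reindex(r1["prescription_id"]).to_numpy()
    r1["pre_relapse"] = False
    pieces.append(r1)

    m0 = evals[evals["prescription_id"].isin(mri0)].copy()
    m0["arm"] = "R0+MRI0"
    m0["pre_relapse"] = False
    pieces.append(m0)

    # R2 at month 12 mirrors the R0 evaluation set: before the second-year
    # relapse occurs these prescriptions are indistinguishable from R0.
    mirror = evals[(evals["panel"] == "R0") & (evals["month"] == 12)].copy()
    mirror["arm"] = "R2"
    mirror["pre_relapse"] = True
    pieces.append(mirror)
    # R2's own pre-relapse month-12 evaluations are not re-reported.
    r2_mask = (base["arm"] == "R2") & (base["month"] == 12)
    pieces[0] = base[~r2_mask]

    observations = pd.concat(pieces, ignore_index=True)[OBS_COLUMNS]
    observations = observations.sort_values(
        ["arm", "month", "prescription_id"], kind="mergesort"
    ).reset_index(drop=True)

    rows = []
    for (arm, month), grp in observations.groupby(["arm", "month"]):
        n = len(grp)
        if n == 0:
            continue
        n_f = int((grp["sex"] == "female").sum())
        n_m = n - n_f
        if arm in ("R1", "R1+", "R1-"):
            relapse_count = n if month == 12 else 0
        elif arm == "R2":
            relapse_count = n if month == 24 else 0
        else:
            relapse_count = 0
        rows.append(
            {
                "arm": arm,
                "month": month,
                "n": n,
                "f_to_m": round(n_f / n_m, 2) if n_m else np.inf,
                "median_age": grp["age"].median(),
                "median_age_symptoms": grp["age_symptoms"].median(),
                "median_symptom_duration": (
                    grp["age"] - grp["age_symptoms"]
                ).median(),
                "relapse_count": relapse_count,
                "median_baseline_edss": grp["baseline_edss"].median(),
                "worsening_count": int(grp["worse"].sum()),
            }
        )
    panel_table = pd.DataFrame(
        rows,
        columns=[
            "arm", "month", "n", "f_to_m", "median_age", "median_age_symptoms",
            "median_symptom_duration", "relapse_count", "median_baseline_edss",
            "worsening_count",
        ],
    )
    if len(panel_table):
        panel_table["arm"] = pd.Categorical(
            panel_table["arm"], categories=ARM_ORDER, ordered=True
        )
        panel_table = panel_table.sort_values(["arm", "month"]).reset_index(
            drop=True
        )
        panel_table["arm"] = panel_table["arm"].astype(str)
    return panel_table, observations
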