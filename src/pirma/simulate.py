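"""Synthetic treatment-registry generation.

Two generators back the pipeline's tests and demonstrations:

* :func:`generate_registry` draws seeded registries with the statistical
  structure the analysis assumes — an annual visit/MRI schedule, heavy
  year-over-year attrition, rare relapses with uniform onset inside each
  treatment year, monotone accumulation of silent progression with
  configured per-month cumulative probabilities, transient post-relapse
  EDSS elevation that remits over subsequent annual visits, and MRI
  activity that is most frequent early in treatment, lower on second-line
  therapy and lowest on natalizumab.

* :func:`make_fixture_from_counts` builds a minimal deterministic registry
  whose panel summary reproduces a given table of per-(arm, month) sizes
  and worsening counts exactly — the bridge from published summary counts
  to a concrete registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .registry import Registry

__all__ = ["GeneratorConfig", "default_config", "generate_registry",
           "make_fixture_from_counts"]

_EDSS_LEVELS = np.arange(0.0, 7.0, 0.5)
_EDSS_PROBS = (
    0.06, 0.08, 0.14, 0.18, 0.20, 0.10, 0.08,
    0.06, 0.04, 0.02, 0.02, 0.01, 0.007, 0.003,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Registry-simulation parameters (defaults = the study conditions).

    Probabilities are per patient unless stated otherwise.
    ``progression_prob_by_month`` gives the *cumulative* probability that a
    patient's silent progression has crossed the worsening threshold by
    months 12, 24, ..., 60; ``relapse_hazard_by_year`` the probability of a
    (single) relapse in each treatment year; ``annual_retention`` the
    probability of attending each annual visit given the previous one.
    """

    n_patients: int = 6000
    seed: int = 0
    female_fraction: float = 0.70
    age_mean: float = 36.5
    age_sd: float = 9.0
    symptom_lead_logmean: float = float(np.log(3.5))
    symptom_lead_logsd: float = 0.8
    baseline_edss_levels: tuple[float, ...] = tuple(_EDSS_LEVELS)
    baseline_edss_probs: tuple[float, ...] = _EDSS_PROBS
    drug_mix: dict = field(
        default_factory=lambda: {"INF": 0.50, "GLA": 0.25, "FTY": 0.15,
                                 "NAT": 0.10}
    )
    line_by_drug: dict = field(
        default_factory=lambda: {"INF": "first", "GLA": "first",
                                 "FTY": "second", "NAT": "second"}
    )
    relapse_hazard_by_year: tuple[float, ...] = (0.10, 0.05, 0.03, 0.02, 0.02)
    relapse_severity_high: float = 0.58
    high_increase_levels: tuple[float, ...] = (1.0, 1.5, 2.0)
    high_increase_probs: tuple[float, ...] = (0.6, 0.3, 0.1)
    low_increase: float = 0.5
    #: probability that a relapse's EDSS elevation is still present at the
    #: next annual examination (most relapses remit before it)
    relapse_persistence: float = 0.27
    #: per-visit geometric decay of a persisting elevation
    relapse_decay: float = 0.5
    progression_prob_by_month: tuple[float, ...] = (
        0.033, 0.046, 0.050, 0.056, 0.061,
    )
    mri_base_by_drug: dict = field(
        default_factory=lambda: {"INF": 0.32, "GLA": 0.30, "FTY": 0.18,
                                 "NAT": 0.08}
    )
    mri_year_multiplier: tuple[float, ...] = (1.0, 0.60, 0.45, 0.40, 0.40)
    #: MRI-activity probability at the visit following a relapse
    mri_relapse_prob: float = 0.42
    annual_retention: tuple[float, ...] = (0.90, 0.55, 0.47, 0.40, 0.45)
    start_day_range: int = 1096  # treatment starts drawn over three years

    def validate(self) -> None:
        seqs = {
            "relapse_hazard_by_year": self.relapse_hazard_by_year,
            "progression_prob_by_month": self.progression_prob_by_month,
            "annual_retention": self.annual_retention,
            "mri_year_multiplier": self.mri_year_multiplier,
        }
        for name, seq in seqs.items():
            if len(seq) < 5:
                raise ValueError(f"{name} needs >= 5 entries, got {len(seq)}")
        probs = (
            [self.female_fraction, self.relapse_severity_high,
             self.relapse_persistence, self.mri_relapse_prob]
            + list(self.relapse_hazard_by_year)
            + list(self.progression_prob_by_month)
            + list(self.annual_retention)
            + list(self.baseline_edss_probs)
            + list(self.drug_mix.values())
            + list(self.mri_base_by_drug.values())
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not np.isclose(sum(self.baseline_edss_probs), 1.0):
            raise ValueError("baseline_edss_probs must sum to 1")
        if not np.isclose(sum(self.drug_mix.values()), 1.0):
            raise ValueError("drug_mix must sum to 1")
        if np.any(np.diff(self.progression_prob_by_month) < 0):
            raise ValueError("progression_prob_by_month must be non-decreasing")


def default_config(**overrides) -> GeneratorConfig:
    """The calibrated default configuration, with keyword overrides."""
    config = GeneratorConfig()
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    return config


def _round_half(x: np.ndarray) -> np.ndarray:
    return np.round(x * 2.0) / 2.0


def generate_registry(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> Registry:
    """Draw one synthetic registry; reproducible for a given seed."""
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    if n == 0:
        return Registry.empty()

    patient_id = np.array([f"P{i:06d}" for i in range(n)])
    prescription_id = np.array([f"RX{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age = np.clip(
        np.round(rng.normal(config.age_mean, config.age_sd, n)), 18, 65
    ).astype(int)
    lead = np.round(
        rng.lognormal(config.symptom_lead_logmean, config.symptom_lead_logsd, n)
    ).astype(int)
    age_symptoms = np.clip(age - np.maximum(lead, 0), 10, None)
    age_symptoms = np.minimum(age_symptoms, age)

    baseline = rng.choice(
        config.baseline_edss_levels, size=n, p=config.baseline_edss_probs
    )
    drugs = list(config.drug_mix)
    drug = rng.choice(drugs, size=n, p=[config.drug_mix[d] for d in drugs])
    line = np.vectorize(config.line_by_drug.__getitem__)(drug)
    start = pd.Timestamp("2014-01-01") + pd.to_timedelta(
        rng.integers(0, config.start_day_range, n), unit="D"
    )

    # follow-up: number of consecutive annual visits attended after baseline
    retained = rng.random((n, 5)) < np.asarray(config.annual_retention)[None, :]
    follow = np.cumprod(retained, axis=1).sum(axis=1)  # 0..5

    # at most one relapse per treatment year, observed only within follow-up
    years = np.arange(1, 6)
    occur = (
        rng.random((n, 5)) < np.asarray(config.relapse_hazard_by_year)[None, :]
    ) & (years[None, :] <= follow[:, None])
    onset = 12.0 * (years - 1)[None, :] + rng.uniform(0.0, 12.0, (n, 5))
    high = rng.random((n, 5)) < config.relapse_severity_high
    high_inc = rng.choice(
        config.high_increase_levels, size=(n, 5), p=config.high_increase_probs
    )
    increase = np.where(high, high_inc, config.low_increase)
    persist = rng.random((n, 5)) < config.relapse_persistence

    # silent progression: month at which the worsening threshold is crossed
    cum = np.asarray(config.progression_prob_by_month[:5])
    u = rng.random(n)
    prog_year = np.searchsorted(cum, u) + 1  # 1..5, 6 = never
    threshold = np.where(baseline < 1.0, 1.5, np.where(baseline < 6.0, 1.0, 0.5))

    # MRI activity per visit year
    mri_base = np.vectorize(config.mri_base_by_drug.__getitem__)(drug)
    p_mri = mri_base[:, None] * np.asarray(config.mri_year_multiplier)[None, :]
    p_mri = np.where(occur, config.mri_relapse_prob, p_mri)
    active = rng.random((n, 5)) < p_mri
    t2 = np.where(active, 1 + rng.poisson(0.7, (n, 5)), 0)
    gd = np.where(active, rng.poisson(0.4, (n, 5)), 0)

    visit_rows = []
    visit_rows.append(
        pd.DataFrame(
            {
                "prescription_id": prescription_id,
                "month": 0,
                "edss": baseline,
                "new_t2_count": 0,
                "gd_count": 0,
            }
        )
    )
    decay_pow = np.array(
        [
            [config.relapse_decay ** (y - y0) if y >= y0 else 0.0
             for y0 in years]
            for y in years
        ]
    )  # decay_pow[y-1, y0-1]
    rel_elev = occur * persist * increase  # (n, 5) elevation at source year
    for y in years:
        mask = follow >= y
        if not mask.any():
            continue
        elev = _round_half(rel_elev[mask] @ decay_pow[y - 1])
        prog = np.where(prog_year[mask] <= y, threshold[mask], 0.0)
        edss = np.clip(baseline[mask] + prog + elev, 0.0, 10.0)
        visit_rows.append(
            pd.DataFrame(
                {
                    "prescription_id": prescription_id[mask],
                    "month": 12 * y,
                    "edss": edss,
                    "new_t2_count": t2[mask, y - 1],
                    "gd_count": gd[mask, y - 1],
                }
            )
        )
    visits = pd.concat(visit_rows, ignore_index=True)

    rel_idx, rel_year = np.nonzero(occur)
    relapses = pd.DataFrame(
        {
            "prescription_id": prescription_id[rel_idx],
            "month_of_onset": onset[rel_idx, rel_year],
            "edss_increase": increase[rel_idx, rel_year],
        }
    )

    end_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    dropped = follow < 5
    end_days = np.round((12 * follow + 6) * 30.4375).astype(int)
    end_date[dropped] = (
        pd.Series(start) + pd.to_timedelta(end_days, unit="D")
    )[dropped]

    registry = Registry(
        patients=pd.DataFrame(
            {
                "patient_id": patient_id,
                "sex": sex,
                "age_at_start": age,
                "age_at_first_symptoms": age_symptoms,
            }
        ),
        prescriptions=pd.DataFrame(
            {
                "prescription_id": prescription_id,
                "patient_id": patient_id,
                "drug": drug,
                "treatment_line": line,
                "start_date": start,
                "end_date": end_date.to_numpy(),
                "baseline_edss": baseline,
            }
        ),
        visits=visits,
        relapses=relapses,
    )
    registry.visits["new_t2_count"] = registry.visits["new_t2_count"].astype("Int64")
    registry.visits["gd_count"] = registry.visits["gd_count"].astype("Int64")
    return registry


# ---------------------------------------------------------------------------
# Deterministic fixtures from summary counts


def _check_counts(counts: pd.DataFrame) -> pd.DataFrame:
    required = {"arm", "month", "n", "positives"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table lacks column(s) {sorted(missing)}")
    counts = counts.copy()
    counts["month"] = counts["month"].astype(int)
    counts["n"] = counts["n"].astype(int)
    counts["positives"] = counts["positives"].astype(int)
    if (counts["positives"] > counts["n"]).any():
        raise ValueError("positives exceed n in the counts table")
    if (counts["n"] < 0).any():
        raise ValueError("negative n in the counts table")
    if not counts["month"].isin([12, 24, 36, 48, 60]).all():
        raise ValueError("months must be annual evaluation months 12..60")
    if counts.duplicated(["arm", "month"]).any():
        raise ValueError("duplicate (arm, month) rows in the counts table")
    return counts


def _cohort_frames(
    tag: str,
    n_by_month: dict[int, int],
    pos_by_month: dict[int, int],
    relapse: tuple[float, float] | None,
    lesion_month: int | None,
    start_index: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, int]:
    """Build one homogeneous cohort of prescriptions.

    Prescription k (0-based) is followed through every month m with
    k < n_by_month[m] (requires n non-increasing in month) and flagged
    worse at m iff k < pos_by_month[m].
    """
    months = sorted(n_by_month)
    sizes = [n_by_month[m] for m in months]
    if any(b > a for a, b in zip(sizes, sizes[1:])):
        raise ValueError(
            f"cohort {tag!r}: n must be non-increasing in month, got "
            f"{dict(zip(months, sizes))}"
        )
    total = sizes[0] if sizes else 0
    ids = [f"{tag}{start_index + k:05d}" for k in range(total)]
    baseline = 2.0
    patients = pd.DataFrame(
        {
            "patient_id": ids,
            # 2:1 female:male mix so the summary F:M is finite
            "sex": ["male" if k % 3 == 2 else "female" for k in range(total)],
            "age_at_start": 36,
            "age_at_first_symptoms": 32,
        }
    )
    prescriptions = pd.DataFrame(
        {
            "prescription_id": ids,
            "patient_id": ids,
            "drug": "INF",
            "treatment_line": "first",
            "start_date": pd.Timestamp("2015-01-01"),
            "end_date": pd.NaT,
            "baseline_edss": baseline,
        }
    )
    visit_rows = [
        {
            "prescription_id": pid,
            "month": 0,
            "edss": baseline,
            "new_t2_count": 0,
            "gd_count": 0,
        }
        for pid in ids
    ]
    # every prescription keeps an unbroken annual visit run through its last
    # counted month; months absent from the counts table contribute visits
    # (the follow-up window must be contiguous) but no worsening
    last = {
        k: max(m for m in months if k < n_by_month[m]) for k in range(total)
    }
    for k in range(total):
        for m in range(12, last[k] + 1, 12):
            worse = m in pos_by_month and k < pos_by_month[m] and m in months
            visit_rows.append(
                {
                    "prescription_id": ids[k],
                    "month": m,
                    "edss": baseline + (1.0 if worse else 0.0),
                    "new_t2_count": 0,
                    "gd_count": 1 if lesion_month == m else 0,
                }
            )
    visits = pd.DataFrame(
        visit_rows,
        columns=["prescription_id", "month", "edss", "new_t2_count", "gd_count"],
    )
    if relapse is not None:
        onset, inc = relapse
        relapses = pd.DataFrame(
            {
                "prescription_id": ids,
                "month_of_onset": onset,
                "edss_increase": inc,
            }
        )
    else:
        relapses = pd.DataFrame(
            columns=["prescription_id", "month_of_onset", "edss_increase"]
        )
    return patients, prescriptions, visits, relapses, start_index + total


def make_fixture_from_counts(arm_counts: pd.DataFrame) -> Registry:
    """Deterministic registry reproducing per-(arm, month) summary counts.

    ``arm_counts`` columns: ``arm`` (R0, R1, R1+, R1-, R2, R0+MRI0),
    ``month`` (12..60), ``n``, ``positives``.  R1 rows may be given either
    directly or implied by an R1+/R1- split (if both are present they must
    be consistent); R0+MRI0 rows must nest inside R0; an R2 month-12 row,
    if present, must equal the R0 month-12 row (it mirrors it by
    construction and is not separately built).
    """
    counts = _check_counts(arm_counts)
    if counts.empty:
        return Registry.empty()
    by_arm = {
        arm: grp.set_index("month")[["n", "positives"]]
        for arm, grp in counts.groupby("arm")
    }
    known = {"R0", "R1", "R1+", "R1-", "R2", "R0+MRI0"}
    unknown = set(by_arm) - known
    if unknown:
        raise ValueError(f"unknown arm(s) in counts table: {sorted(unknown)}")

    cohorts = []  # (tag, n_by_month, pos_by_month, relapse, lesion_month)

    has_split = "R1+" in by_arm or "R1-" in by_arm
    if has_split:
        if "R1" in by_arm:
            plus = by_arm.get("R1+")
            minus = by_arm.get("R1-")
            for m, row in by_arm["R1"].iterrows():
                s_n = (0 if plus is None or m not in plus.index else plus.loc[m, "n"]) + (
                    0 if minus is None or m not in minus.index else minus.loc[m, "n"]
                )
                s_p = (
                    0 if plus is None or m not in plus.index else plus.loc[m, "positives"]
                ) + (
                    0 if minus is None or m not in minus.index else minus.loc[m, "positives"]
                )
                if (row["n"], row["positives"]) != (s_n, s_p):
                    raise ValueError(
                        f"R1 row at month {m} inconsistent with R1+/R1- split"
                    )
        if "R1+" in by_arm:
            tab = by_arm["R1+"]
            cohorts.append(
                ("R1P", tab["n"].to_dict(), tab["positives"].to_dict(),
                 (9.0, 1.5), None)
            )
        if "R1-" in by_arm:
            tab = by_arm["R1-"]
            cohorts.append(
                ("R1M", tab["n"].to_dict(), tab["positives"].to_dict(),
                 (9.0, 0.5), None)
            )
    elif "R1" in by_arm:
        tab = by_arm["R1"]
        cohorts.append(
            ("R1A", tab["n"].to_dict(), tab["positives"].to_dict(),
             (9.0, 1.5), None)
        )

    if "R2" in by_arm:
        tab = by_arm["R2"].copy()
        if 12 in tab.index:
            if "R0" not in by_arm or not (
                tab.loc[12].equals(by_arm["R0"].loc[12])
                if 12 in by_arm["R0"].index
                else False
            ):
                raise ValueError(
                    "an R2 month-12 row must equal the R0 month-12 row "
                    "(it mirrors the relapse-free evaluation set)"
                )
            tab = tab.drop(index=12)
        if len(tab):
            cohorts.append(
                ("R2C", tab["n"].to_dict(), tab["positives"].to_dict(),
                 (20.0, 1.5), None)
            )

    if "R0" in by_arm:
        r0 = by_arm["R0"]
        if "R0+MRI0" in by_arm:
            m0 = by_arm["R0+MRI0"]
            extra = set(m0.index) - set(r0.index)
            if extra:
                raise ValueError(f"R0+MRI0 months {sorted(extra)} not in R0")
            comp_n, comp_p = {}, {}
            for m, row in r0.iterrows():
                sub_n = int(m0.loc[m, "n"]) if m in m0.index else 0
                sub_p = int(m0.loc[m, "positives"]) if m in m0.index else 0
                if sub_n > row["n"] or sub_p > row["positives"]:
                    raise ValueError(
                        f"R0+MRI0 exceeds R0 at month {m}"
                    )
                comp_n[m] = int(row["n"]) - sub_n
                comp_p[m] = int(row["positives"]) - sub_p
                if comp_p[m] > comp_n[m]:
                    raise ValueError(
                        f"R0 minus R0+MRI0 at month {m}: positives "
                        f"{comp_p[m]} exceed n {comp_n[m]}"
                    )
            cohorts.append(
                ("R0S", m0["n"].to_dict(), m0["positives"].to_dict(),
                 None, None)
            )
            if any(v > 0 for v in comp_n.values()):
                cohorts.append(("R0A", comp_n, comp_p, None, 12))
        else:
            # keep the R0+MRI0 arm empty unless explicitly requested
            cohorts.append(
                ("R0A", r0["n"].to_dict(), r0["positives"].to_dict(),
                 None, 12)
            )
    elif "R0+MRI0" in by_arm:
        tab = by_arm["R0+MRI0"]
        cohorts.append(
            ("R0S", tab["n"].to_dict(), tab["positives"].to_dict(), None, None)
        )

    frames = {"patients": [], "prescriptions": [], "visits": [], "relapses": []}
    index = 0
    for tag, n_by_month, pos_by_month, relapse, lesion_month in cohorts:
        p, rx, v, r, index = _cohort_frames(
            tag, n_by_month, pos_by_month, relapse, lesion_month, index
        )
        frames["patients"].append(p)
        frames["prescriptions"].append(rx)
        frames["visits"].append(v)
        frames["relapses"].append(r)
    if not frames["patients"]:
        return Registry.empty()
    registry = Registry(
        **{
            name: pd.concat(
                [p for p in parts if not p.empty] or parts, ignore_index=True
            )
            for name, parts in frames.items()
        }
    )
    registry.relapses["month_of_onset"] = registry.relapses[
        "month_of_onset"
    ].astype(float)
    registry.relapses["edss_increase"] = registry.relapses[
        "edss_increase"
    ].astype(float)
    registry.visits["new_t2_count"] = registry.visits["new_t2_count"].astype("Int64")
    registry.visits["gd_count"] = registry.visits["gd_count"].astype("Int64")
    return registry
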