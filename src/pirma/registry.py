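"""Registry data model and CSV interchange.

A registry is four linked tables mirroring how treatment-programme
monitoring systems record DMT-treated RRMS patients:

* ``patients``      - one row per patient (sex, age at treatment start,
                      age at first symptoms),
* ``prescriptions`` - one row per patient x drug treatment episode, with the
                      start/end dates and the fixed baseline EDSS,
* ``visits``        - annual visits keyed by integer month since treatment
                      start (0, 12, ..., 60) carrying the EDSS score and the
                      new-T2 / Gd+ lesion counts since the previous scan,
* ``relapses``      - relapses with a real-valued onset month and the EDSS
                      increase they produced.

The interchange format is four co-located CSV files (UTF-8, header row,
ISO-8601 dates, empty cell = missing).  Validation is total: it returns a
report of violations rather than raising, so dirty registries can be
triaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .events import EDSS_STEP

__all__ = [
    "Registry",
    "ValidationReport",
    "Violation",
    "RegistryIOError",
    "RegistryParseError",
    "read_registry",
    "write_registry",
    "validate_registry",
    "VISIT_MONTHS",
]

#: The annual visit schedule, months since prescription start.
VISIT_MONTHS = (0, 12, 24, 36, 48, 60)

TABLE_COLUMNS = {
    "patients": ["patient_id", "sex", "age_at_start", "age_at_first_symptoms"],
    "prescriptions": [
        "prescription_id",
        "patient_id",
        "drug",
        "treatment_line",
        "start_date",
        "end_date",
        "baseline_edss",
    ],
    "visits": ["prescription_id", "month", "edss", "new_t2_count", "gd_count"],
    "relapses": ["prescription_id", "month_of_onset", "edss_increase"],
}

DRUGS = ("INF", "GLA", "FTY", "NAT")
TREATMENT_LINES = ("first", "second")
SEXES = ("female", "male")


class RegistryIOError(OSError):
    """A registry table file is missing or unreadable."""


class RegistryParseError(ValueError):
    """A registry field failed parsing; the message names table/row/column."""


@dataclass
class Registry:
    """In-memory registry: four pandas DataFrames with fixed schemas."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    visits: pd.DataFrame
    relapses: pd.DataFrame

    def __post_init__(self) -> None:
        for name in TABLE_COLUMNS:
            frame = getattr(self, name)
            missing = [c for c in TABLE_COLUMNS[name] if c not in frame.columns]
            if missing:
                raise RegistryParseError(f"table {name!r} lacks columns {missing}")
            setattr(self, name, frame[TABLE_COLUMNS[name]].copy())

    @classmethod
    def empty(cls) -> "Registry":
        frames = {}
        for name, cols in TABLE_COLUMNS.items():
            frames[name] = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        reg = cls(**frames)
        return _coerce_types(reg)

    def canonical(self) -> "Registry":
        """Deterministically sorted copy (the serialization order)."""
        return Registry(
            patients=self.patients.sort_values("patient_id", kind="mergesort")
            .reset_index(drop=True),
            prescriptions=self.prescriptions.sort_values(
                "prescription_id", kind="mergesort"
            ).reset_index(drop=True),
            visits=self.visits.sort_values(
                ["prescription_id", "month"], kind="mergesort"
            ).reset_index(drop=True),
            relapses=self.relapses.sort_values(
                ["prescription_id", "month_of_onset", "edss_increase"],
                kind="mergesort",
            ).reset_index(drop=True),
        )

    def equals(self, other: "Registry") -> bool:
        a, b = self.canonical(), other.canonical()
        return all(
            getattr(a, name).equals(getattr(b, name)) for name in TABLE_COLUMNS
        )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - delegation
        if not isinstance(other, Registry):
            return NotImplemented
        return self.equals(other)

    def counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in TABLE_COLUMNS}


@dataclass(frozen=True)
class Violation:
    table: str
    record: str
    rule: str
    detail: str

    def __str__(self) -> str:
        return f"[{self.table}:{self.record}] {self.rule}: {self.detail}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, table: str, record: object, rule: str, detail: str) -> None:
        self.violations.append(Violation(table, str(record), rule, detail))

    def __len__(self) -> int:
        return len(self.violations)

    def __str__(self) -> str:
        if self.ok:
            return "registry valid: no violations"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  {v}" for v in self.violations]
        return "\n".join(lines)


def _coerce_types(registry: Registry) -> Registry:
    """Coerce column dtypes in place; raise RegistryParseError on failure."""

    def to_num(frame: pd.DataFrame, table: str, col: str, dtype: str) -> None:
        if dtype == "float64":
            # element-wise float() parses IEEE-exactly (CSV round-trip);
            # pandas' fast C parser may be off by half an ulp
            def conv(x):
                if x is None or (isinstance(x, float) and np.isnan(x)):
                    return np.nan
                return float(x)

            try:
                frame[col] = np.array(
                    [conv(x) for x in frame[col]], dtype="float64"
                )
                return
            except (ValueError, TypeError) as exc:
                raise RegistryParseError(
                    f"table {table!r}, column {col!r}: unparseable value"
                ) from exc
        try:
            converted = pd.to_numeric(frame[col], errors="raise")
            frame[col] = converted.astype(dtype)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(frame[col], errors="coerce")
            rows = frame.index[bad.isna() & frame[col].notna()].tolist()[:5]
            raise RegistryParseError(
                f"table {table!r}, column {col!r}: unparseable value(s) "
                f"at row(s) {rows}"
            ) from exc

    p = registry.patients
    p["patient_id"] = p["patient_id"].astype(str)
    p["sex"] = p["sex"].astype(str)
    to_num(p, "patients", "age_at_start", "int64")
    to_num(p, "patients", "age_at_first_symptoms", "int64")

    rx = registry.prescriptions
    for col in ("prescription_id", "patient_id", "drug", "treatment_line"):
        rx[col] = rx[col].astype(str)
    for col in ("start_date", "end_date"):
        try:
            rx[col] = pd.to_datetime(rx[col], format="ISO8601", errors="raise")
        except (ValueError, TypeError) as exc:
            raise RegistryParseError(
                f"table 'prescriptions', column {col!r}: unparseable date"
            ) from exc
    to_num(rx, "prescriptions", "baseline_edss", "float64")

    v = registry.visits
    v["prescription_id"] = v["prescription_id"].astype(str)
    to_num(v, "visits", "month", "int64")
    to_num(v, "visits", "edss", "float64")
    # Lesion counts are nullable: a scan may be missing at a visit.
    to_num(v, "visits", "new_t2_count", "Int64")
    to_num(v, "visits", "gd_count", "Int64")

    r = registry.relapses
    r["prescription_id"] = r["prescription_id"].astype(str)
    to_num(r, "relapses", "month_of_onset", "float64")
    to_num(r, "relapses", "edss_increase", "float64")
    return registry


def _parse_checks(registry: Registry) -> None:
    """Structural checks enforced at read time (raise, do not report)."""
    v = registry.visits
    bad_month = ~v["month"].isin(VISIT_MONTHS)
    if bad_month.any():
        raise RegistryParseError(
            "table 'visits', column 'month': values must lie on the annual "
            f"grid {VISIT_MONTHS}; offending row(s) "
            f"{v.index[bad_month].tolist()[:5]}"
        )
    dup = v.duplicated(subset=["prescription_id", "month"], keep=False)
    if dup.any():
        pairs = v.loc[dup, ["prescription_id", "month"]].drop_duplicates()
        raise RegistryParseError(
            "table 'visits': duplicate (prescription_id, month) visit(s): "
            + ", ".join(f"({p},{m})" for p, m in pairs.itertuples(index=False))
        )
    for table, col in (
        ("prescriptions", "baseline_edss"),
        ("visits", "edss"),
        ("relapses", "edss_increase"),
    ):
        series = getattr(registry, table)[col]
        off = ~np.isclose(
            np.round(series / EDSS_STEP) * EDSS_STEP, series, equal_nan=True
        )
        if off.any():
            raise RegistryParseError(
                f"table {table!r}, column {col!r}: values off the "
                f"{EDSS_STEP}-point EDSS grid at row(s) "
                f"{series.index[off].tolist()[:5]}"
            )


def read_registry(path: str | Path) -> Registry:
    """Read a registry bundle directory of four CSV tables.

    Parameters
    ----------
    path
        Directory containing ``patients.csv``, ``prescriptions.csv``,
        ``visits.csv`` and ``relapses.csv``.
    """
    path = Path(path)
    frames = {}
    for name, cols in TABLE_COLUMNS.items():
        file = path / f"{name}.csv"
        if not file.exists():
            raise RegistryIOError(f"missing registry table: {file}")
        frame = pd.read_csv(file, dtype=object, keep_default_na=True)
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise RegistryParseError(f"table {name!r} lacks columns {missing}")
        frames[name] = frame
    registry = _coerce_types(Registry(**frames))
    _parse_checks(registry)
    return registry


def write_registry(registry: Registry, path: str | Path) -> None:
    """Write the four CSV tables; round-trips through :func:`read_registry`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    reg = registry.canonical()
    for name in TABLE_COLUMNS:
        frame = getattr(reg, name).copy()
        for col in frame.columns:
            if pd.api.types.is_datetime64_any_dtype(frame[col]):
                frame[col] = frame[col].dt.strftime("%Y-%m-%d")
        # %.17g guarantees binary round-trip of float columns
        frame.to_csv(path / f"{name}.csv", index=False, float_format="%.17g")


def validate_registry(registry: Registry) -> ValidationReport:
    """Check every structural invariant; never raises on parseable input."""
    report = ValidationReport()
    p, rx, v, r = (
        registry.patients,
        registry.prescriptions,
        registry.visits,
        registry.relapses,
    )

    def flag(table: str, ids: Iterable, rule: str, detail) -> None:
        for rid in ids:
            report.add(table, rid, rule, detail if isinstance(detail, str)
                       else detail(rid))

    flag("patients", p["patient_id"][p["patient_id"].duplicated()],
         "unique_id", "duplicate patient_id")
    flag("patients", p.loc[~p["sex"].isin(SEXES), "patient_id"],
         "sex", "sex not in {female, male}")
    bad_age = ~(
        (p["age_at_first_symptoms"] >= 0)
        & (p["age_at_first_symptoms"] <= p["age_at_start"])
        & (p["age_at_start"] <= 120)
    )
    flag("patients", p.loc[bad_age, "patient_id"], "age_order",
         "ages must satisfy 0 <= age_at_first_symptoms <= age_at_start <= 120")

    patient_ids = set(p["patient_id"])
    flag("prescriptions",
         rx["prescription_id"][rx["prescription_id"].duplicated()],
         "unique_id", "duplicate prescription_id")
    flag("prescriptions",
         rx.loc[~rx["patient_id"].isin(patient_ids), "prescription_id"],
         "foreign_key", "unknown patient_id")
    flag("prescriptions", rx.loc[~rx["drug"].isin(DRUGS), "prescription_id"],
         "drug", f"drug not in {DRUGS}")
    flag("prescriptions",
         rx.loc[~rx["treatment_line"].isin(TREATMENT_LINES), "prescription_id"],
         "treatment_line", f"treatment_line not in {TREATMENT_LINES}")
    bad_dates = rx["end_date"].notna() & (rx["end_date"] < rx["start_date"])
    flag("prescriptions", rx.loc[bad_dates, "prescription_id"],
         "date_order", "end_date before start_date")
    flag("prescriptions",
         rx.loc[~_edss_ok_vec(rx["baseline_edss"]), "prescription_id"],
         "edss_grid", "baseline_edss off the EDSS grid")

    rx_ids = set(rx["prescription_id"])
    orphan = ~v["prescription_id"].isin(rx_ids)
    flag("visits", v.loc[orphan, "prescription_id"].unique(),
         "foreign_key", "orphan visit")
    vv = v[~orphan]
    dup = vv.duplicated(subset=["prescription_id", "month"])
    flag("visits", vv.loc[dup, "prescription_id"],
         "unique_visit", "duplicate (prescription, month) visit")
    flag("visits", vv.loc[~vv["month"].isin(VISIT_MONTHS), "prescription_id"],
         "month_grid", f"month not in {VISIT_MONTHS}")
    flag("visits", vv.loc[~_edss_ok_vec(vv["edss"]), "prescription_id"],
         "edss_grid", "visit EDSS off the grid")
    for col in ("new_t2_count", "gd_count"):
        neg = vv[col].notna() & (vv[col] < 0)
        flag("visits", vv.loc[neg.fillna(False).astype(bool),
                              "prescription_id"],
             "lesion_counts", f"negative {col}")
    baseline = rx.set_index("prescription_id")["baseline_edss"]
    m0 = vv[vv["month"] == 0].drop_duplicates("prescription_id")
    expected = baseline.reindex(m0["prescription_id"]).to_numpy()
    mismatch = ~np.isclose(m0["edss"].to_numpy(dtype=float), expected)
    flag("visits", m0.loc[mismatch, "prescription_id"], "baseline_match",
         "month-0 EDSS differs from baseline_edss")
    flag("visits", sorted(rx_ids - set(m0["prescription_id"])),
         "baseline_visit", "no month-0 visit")

    flag("relapses",
         r.loc[~r["prescription_id"].isin(rx_ids), "prescription_id"],
         "foreign_key", "orphan relapse")
    flag("relapses", r.loc[r["month_of_onset"] < 0, "prescription_id"],
         "onset", "negative month_of_onset")
    bad_inc = (r["edss_increase"] < 0) | ~_delta_ok_vec(r["edss_increase"])
    flag("relapses", r.loc[bad_inc, "prescription_id"],
         "edss_grid", "edss_increase off the EDSS-delta grid")
    return report


def _edss_ok_vec(values: pd.Series) -> np.ndarray:
    x = values.to_numpy(dtype=float)
    return (
        np.isfinite(x)
        & (x >= 0.0)
        & (x <= 10.0)
        & np.isclose(np.round(x / EDSS_STEP) * EDSS_STEP, x)
    )


def _delta_ok_vec(values: pd.Series) -> np.ndarray:
    x = values.to_numpy(dtype=float)
    return np.isfinite(x) & np.isclose(np.round(x / EDSS_STEP) * EDSS_STEP, x)
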