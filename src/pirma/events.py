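"""Event definitions for disability worsening/progression in treated RRMS.

Confirmed worsening is judged against a *fixed* baseline EDSS (the score at
treatment start), never a roving reference: each annual EDSS is compared to
baseline and flagged when the increase reaches a baseline-dependent
threshold.  Relapses are graded low/high by the EDSS increase they caused,
brain MRI activity is the presence of any new T2 or gadolinium-enhancing
lesion since the previous scan, and a confirmed worsening is labelled by the
relapse/MRI context of the panel it was observed in:

* RAW   - relapse-associated worsening (a qualifying relapse on treatment),
* PIRA  - progression independent of relapse activity (no relapses),
* PIRMA - progression independent of relapses *and* brain MRI activity.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = [
    "EDSS_STEP",
    "ProgressionLabel",
    "RelapseSeverity",
    "validate_edss",
    "worsening_threshold",
    "is_confirmed_worsening",
    "classify_relapse_severity",
    "mri_active",
    "progression_label",
]

EDSS_STEP = 0.5

#: Default boundary above/at which a relapse's EDSS increase is graded high.
SEVERITY_HIGH_MIN = 1.0

_RAW_PANELS = frozenset({"R1", "R2", "R1+", "R1-"})


class RelapseSeverity(str, enum.Enum):
    LOW = "low"
    HIGH = "high"


class ProgressionLabel(str, enum.Enum):
    RAW = "RAW"
    PIRA = "PIRA"
    PIRMA = "PIRMA"
    NONE = "none"


def _on_grid(value: float) -> bool:
    return bool(np.isclose(np.round(value / EDSS_STEP) * EDSS_STEP, value))


def validate_edss(value: float, *, name: str = "edss") -> float:
    """Check an EDSS score lies on the half-point grid in [0, 10]."""
    value = float(value)
    if not np.isfinite(value) or not (0.0 <= value <= 10.0):
        raise ValueError(f"{name} must be in [0, 10], got {value}")
    if not _on_grid(value):
        raise ValueError(f"{name} must be a multiple of {EDSS_STEP}, got {value}")
    return value


def worsening_threshold(baseline_edss: float) -> float:
    """Minimum EDSS increase that counts as confirmed worsening.

    The threshold is a non-increasing step function of the baseline score:
    1.5 points below EDSS 1, 1.0 point from 1 up to (but excluding) 6, and
    0.5 points at 6 or above — low-disability patients must move further on
    the scale before the change is considered clinically meaningful.
    """
    baseline_edss = validate_edss(baseline_edss, name="baseline_edss")
    if baseline_edss < 1.0:
        return 1.5
    if baseline_edss < 6.0:
        return 1.0
    return 0.5


def is_confirmed_worsening(baseline_edss: float, current_edss: float) -> bool:
    """True iff ``current_edss - baseline_edss`` meets the baseline threshold."""
    threshold = worsening_threshold(baseline_edss)
    current_edss = validate_edss(current_edss, name="current_edss")
    # EDSS values are exact halves, so the comparison is safe up to rounding
    # noise from upstream arithmetic; tolerate 1e-9.
    return current_edss - baseline_edss >= threshold - 1e-9


def classify_relapse_severity(
    edss_increase: float, *, high_min: float = SEVERITY_HIGH_MIN
) -> RelapseSeverity:
    """Grade a relapse low/high by the EDSS increase it produced.

    A 0.5-point increase is the canonical low relapse; increases of
    ``high_min`` (default 1.0) or more are high.  The boundary is
    configurable because the clinical wording ("0.5-point" vs "more than
    one point") leaves exactly 1.0 unassigned; placing it with the high
    grade keeps the low/high split an exhaustive partition.
    """
    edss_increase = float(edss_increase)
    if edss_increase < 0 or not _on_grid(edss_increase):
        raise ValueError(
            f"edss_increase must be a non-negative multiple of {EDSS_STEP}, "
            f"got {edss_increase}"
        )
    return (
        RelapseSeverity.HIGH
        if edss_increase >= high_min - 1e-9
        else RelapseSeverity.LOW
    )


def mri_active(new_t2_count: int, gd_count: int) -> bool:
    """Brain MRI activity: any new T2 lesion and/or any Gd-enhancing lesion."""
    new_t2_count = int(new_t2_count)
    gd_count = int(gd_count)
    if new_t2_count < 0 or gd_count < 0:
        raise ValueError("lesion counts must be non-negative")
    return new_t2_count >= 1 or gd_count >= 1


def progression_label(
    panel: str, worse: bool, mri_restricted: bool = False
) -> ProgressionLabel:
    """Label a confirmed worsening by its panel context.

    RAW in the relapse panels (R1/R2 and the severity splits), PIRA in the
    relapse-free panel R0, and PIRMA in the relapse-free panel further
    restricted to MRI-inactive follow-up (R0+MRI0).  Without a confirmed
    worsening the label is ``none`` regardless of the panel.
    """
    if panel not in _RAW_PANELS and panel not in {"R0", "R0+MRI0"}:
        raise ValueError(f"unknown panel {panel!r}")
    if not worse:
        return ProgressionLabel.NONE
    if panel in _RAW_PANELS:
        return ProgressionLabel.RAW
    if panel == "R0+MRI0":
        return ProgressionLabel.PIRMA
    return ProgressionLabel.PIRA
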