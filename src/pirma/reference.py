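"""Published summary counts from the Polish DMT-registry progression study.

Per-(arm, month) numbers of evaluated prescriptions and confirmed
worsenings, as reported in the study's patient-characteristics table.
Together with :func:`pirma.simulate.make_fixture_from_counts` these counts
reconstruct a registry whose covariate-free analysis reproduces the
published raw proportions exactly (e.g. the R1- arm: 13/250 = 0.052 at
month 12, 2/80 = 0.025 at month 24).

The R2 month-12 row is intentionally absent: it mirrors the R0 evaluation
set (before the second-year relapse, R2 candidates are indistinguishable
from relapse-free prescriptions) and the panel builder reproduces it from
the R0 arm.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_panel_counts"]

_ROWS = [
    # arm, month, n, positives (confirmed worsenings)
    ("R0", 12, 5339, 231),
    ("R0", 24, 2961, 184),
    ("R0", 36, 1392, 93),
    ("R0", 48, 525, 40),
    ("R0", 60, 255, 21),
    ("R1", 12, 592, 103),
    ("R1", 24, 153, 17),
    ("R1", 36, 63, 5),
    ("R1", 48, 21, 0),
    ("R1", 60, 10, 1),
    ("R1+", 12, 342, 90),
    ("R1+", 24, 73, 15),
    ("R1+", 36, 23, 5),
    ("R1+", 48, 9, 0),
    ("R1+", 60, 4, 0),
    ("R1-", 12, 250, 13),
    ("R1-", 24, 80, 2),
    ("R1-", 36, 40, 0),
    ("R1-", 48, 12, 0),
    ("R1-", 60, 6, 1),
    ("R2", 24, 378, 94),
    ("R2", 36, 116, 16),
    ("R2", 48, 31, 5),
    ("R2", 60, 12, 3),
    ("R0+MRI0", 12, 4051, 170),
    ("R0+MRI0", 24, 2010, 130),
    ("R0+MRI0", 36, 885, 67),
    ("R0+MRI0", 48, 296, 27),
    ("R0+MRI0", 60, 139, 11),
]


def reference_panel_counts(arms: tuple[str, ...] | None = None) -> pd.DataFrame:
    """The published (arm, month, n, positives) counts, optionally filtered."""
    table = pd.DataFrame(_ROWS, columns=["arm", "month", "n", "positives"])
    if arms is not None:
        table = table[table["arm"].isin(arms)].reset_index(drop=True)
    return table
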