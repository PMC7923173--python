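"""Follow-up truncation, panel assignment and the per-arm summary table."""

import pandas as pd
import pytest

from pirma import (
    PanelConfig,
    assign_panel,
    build_panel_table,
    default_config,
    generate_registry,
    truncate_follow_up,
)
from pirma.panels import split_r1_by_severity


def _visits(months):
    return pd.DataFrame({"month": list(months)})


def _rx(end_date=None, start="2015-01-15"):
    return {
        "prescription_id": "RX1",
        "start_date": pd.Timestamp(start),
        "end_date": pd.Timestamp(end_date) if end_date else None,
    }


class TestTruncateFollowUp:
    def test_full_contiguous_run(self):
        assert truncate_follow_up(_rx(), _visits([0, 12, 24, 36, 48, 60])) == (0, 60)

    def test_gap_ends_window_even_with_later_visits(self):
        assert truncate_follow_up(_rx(), _visits([0, 12, 36, 48])) == (0, 12)

    def test_baseline_only(self):
        assert truncate_follow_up(_rx(), _visits([0])) == (0, 0)

    def test_missing_baseline_raises(self):
        with pytest.raises(ValueError, match="month-0"):
            truncate_follow_up(_rx(), _visits([12, 24]))

    def test_end_date_caps_window(self):
        # 30 calendar months of exposure: the month-36 visit is out of window.
        window = truncate_follow_up(
            _rx(end_date="2017-07-20"), _visits([0, 12, 24, 36])
        )
        assert window == (0, 24)

    def test_end_date_day_before_anniversary_caps_tighter(self):
        # Ends one day short of 24 whole months.
        window = truncate_follow_up(
            _rx(end_date="2017-01-14"), _visits([0, 12, 24])
        )
        assert window == (0, 12)


class TestAssignPanel:
    def _one(self, onsets, window=(0, 60), config=None):
        relapses = pd.DataFrame(
            {"month_of_onset": list(onsets),
             "edss_increase": [1.0] * len(onsets)}
        )
        return assign_panel(_rx(), relapses, window, config)

    def test_no_relapse_is_r0(self):
        assert self._one([]) == "R0"

    @pytest.mark.parametrize("t", [6.0, 9.0, 15.0])
    def test_first_window_closed_on_both_ends(self, t):
        assert self._one([t]) == "R1"

    @pytest.mark.parametrize("t", [15.5, 20.0, 27.0])
    def test_second_window_open_below_closed_above(self, t):
        assert self._one([t]) == "R2"

    @pytest.mark.parametrize("t", [2.0, 5.5, 27.5, 40.0])
    def test_outside_both_windows_unclassified(self, t):
        assert self._one([t]) == "unclassified"

    def test_two_relapses_unclassified(self):
        assert self._one([8.0, 20.0]) == "unclassified"

    def test_relapse_beyond_observed_window_is_invisible(self):
        assert self._one([20.0], window=(0, 12)) == "R0"

    def test_ignore_policy_discards_early_relapse(self):
        cfg = PanelConfig(early_relapse_policy="ignore")
        assert self._one([2.0], config=cfg) == "R0"
        assert self._one([2.0, 9.0], config=cfg) == "R1"

    def test_custom_windows(self):
        cfg = PanelConfig(r1_window=(3.0, 12.0), r2_window=(12.0, 24.0))
        assert self._one([4.0], config=cfg) == "R1"
        assert self._one([14.0], config=cfg) == "R2"
        assert self._one([26.0], config=cfg) == "unclassified"

    def test_bad_policy_rejected(self):
        with pytest.raises(ValueError, match="early_relapse_policy"):
            PanelConfig(early_relapse_policy="drop")


def test_severity_split_requires_edss_increase():
    assignment = pd.DataFrame(
        {
            "panel": ["R1", "R1"],
            "relapse_increase": [1.0, float("nan")],
            "window_end": [60, 60],
        },
        index=["A", "B"],
    )
    with pytest.raises(ValueError, match="edss_increase"):
        split_r1_by_severity(assignment)


class TestPublishedCounts:
    """The published-counts fixture must reproduce its own summary table."""

    def test_every_published_row_reproduced(
        self, published_counts, published_panels
    ):
        table = published_panels[0].set_index(["arm", "month"])
        for _, row in published_counts.iterrows():
            got = table.loc[(row["arm"], row["month"])]
            assert got["n"] == row["n"], (row["arm"], row["month"])
            assert got["worsening_count"] == row["positives"], (
                row["arm"], row["month"],
            )

    def test_no_extra_rows(self, published_counts, published_panels):
        want = set(zip(published_counts["arm"], published_counts["month"]))
        got = set(zip(published_panels[0]["arm"], published_panels[0]["month"]))
        # The table adds the pre-relapse R2 month-12 mirror of R0.
        assert got == want | {("R2", 12)}

    def test_r2_month_12_mirrors_r0(self, published_panels):
        table, obs = published_panels
        r0 = table.query("arm == 'R0' and month == 12").iloc[0]
        r2 = table.query("arm == 'R2' and month == 12").iloc[0]
        assert (r2["n"], r2["worsening_count"]) == (
            r0["n"], r0["worsening_count"],
        )
        mirror = obs.query("arm == 'R2' and month == 12")
        assert mirror["pre_relapse"].all()
        assert set(mirror["prescription_id"]) == set(
            obs.query("arm == 'R0' and month == 12")["prescription_id"]
        )

    def test_r1_severity_partition(self, published_panels):
        table = published_panels[0].set_index(["arm", "month"])
        for month in (12, 24, 36, 48, 60):
            if ("R1", month) not in table.index:
                continue
            assert (
                table.loc[("R1+", month), "n"]
                + table.loc[("R1-", month), "n"]
                == table.loc[("R1", month), "n"]
            )


@pytest.fixture(scope="module")
def panels():
    registry = generate_registry(default_config(n_patients=1200), seed=3)
    return build_panel_table(registry)


class TestSyntheticInvariants:

    def test_arms_disjoint_per_month_excluding_nesting(self, panels):
        obs = panels[1]
        real = obs[~obs["pre_relapse"]]
        for month, grp in real.groupby("month"):
            by_arm = {
                arm: set(g["prescription_id"])
                for arm, g in grp.groupby("arm")
            }
            top = [by_arm.get(a, set()) for a in ("R0", "R1", "R2")]
            assert not (top[0] & top[1] or top[0] & top[2] or top[1] & top[2])
            r1 = by_arm.get("R1", set())
            assert by_arm.get("R1+", set()) | by_arm.get("R1-", set()) == r1
            assert by_arm.get("R1+", set()).isdisjoint(by_arm.get("R1-", set()))
            assert by_arm.get("R0+MRI0", set()) <= by_arm.get("R0", set())

    def test_n_non_increasing_within_arm(self, panels):
        for arm, grp in panels[0].groupby("arm"):
            ns = grp.sort_values("month")["n"].tolist()
            assert ns == sorted(ns, reverse=True), arm

    def test_worsening_count_bounded_by_n(self, panels):
        table = panels[0]
        assert (table["worsening_count"] <= table["n"]).all()
        assert (table["worsening_count"] >= 0).all()

    def test_evaluations_within_observed_window(self, panels):
        obs = panels[1]
        assert obs["month"].isin([12, 24, 36, 48, 60]).all()

    def test_relapse_count_conventions(self, panels):
        table = panels[0].set_index(["arm", "month"])
        for (arm, month), row in table.iterrows():
            if arm in ("R1", "R1+", "R1-") and month == 12:
                assert row["relapse_count"] == row["n"]
            elif arm == "R2" and month == 24:
                assert row["relapse_count"] == row["n"]
            else:
                assert row["relapse_count"] == 0
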