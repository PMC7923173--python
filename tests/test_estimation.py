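"""Proportions, logistic fits, adjusted means, letters and contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pirma import (
    ModelSpec,
    adjusted_means,
    arm_adjusted_table,
    binomial_se,
    compare_panels,
    default_config,
    fit_model,
    generate_registry,
    build_panel_table,
    raw_proportion,
    tukey_groups,
    wald_ci_logit,
)
from pirma.estimation import FitError, _compact_letters


class TestScalarStatistics:
    def test_raw_proportion(self):
        assert raw_proportion(13, 250) == pytest.approx(0.052)
        with pytest.raises(ValueError):
            raw_proportion(5, 0)
        with pytest.raises(ValueError):
            raw_proportion(-1, 10)
        with pytest.raises(ValueError):
            raw_proportion(11, 10)

    def test_binomial_se_matches_formula(self):
        p, n = 0.052, 250
        assert binomial_se(p, n) == pytest.approx(
            math.sqrt(p * (1 - p) / n)
        )

    def test_wald_ci_logit_hand_computed(self):
        # logit(0.052) = -2.903; se_logit = se / (p (1-p)) = 0.2845
        p, n = 0.052, 250
        lcl, ucl = wald_ci_logit(p, binomial_se(p, n))
        assert lcl == pytest.approx(0.0304, abs=5e-4)
        assert ucl == pytest.approx(0.0875, abs=5e-4)

    def test_ci_respects_unit_interval(self):
        lcl, ucl = wald_ci_logit(0.01, binomial_se(0.01, 30))
        assert 0.0 < lcl < 0.01 < ucl < 1.0


def _obs(months, probs, n_per_month, rng):
    frames = []
    for m, p in zip(months, probs):
        frames.append(
            pd.DataFrame(
                {
                    "month": m,
                    "worse": rng.random(n_per_month) < p,
                    "baseline_edss": 2.0,
                    "age": 30.0,
                    "sex": "female",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestFitModel:
    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(11)
        true = (0.03, 0.05, 0.06)
        sizes = (5000, 2500, 1000)
        frames = []
        for m, p, n in zip((12, 24, 36), true, sizes):
            frames.append(
                pd.DataFrame({"month": m, "worse": rng.random(n) < p})
            )
        obs = pd.concat(frames, ignore_index=True)
        model = fit_model(obs, ModelSpec())
        est = adjusted_means(model).table.set_index("month")
        for m, p, n in zip((12, 24, 36), true, sizes):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(est.loc[m, "prob"] - p) < 3 * se

    def test_covariate_free_means_equal_raw_proportions(self):
        obs = _obs((12, 24), (0.08, 0.04), 600, np.random.default_rng(5))
        model = fit_model(obs, ModelSpec())
        est = adjusted_means(model).table.set_index("month")
        for m in (12, 24):
            grp = obs[obs["month"] == m]["worse"]
            p_hat = grp.mean()
            assert est.loc[m, "prob"] == pytest.approx(p_hat, abs=1e-9)
            assert est.loc[m, "se"] == pytest.approx(
                binomial_se(p_hat, len(grp)), rel=1e-6
            )

    def test_constant_response_months_are_dropped(self):
        obs = _obs((12, 24, 36), (0.1, 0.0, 0.1), 200,
                   np.random.default_rng(2))
        model = fit_model(obs, ModelSpec())
        assert model.months == (12, 36)
        assert model.dropped_months == (24,)

    def test_fewer_than_two_informative_months_raises(self):
        obs = _obs((12,), (0.1,), 100, np.random.default_rng(3))
        with pytest.raises((FitError, ValueError), match="informative"):
            fit_model(obs, ModelSpec())

    def test_binomial_dispersion_rarely_triggers_on_true_binomial(self):
        quasi = 0
        for seed in range(100):
            obs = _obs((12, 24), (0.06, 0.05), 400,
                       np.random.default_rng(seed))
            model = fit_model(obs, ModelSpec())
            quasi += model.family == "quasi_binomial"
        assert quasi <= 5

    def test_quasi_scaling_widens_but_does_not_move_points(self):
        obs = _obs((12, 24), (0.07, 0.05), 500, np.random.default_rng(9))
        plain = fit_model(obs, ModelSpec(family="binomial"))
        quasi = fit_model(obs, ModelSpec(family="quasi_binomial"))
        assert np.allclose(plain.params, quasi.params)
        ratio = quasi.cov.to_numpy() / plain.cov.to_numpy()
        assert np.allclose(ratio, quasi.dispersion)

    def test_zero_effect_covariate_leaves_means_unchanged(self):
        rng = np.random.default_rng(21)
        obs = _obs((12, 24), (0.06, 0.05), 800, rng)
        obs["age"] = rng.normal(30.0, 8.0, len(obs))  # independent of worse
        plain = fit_model(obs, ModelSpec())
        with_cov = fit_model(obs, ModelSpec(covariates=("age",)))
        a = adjusted_means(plain).table["prob"].to_numpy()
        b = adjusted_means(with_cov, {"age": 30.0}).table["prob"].to_numpy()
        assert np.allclose(a, b, atol=0.01)

    def test_by_factor_model_refuses_adjusted_means(self):
        rng = np.random.default_rng(4)
        obs = _obs((12, 24), (0.06, 0.05), 300, rng)
        obs["drug"] = rng.choice(["INF", "GLA"], len(obs))
        model = fit_model(obs, ModelSpec(by="drug"))
        with pytest.raises(ValueError, match="single-arm"):
            adjusted_means(model)


@pytest.fixture(scope="module")
def r1_minus_table(published_panels):
    return arm_adjusted_table(published_panels[1], arms=("R1-",))


class TestPublishedValues:
    """Frozen published R1- adjusted means (covariate-free profile)."""

    # Published SE at month 12 prints as 0.0174 (truncated); the exact
    # binomial SE of 13/250 is 0.017455, matched at 1e-4 below.
    @pytest.mark.parametrize(
        "month, prob, se, lcl, ucl",
        [
            (12, 0.052, 0.0140, 0.0304, 0.0875),
            (24, 0.025, 0.0175, 0.0063, 0.0945),
        ],
    )
    def test_r1_minus_rows(self, r1_minus_table, month, prob, se, lcl, ucl):
        table = r1_minus_table
        row = table[(table["Arm"] == "R1-") & (table["Time"] == month)].iloc[0]
        assert row["Prob"] == pytest.approx(prob, abs=5e-4)
        assert row["SE"] == pytest.approx(se, abs=1e-4)
        assert row["Asymp.LCL"] == pytest.approx(lcl, abs=5e-4)
        assert row["Asymp.UCL"] == pytest.approx(ucl, abs=5e-4)

    def test_no_covariate_survives_in_constant_fixture(self, r1_minus_table):
        assert (r1_minus_table["Covariate"] == "none").all()


class TestTukeyGroups:
    def _fit(self, probs, n, seed=0):
        obs = _obs(
            tuple(12 * (i + 1) for i in range(len(probs))),
            probs, n, np.random.default_rng(seed),
        )
        return adjusted_means(fit_model(obs, ModelSpec()))

    def test_identical_months_share_a_letter(self):
        est = self._fit((0.05, 0.05, 0.05), 800, seed=1)
        letters = tukey_groups(est)
        assert set(letters) == {"a"}

    def test_clearly_different_months_get_distinct_letters(self):
        est = self._fit((0.02, 0.30), 1500, seed=2)
        letters = tukey_groups(est)
        assert len(set(letters)) == 2

    def test_bonferroni_at_least_as_conservative(self):
        est = self._fit((0.03, 0.06, 0.10), 700, seed=3)
        single = tukey_groups(est, method="single-step")
        bonf = tukey_groups(est, method="bonferroni")
        # Bonferroni can only merge groups relative to single-step.
        assert len(set(bonf)) <= len(set(single))

    def test_seed_determinism(self):
        est = self._fit((0.03, 0.05, 0.08, 0.04), 400, seed=4)
        assert tukey_groups(est, seed=7) == tukey_groups(est, seed=7)

    def test_compact_letters_bridge_pattern(self):
        # 0 differs from 1 and 2 but not 3; classic a / b / b / ab shape.
        letters = _compact_letters(4, [(0, 1), (0, 2)])
        assert letters[0] != letters[1]
        assert letters[1][-1] == letters[2][-1]
        shared = set(letters[0]) & set(letters[3])
        assert shared and set(letters[1]) & set(letters[3])


class TestComparePanels:
    def test_single_contrast_matches_chi2_scale(self, published_panels):
        obs = published_panels[1]
        out = compare_panels(obs, contrasts=[(("R1", 12), ("R0", 12))])
        assert len(out) == 1
        row = out.iloc[0]
        # oracle: Pearson chi-squared on the 2x2 table, same order of p
        r1 = obs.query("arm == 'R1' and month == 12")["worse"]
        r0 = obs.query("arm == 'R0' and month == 12")["worse"]
        table = [
            [int(r1.sum()), int(len(r1) - r1.sum())],
            [int(r0.sum()), int(len(r0) - r0.sum())],
        ]
        chi2_p = stats.chi2_contingency(table, correction=False)[1]
        assert row["p_unadjusted"] == pytest.approx(chi2_p, rel=0.2)
        assert row["significant"]
        assert row["log_odds_diff"] > 0  # relapse arm worsens more

    def test_published_default_family(self, published_panels):
        out = compare_panels(published_panels[1]).set_index(
            ["lhs_arm", "lhs_month", "rhs_arm", "rhs_month"]
        )
        assert out.loc[("R1", 12, "R0", 12), "significant"]
        assert out.loc[("R2", 24, "R1", 12), "significant"]
        assert out.loc[("R2", 24, "R1", 12), "p_adjusted"] < 0.05
        later = out.loc[("R2", 36, "R1", 24)]
        assert not later["significant"]

    def test_degenerate_cells_skipped_with_warning(self):
        rng = np.random.default_rng(6)
        obs = pd.DataFrame(
            {
                "arm": ["R0"] * 200 + ["R1"] * 50,
                "month": 12,
                "worse": list(rng.random(200) < 0.05) + [False] * 50,
                "pre_relapse": False,
            }
        )
        with pytest.warns(UserWarning, match="skipping"):
            out = compare_panels(obs, contrasts=[(("R1", 12), ("R0", 12))])
        assert out.empty

    def test_mirror_rows_are_not_double_counted(self, published_panels):
        obs = published_panels[1]
        no_mirror = obs[~obs["pre_relapse"]]
        a = compare_panels(obs, contrasts=[(("R1", 12), ("R0", 12))])
        b = compare_panels(no_mirror, contrasts=[(("R1", 12), ("R0", 12))])
        assert a["z"].iloc[0] == pytest.approx(b["z"].iloc[0], rel=1e-9)


def test_full_pipeline_table_has_expected_shape():
    registry = generate_registry(default_config(n_patients=1500), seed=8)
    _, obs = build_panel_table(registry)
    table = arm_adjusted_table(obs, arms=("R0", "R1"))
    assert set(table.columns) == {
        "Arm", "Time", "Covariate", "Prob", "SE",
        "Asymp.LCL", "Asymp.UCL", "Group",
    }
    assert (table["Prob"] > 0).all() and (table["Prob"] < 1).all()
    assert (table["Asymp.LCL"] < table["Prob"]).all()
    assert (table["Asymp.UCL"] > table["Prob"]).all()
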