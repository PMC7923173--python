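"""Worsening/progression probability estimation.

Per-arm probabilities of confirmed disability worsening are estimated two
ways that coincide when no covariates are used:

* raw per-month proportions with binomial standard errors
  ``sqrt(p(1-p)/n)`` and logit-scale Wald confidence limits, and
* logistic (binomial GLM, logit link) models with observation month as a
  categorical factor, optionally drug or treatment line (plus the two-way
  interaction) and patient covariates; adjusted means are the model's
  predicted probabilities at a fixed covariate reference profile.

Residual overdispersion (Pearson chi-squared / df above a threshold)
switches the variance model to quasi-binomial: point estimates are kept and
the coefficient covariance is scaled by the dispersion.  Post hoc pairwise
comparisons between months (or between panels) are multiplicity-adjusted
single-step over the contrast family using the joint normal distribution of
the contrast statistics (Tukey-style), and summarized as a compact letter
display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "ModelSpec",
    "FittedModel",
    "AdjustedMeans",
    "FitError",
    "raw_proportion",
    "binomial_se",
    "wald_ci_logit",
    "fit_model",
    "adjusted_means",
    "tukey_groups",
    "compare_panels",
    "arm_adjusted_table",
    "DEFAULT_PROFILE",
]

#: Covariate reference profile used for adjusted means.
DEFAULT_PROFILE = {"baseline_edss": 2.0, "age": 30.0, "sex": "female"}

#: Pearson dispersion above which the quasi-binomial variance model is used.
DISPERSION_THRESHOLD = 1.5

_PROFILE_LABELS = {"baseline_edss": "EDSS", "age": "Age", "sex": "Sex"}


class FitError(RuntimeError):
    """Model fitting failed (e.g. complete separation)."""


def raw_proportion(positives: int, n: int) -> float:
    """Observed worsening frequency ``positives / n``."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= positives <= n:
        raise ValueError("positives must lie in [0, n]")
    return positives / n


def binomial_se(p: float, n: int) -> float:
    """Binomial standard error ``sqrt(p (1 - p) / n)``."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return float(np.sqrt(p * (1.0 - p) / n))


def wald_ci_logit(
    p: float, se: float, level: float = 0.95
) -> tuple[float, float]:
    """Asymptotic confidence limits built on the logit scale.

    The probability-scale standard error is moved to the logit scale by the
    delta method (``se_logit = se / (p (1 - p))``), a symmetric Wald
    interval is formed there, and both limits are mapped back with the
    inverse logit — keeping the interval inside (0, 1) and asymmetric
    around small probabilities.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(
            f"degenerate proportion p={p}: logit-scale interval undefined"
        )
    if se < 0:
        raise ValueError("se must be non-negative")
    if se == 0:
        return (p, p)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se_logit = se / (p * (1.0 - p))
    eta = logit(p)
    return (float(expit(eta - z * se_logit)), float(expit(eta + z * se_logit)))


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, grouping factor and covariates.

    ``by`` optionally adds the drug or the treatment line (never both) as a
    factor, with its month interaction when ``interaction`` is set.  The
    observation month is always a categorical factor.
    """

    response: str = "worse"
    by: str | None = None  # None | "drug" | "treatment_line"
    interaction: bool = False
    covariates: tuple[str, ...] = ()
    family: str = "auto"  # "binomial" | "quasi_binomial" | "auto"
    dispersion_threshold: float = DISPERSION_THRESHOLD

    def formula(self) -> str:
        terms = ["C(month)"]
        if self.by is not None:
            if self.by not in ("drug", "treatment_line"):
                raise ValueError("by must be None, 'drug' or 'treatment_line'")
            terms.append(f"C({self.by})")
            if self.interaction:
                terms.append(f"C(month):C({self.by})")
        for cov in self.covariates:
            terms.append(f"C({cov})" if cov == "sex" else cov)
        return f"{self.response} ~ " + " + ".join(terms)


@dataclass
class FittedModel:
    """A fitted (quasi-)binomial logistic model for one observation table."""

    result: object
    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    dispersion: float
    family: str
    n_obs: int
    months: tuple[int, ...]
    dropped_months: tuple[int, ...]
    term_tests: pd.DataFrame = field(repr=False, default=None)

    @property
    def design_info(self):
        return self.result.model.data.design_info


def fit_model(observations: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Fit the logistic model of a per-evaluation observation table.

    Months at which the response is constant (all or no events) carry no
    information for a month-level log-odds and would separate the fit; they
    are excluded and recorded on the returned model.
    """
    data = observations.copy()
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} missing")
    data[spec.response] = data[spec.response].astype(int)

    by_month = data.groupby("month")[spec.response].agg(["mean"])
    constant = by_month.index[(by_month["mean"] <= 0) | (by_month["mean"] >= 1)]
    dropped = tuple(int(m) for m in constant)
    data = data[~data["month"].isin(constant)]
    months = tuple(int(m) for m in sorted(data["month"].unique()))
    if len(months) < 2:
        raise ValueError(
            f"need at least two informative months, have {months} "
            f"(dropped {dropped})"
        )
    model = sm.GLM.from_formula(
        spec.formula(), data=data, family=sm.families.Binomial()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit()
        except Exception as exc:  # statsmodels raises PerfectSeparationError
            raise FitError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(result.params)) or np.any(
        np.abs(result.params) > 30
    ):
        raise FitError(
            "complete or quasi-complete separation: coefficient(s) diverged "
            f"in {spec.formula()!r}"
        )

    dispersion = float(result.pearson_chi2 / result.df_resid)
    family = spec.family
    if family == "auto":
        family = (
            "quasi_binomial"
            if dispersion > spec.dispersion_threshold
            else "binomial"
        )
    cov = pd.DataFrame(
        result.cov_params(), index=result.params.index, columns=result.params.index
    )
    used_dispersion = 1.0
    if family == "quasi_binomial":
        cov = cov * dispersion
        used_dispersion = dispersion

    fitted = FittedModel(
        result=result,
        spec=spec,
        params=result.params,
        cov=cov,
        dispersion=used_dispersion,
        family=family,
        n_obs=int(result.nobs),
        months=months,
        dropped_months=dropped,
    )
    fitted.term_tests = _term_tests(fitted)
    return fitted


def _term_tests(model: FittedModel) -> pd.DataFrame:
    """Approximate chi-squared (Wald) test for each model term.

    Built directly from the (dispersion-scaled) covariance so that the
    quasi-binomial correction propagates into the term tests.
    """
    info = model.design_info
    rows = []
    beta = model.params.to_numpy()
    V = model.cov.to_numpy()
    for term, slc in info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(len(beta))[slc]
        b = beta[idx]
        Vb = V[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(Vb, b))
        except np.linalg.LinAlgError:
            chi2 = float(b @ np.linalg.pinv(Vb) @ b)
        df = len(idx)
        rows.append(
            {
                "term": term,
                "df": df,
                "chi2": chi2,
                "p_value": float(stats.chi2.sf(chi2, df)),
            }
        )
    return pd.DataFrame(rows, columns=["term", "df", "chi2", "p_value"])


@dataclass
class AdjustedMeans:
    """Adjusted (marginal) means at a covariate profile, one row per month."""

    table: pd.DataFrame
    eta: np.ndarray
    cov_eta: np.ndarray
    model: FittedModel
    profile: dict


def adjusted_means(
    model: FittedModel,
    profile: dict | None = None,
    level: float = 0.95,
) -> AdjustedMeans:
    """Model-predicted worsening probability per month at a fixed profile.

    The linear predictor at the profile is formed for every month level,
    its covariance taken from the coefficient covariance (L V L'), and the
    probability-scale SE obtained by the delta method
    ``se_p = p (1 - p) se_eta``; confidence limits are Wald on the logit
    scale, hence identical to :func:`wald_ci_logit` on ``(p, se_p)``.
    """
    profile = dict(DEFAULT_PROFILE if profile is None else profile)
    needed = set(model.spec.covariates)
    missing = needed - set(profile)
    if missing:
        raise ValueError(f"profile missing covariate(s): {sorted(missing)}")
    grid = {"month": list(model.months)}
    new = pd.DataFrame(grid)
    for cov_name in model.spec.covariates:
        new[cov_name] = profile[cov_name]
    if model.spec.by is not None:
        raise ValueError(
            "adjusted_means averages a single-arm model; marginalize the "
            "drug/line factor explicitly instead"
        )
    (L,) = patsy.build_design_matrices([model.design_info], new)
    L = np.asarray(L)
    beta = model.params.to_numpy()
    V = model.cov.to_numpy()
    eta = L @ beta
    cov_eta = L @ V @ L.T
    se_eta = np.sqrt(np.clip(np.diag(cov_eta), 0, None))
    prob = expit(eta)
    se_p = prob * (1 - prob) * se_eta
    z = stats.norm.ppf(0.5 + level / 2.0)
    lcl = expit(eta - z * se_eta)
    ucl = expit(eta + z * se_eta)
    table = pd.DataFrame(
        {
            "month": model.months,
            "prob": prob,
            "se": se_p,
            "lcl": lcl,
            "ucl": ucl,
        }
    )
    return AdjustedMeans(
        table=table, eta=eta, cov_eta=cov_eta, model=model, profile=profile
    )


def _single_step_pvalues(
    z_stats: np.ndarray, corr: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Single-step adjusted p-values over a family of correlated z tests.

    ``p_k = 1 - P(max_j |Z_j| <= |z_k|)`` with Z multivariate normal with
    the family's correlation matrix (the Tukey-style joint adjustment for
    all pairwise contrasts).  The rectangle probabilities are evaluated by
    quasi-Monte-Carlo with a fixed generator for reproducibility.
    """
    k = len(z_stats)
    if k == 1:
        return np.array([2 * stats.norm.sf(abs(z_stats[0]))])
    corr = np.asarray(corr, dtype=float)
    out = np.empty(k)
    for i, z in enumerate(np.abs(z_stats)):
        if not np.isfinite(z):
            out[i] = np.nan
            continue
        rng = np.random.default_rng(seed)
        inside = stats.multivariate_normal.cdf(
            np.full(k, z),
            mean=np.zeros(k),
            cov=corr,
            lower_limit=np.full(k, -z),
            allow_singular=True,
            maxpts=50_000,
            abseps=1e-4,
            releps=0.0,
            rng=rng,
        )
        out[i] = min(1.0, max(0.0, 1.0 - float(inside)))
        # never report below the unadjusted two-sided p
        out[i] = max(out[i], 2 * stats.norm.sf(z))
    return out


def _bonferroni_pvalues(z_stats: np.ndarray) -> np.ndarray:
    k = len(z_stats)
    return np.minimum(1.0, 2 * stats.norm.sf(np.abs(z_stats)) * k)


def _compact_letters(n: int, sig_pairs: list[tuple[int, int]]) -> list[str]:
    """Insert-and-absorb compact letter display.

    Items sharing a letter are not significantly different; every
    significant pair ends up in no common letter group.
    """
    columns: list[set[int]] = [set(range(n))]
    for i, j in sig_pairs:
        new_columns: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                new_columns.append(col - {i})
                new_columns.append(col - {j})
            else:
                new_columns.append(col)
        # absorb columns contained in another
        columns = [
            c
            for idx, c in enumerate(new_columns)
            if c
            and not any(
                c < other or (c == other and idx > jdx)
                for jdx, other in enumerate(new_columns)
            )
        ]
    columns.sort(key=lambda c: min(c))
    letters = "abcdefghijklmnopqrstuvwxyz"
    labels = ["" for _ in range(n)]
    for letter, col in zip(letters, columns):
        for item in col:
            labels[item] += letter
    return labels


def tukey_groups(
    estimates: AdjustedMeans,
    alpha: float = 0.05,
    method: str = "single-step",
    seed: int = 0,
) -> list[str]:
    """Compact letter display over all pairwise month comparisons.

    Contrasts are tested on the logit scale with single-step multiplicity
    adjustment (``method="bonferroni"`` for the conservative fallback).
    Returns one letter label per month, aligned with ``estimates.table``.
    """
    eta = estimates.eta
    V = estimates.cov_eta
    k = len(eta)
    if k == 1:
        return ["a"]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    diffs = np.array([eta[i] - eta[j] for i, j in pairs])
    var = np.array([V[i, i] + V[j, j] - 2 * V[i, j] for i, j in pairs])
    se = np.sqrt(np.clip(var, 1e-300, None))
    z = diffs / se
    # correlation of the contrast family
    C = np.zeros((len(pairs), len(eta)))
    for row, (i, j) in enumerate(pairs):
        C[row, i] = 1.0
        C[row, j] = -1.0
    cov_c = C @ V @ C.T
    d = np.sqrt(np.clip(np.diag(cov_c), 1e-300, None))
    corr = cov_c / np.outer(d, d)
    if method == "bonferroni":
        p_adj = _bonferroni_pvalues(z)
    else:
        p_adj = _single_step_pvalues(z, corr, seed=seed)
    sig = [pairs[m] for m in range(len(pairs)) if p_adj[m] < alpha]
    return _compact_letters(k, sig)


def compare_panels(
    observations: pd.DataFrame,
    contrasts: list[tuple[tuple[str, int], tuple[str, int]]] | None = None,
    response: str = "worse",
    alpha: float = 0.05,
    method: str = "single-step",
    seed: int = 0,
) -> pd.DataFrame:
    """Between-panel contrasts of worsening probability.

    A cell-means logistic model is fitted over (arm, month) cells and the
    requested contrasts tested with multiplicity adjustment over the
    family.  By default the family is R1-vs-R0 at every shared month plus
    the lagged R2-vs-R1 comparisons (R2 one year after its relapse against
    R1 one year after its own, e.g. R2 at 24 vs R1 at 12).  Contrasts whose
    cell is absent or carries a constant response are skipped with a
    warning.
    """
    data = observations[observations["arm"].isin(["R0", "R1", "R2"])].copy()
    if "pre_relapse" in data.columns:
        # the R2 arm's month-12 mirror duplicates R0 evaluations; keep the
        # originals only so no observation enters the model twice
        data = data[~data["pre_relapse"].astype(bool)]
    data[response] = data[response].astype(int)
    cell_stats = data.groupby(["arm", "month"])[response].agg(["size", "sum"])
    informative = cell_stats[
        (cell_stats["sum"] > 0) & (cell_stats["sum"] < cell_stats["size"])
    ].index
    usable = set(informative)

    if contrasts is None:
        contrasts = []
        months_by_arm = {
            arm: sorted(
                set(data.loc[data["arm"] == arm, "month"].astype(int))
            )
            for arm in ("R0", "R1", "R2")
        }
        for m in months_by_arm["R0"]:
            if m in months_by_arm["R1"]:
                contrasts.append((("R1", m), ("R0", m)))
        for m in months_by_arm["R2"]:
            if m - 12 in months_by_arm["R1"] and m >= 24:
                contrasts.append((("R2", m), ("R1", m - 12)))

    kept, skipped = [], []
    for a, b in contrasts:
        if tuple(a) in usable and tuple(b) in usable:
            kept.append((tuple(a), tuple(b)))
        else:
            skipped.append((a, b))
    if skipped:
        warnings.warn(
            f"skipping {len(skipped)} contrast(s) with absent or "
            f"degenerate cells: {skipped}",
            stacklevel=2,
        )
    if not kept:
        return pd.DataFrame(
            columns=[
                "lhs_arm", "lhs_month", "rhs_arm", "rhs_month",
                "log_odds_diff", "se", "z", "p_unadjusted", "p_adjusted",
                "significant",
            ]
        )

    cells = sorted(usable)
    data = data.set_index(["arm", "month"])
    data = data.loc[data.index.isin(usable)].reset_index()
    data["cell"] = (
        data["arm"].astype(str) + "@" + data["month"].astype(int).astype(str)
    )
    model = sm.GLM.from_formula(
        f"{response} ~ C(cell) - 1", data=data, family=sm.families.Binomial()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit()
    dispersion = float(result.pearson_chi2 / result.df_resid) if result.df_resid else 1.0
    V = np.asarray(result.cov_params())
    if dispersion > DISPERSION_THRESHOLD:
        V = V * dispersion
    names = list(result.params.index)

    def col(cell: tuple[str, int]) -> int:
        label = f"C(cell)[{cell[0]}@{int(cell[1])}]"
        return names.index(label)

    beta = result.params.to_numpy()
    C = np.zeros((len(kept), len(beta)))
    for row, (a, b) in enumerate(kept):
        C[row, col(a)] = 1.0
        C[row, col(b)] = -1.0
    est = C @ beta
    cov_c = C @ V @ C.T
    se = np.sqrt(np.clip(np.diag(cov_c), 1e-300, None))
    z = est / se
    p_un = 2 * stats.norm.sf(np.abs(z))
    if len(kept) == 1:
        p_adj = p_un.copy()
    elif method == "bonferroni":
        p_adj = _bonferroni_pvalues(z)
    else:
        d = np.sqrt(np.clip(np.diag(cov_c), 1e-300, None))
        corr = cov_c / np.outer(d, d)
        p_adj = _single_step_pvalues(z, corr, seed=seed)
    return pd.DataFrame(
        {
            "lhs_arm": [a[0] for a, _ in kept],
            "lhs_month": [a[1] for a, _ in kept],
            "rhs_arm": [b[0] for _, b in kept],
            "rhs_month": [b[1] for _, b in kept],
            "log_odds_diff": est,
            "se": se,
            "z": z,
            "p_unadjusted": p_un,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )


def _select_covariates(
    observations: pd.DataFrame,
    candidates: tuple[str, ...],
    response: str,
    alpha: float = 0.05,
) -> tuple[str, ...]:
    """Keep candidate covariates whose Wald chi-squared p < alpha in the
    full model; fall back to none if the full model cannot be fitted."""
    candidates = tuple(
        c
        for c in candidates
        if c in observations.columns and observations[c].nunique() > 1
    )
    if not candidates:
        return ()
    try:
        full = fit_model(
            observations,
            ModelSpec(response=response, covariates=tuple(candidates)),
        )
    except (FitError, ValueError):
        return ()
    tests = full.term_tests.set_index("term")["p_value"]
    kept = []
    for cov_name in candidates:
        term = f"C({cov_name})" if cov_name == "sex" else cov_name
        if term in tests.index and tests[term] < alpha:
            kept.append(cov_name)
    return tuple(kept)


def _covariate_label(covariates: tuple[str, ...], profile: dict) -> str:
    if not covariates:
        return "none"
    parts = []
    for cov_name in covariates:
        label = _PROFILE_LABELS.get(cov_name, cov_name)
        value = profile[cov_name]
        if isinstance(value, float) and value == int(value):
            value = int(value)
        parts.append(f"[{label} = {value}]")
    return " ".join(parts)


def arm_adjusted_table(
    observations: pd.DataFrame,
    arms: tuple[str, ...] = ("R1-", "R1+", "R0", "R0+MRI0", "R1", "R2"),
    response: str = "worse",
    profile: dict | None = None,
    candidates: tuple[str, ...] = ("baseline_edss", "age", "sex"),
    select: bool = True,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-arm adjusted means with Tukey letters (the published table shape).

    For each arm a logistic model in observation month is fitted, keeping
    the candidate covariates whose term test is significant; adjusted means
    at the reference profile, their SEs and logit-Wald limits and the
    compact letter display are reported with columns
    Arm, Time, Covariate, Prob, SE, Asymp.LCL, Asymp.UCL, Group.
    """
    profile = dict(DEFAULT_PROFILE if profile is None else profile)
    rows = []
    for arm in arms:
        sub = observations[observations["arm"] == arm]
        if sub.empty:
            continue
        kept = (
            _select_covariates(sub, candidates, response, alpha)
            if select
            else tuple(candidates)
        )
        try:
            model = fit_model(
                sub, ModelSpec(response=response, covariates=kept)
            )
        except (FitError, ValueError):
            if kept:  # covariate fit failed; retry covariate-free
                kept = ()
                try:
                    model = fit_model(sub, ModelSpec(response=response))
                except (FitError, ValueError):
                    continue
            else:
                continue
        est = adjusted_means(model, profile)
        letters = tukey_groups(est, alpha=alpha, seed=seed)
        label = _covariate_label(kept, profile)
        for (_, r), group in zip(est.table.iterrows(), letters):
            rows.append(
                {
                    "Arm": arm,
                    "Time": int(r["month"]),
                    "Covariate": label,
                    "Prob": r["prob"],
                    "SE": r["se"],
                    "Asymp.LCL": r["lcl"],
                    "Asymp.UCL": r["ucl"],
                    "Group": group,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "Arm", "Time", "Covariate", "Prob", "SE",
            "Asymp.LCL", "Asymp.UCL", "Group",
        ],
    )
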