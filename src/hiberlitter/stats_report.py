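"""Statistical battery: group comparisons, post hocs, count and mixed models,
AICc model selection and simple regression.

Conventions
-----------
* All tests are two-sided; the significance threshold used by reporting
  helpers is alpha = 0.05.
* Dispersion is reported as the standard error of the mean (s.e.m.).
* "auto" mode for group comparisons screens OLS residuals with Shapiro–Wilk
  and group variances with Levene at alpha = 0.05; both must pass for the
  parametric one-way F test, otherwise Kruskal–Wallis is used.
* AICc follows the R/MuMIn convention: for Gaussian models the residual
  variance counts as a parameter, so k = n_coefficients + 1 and
  AICc = AIC + 2k(k+1)/(n − k − 1).
* Marginal R² (Nakagawa) is the fixed-effect variance over the sum of
  fixed-effect, random-intercept and residual variances; for the Poisson
  family the residual term uses the lognormal approximation ln(1 + 1/λ̄).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .hibernation import sem
from .trace_io import ValidationError

__all__ = [
    "StatResult",
    "ModelRanking",
    "compare_groups",
    "posthoc",
    "count_model",
    "mixed_model",
    "aicc_rank",
    "simple_regression",
]

ALPHA = 0.05


@dataclass
class StatResult:
    test_name: str
    statistic_label: str  # one of F, H, U, z, chi2, t
    statistic_value: float
    df: tuple | float | None
    p_value: float
    effect_summary: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ModelRanking:
    table: pd.DataFrame  # columns: predictors, k, aic, aicc, delta_aicc, weight
    best_model: tuple[str, ...]


def _group_effect_summary(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": g,
                "n": len(v),
                "mean": float(np.mean(v)),
                "sem": sem(v),
            }
            for g, v in values_by_group.items()
        ]
    )


def _check_groups(values_by_group: Mapping[str, Sequence[float]]) -> None:
    if len(values_by_group) < 2:
        raise ValidationError("need at least 2 groups")
    for g, v in values_by_group.items():
        if len(v) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 values")


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    mode: str = "auto",
) -> StatResult:
    """One-way comparison of a numeric response across groups.

    ``parametric`` runs the one-way linear-model F test; ``nonparametric``
    runs Kruskal–Wallis with tie correction; ``auto`` applies the
    Shapiro+Levene screen described in the module docstring.
    """
    _check_groups(values_by_group)
    arrays = [np.asarray(v, dtype=float) for v in values_by_group.values()]

    if mode == "auto":
        resid = np.concatenate([a - a.mean() for a in arrays])
        normal_ok = stats.shapiro(resid).pvalue >= ALPHA if resid.size <= 5000 else True
        var_ok = stats.levene(*arrays).pvalue >= ALPHA
        mode = "parametric" if (normal_ok and var_ok) else "nonparametric"

    summary = _group_effect_summary(values_by_group)
    if mode == "parametric":
        if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
            # Zero variance everywhere: F is 0/0; report no evidence against the null.
            return StatResult("one-way lm", "F", 0.0, (len(arrays) - 1, sum(map(len, arrays)) - len(arrays)), 1.0, summary)
        f, p = stats.f_oneway(*arrays)
        df = (len(arrays) - 1, sum(a.size for a in arrays) - len(arrays))
        return StatResult("one-way lm", "F", float(f), df, float(p), summary)
    if mode == "nonparametric":
        if len({x for a in arrays for x in a}) == 1:
            return StatResult("Kruskal-Wallis", "H", 0.0, len(arrays) - 1, 1.0, summary)
        h, p = stats.kruskal(*arrays)
        return StatResult("Kruskal-Wallis", "H", float(h), len(arrays) - 1, float(p), summary)
    raise ValueError(f"unknown mode {mode!r}")


def _dunn_pvalues(
    values_by_group: Mapping[str, Sequence[float]], adjust: str = "holm"
) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests with tie correction.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) where
    T = Σ(t³ − t)/(12(N − 1)) over tie groups of the pooled sample.
    """
    groups = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], float) for g in groups])
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in groups:
        n = len(values_by_group[g])
        mean_ranks[g] = ranks[start : start + n].mean()
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": float(z), "p_unadjusted": float(p)})
    df = pd.DataFrame(rows)
    if adjust == "none":
        df["p_adjusted"] = df["p_unadjusted"]
    else:
        method = {"holm": "holm", "bonferroni": "bonferroni"}[adjust]
        df["p_adjusted"] = multipletests(df["p_unadjusted"], method=method)[1]
    return df


def posthoc(
    values_by_group: Mapping[str, Sequence[float]],
    family: str = "tukey",
    adjust: str = "holm",
) -> pd.DataFrame:
    """All pairwise comparisons after an omnibus test.

    ``tukey`` gives family-wise Tukey HSD p-values; ``dunn`` gives rank-based
    z tests with multiplicity adjustment (``holm`` default, also
    ``bonferroni`` or ``none``).
    """
    _check_groups(values_by_group)
    if family == "tukey":
        groups = list(values_by_group)
        res = stats.tukey_hsd(*[np.asarray(values_by_group[g], float) for g in groups])
        rows = [
            {
                "group_a": a,
                "group_b": b,
                "statistic": float(res.statistic[i, j]),
                "p_adjusted": float(res.pvalue[i, j]),
            }
            for (i, a), (j, b) in itertools.combinations(enumerate(groups), 2)
        ]
        return pd.DataFrame(rows)
    if family == "dunn":
        return _dunn_pvalues(values_by_group, adjust=adjust)
    raise ValueError(f"unknown post hoc family {family!r}")


def count_model(
    counts: Sequence[int],
    groups: Sequence[str],
    offset_log: Sequence[float] | None = None,
) -> StatResult:
    """Poisson GLM of counts on group, with a likelihood-ratio group test.

    Reports the LR chi² with k−1 df and per-group rate estimates ± s.e.m.
    (delta method on the log scale).  Degenerate designs (a group with a
    single observation leaves no residual information) raise instead of
    silently fitting.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    if counts.size != groups.size:
        raise ValidationError("counts and groups length mismatch")
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    sizes = {g: int(np.sum(groups == g)) for g in labels}
    if any(n < 2 for n in sizes.values()):
        raise ValidationError(f"degenerate design: group sizes {sizes} (need >= 2 per group)")

    dummies = pd.get_dummies(pd.Categorical(groups, categories=labels), drop_first=True).astype(float)
    x_full = sm.add_constant(dummies.to_numpy())
    offset = None if offset_log is None else np.asarray(offset_log, float)
    full = sm.GLM(counts, x_full, family=sm.families.Poisson(), offset=offset).fit()
    null = sm.GLM(counts, np.ones((counts.size, 1)), family=sm.families.Poisson(), offset=offset).fit()
    lr = 2.0 * (full.llf - null.llf)
    df = len(labels) - 1
    p = float(stats.chi2.sf(max(lr, 0.0), df))

    rows = []
    for g in labels:
        mask = groups == g
        rate = float(counts[mask].mean())
        rows.append({"group": g, "n": sizes[g], "rate": rate, "sem": sem(counts[mask])})
    return StatResult(
        test_name="Poisson GLM (LR test of group)",
        statistic_label="chi2",
        statistic_value=float(max(lr, 0.0)),
        df=df,
        p_value=p,
        effect_summary=pd.DataFrame(rows),
        extra={"coefficients": dict(zip(range(x_full.shape[1]), full.params))},
    )


def mixed_model(
    data: pd.DataFrame,
    response: str,
    covariate: str,
    group: str,
    family: str = "gaussian",
) -> StatResult:
    """Random-intercept mixed model ``response ~ covariate + (1 | group)``.

    Returns the covariate Wald test and Nakagawa's marginal R²
    (fixed-effect variance / (fixed + random-intercept + residual)).  The
    Gaussian family uses REML via MixedLM; the Poisson family uses a
    variational-Bayes fit with the lognormal residual-variance approximation
    on the log link (documented in ``extra['r2m_convention']``).
    """
    y = data[response].to_numpy(float)
    x = data[covariate].to_numpy(float)
    g = data[group]
    if family == "gaussian":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, sm.add_constant(x), groups=g)
            fit = model.fit(reml=True)
        slope = float(fit.fe_params[1])
        p = float(fit.pvalues[1])
        z = float(fit.tvalues[1])
        var_fixed = float(np.var(fit.fe_params[0] + slope * x))
        var_re = float(np.asarray(fit.cov_re)[0, 0])
        var_resid = float(fit.scale)
        denom = var_fixed + var_re + var_resid
        r2m = var_fixed / denom if denom > 0 else float("nan")
        return StatResult(
            test_name="linear mixed model (random intercept)",
            statistic_label="z",
            statistic_value=z,
            df=None,
            p_value=p,
            effect_summary=pd.DataFrame(
                [{"term": covariate, "estimate": slope, "se": float(fit.bse_fe[1])}]
            ),
            extra={
                "marginal_r2": r2m,
                "var_fixed": var_fixed,
                "var_random_intercept": var_re,
                "var_residual": var_resid,
                "r2m_convention": "gaussian: residual variance = REML scale",
            },
        )
    if family == "poisson":
        exog = sm.add_constant(x)
        groups_codes = pd.Categorical(g).codes
        exog_vc = pd.get_dummies(groups_codes).to_numpy(float)
        ident = np.zeros(exog_vc.shape[1], dtype=int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.PoissonBayesMixedGLM(y, exog, exog_vc, ident)
            fit = model.fit_vb()
        slope = float(fit.fe_mean[1])
        se = float(fit.fe_sd[1])
        z = slope / se if se > 0 else float("nan")
        p = float(2 * stats.norm.sf(abs(z)))
        var_fixed = float(np.var(fit.fe_mean[0] + slope * x))
        var_re = float(np.exp(fit.vcp_mean[0]) ** 2)
        lam = float(np.exp(np.mean(fit.fe_mean[0] + slope * x) + 0.5 * var_re))
        var_resid = float(np.log1p(1.0 / lam))  # lognormal approximation
        denom = var_fixed + var_re + var_resid
        r2m = var_fixed / denom if denom > 0 else float("nan")
        return StatResult(
            test_name="Poisson mixed model (random intercept, VB)",
            statistic_label="z",
            statistic_value=z,
            df=None,
            p_value=p,
            effect_summary=pd.DataFrame([{"term": covariate, "estimate": slope, "se": se}]),
            extra={
                "marginal_r2": r2m,
                "var_fixed": var_fixed,
                "var_random_intercept": var_re,
                "var_residual": var_resid,
                "r2m_convention": "poisson log link: residual variance = ln(1 + 1/lambda_bar)",
            },
        )
    raise ValueError(f"unknown family {family!r}")


def _gaussian_loglik(rss: float, n: int) -> float:
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def aicc_correction(k: int, n: int) -> float:
    """Small-sample AIC correction term 2k(k+1)/(n − k − 1)."""
    if n - k - 1 <= 0:
        return float("inf")
    return 2.0 * k * (k + 1) / (n - k - 1)


def aicc_rank(
    y: Sequence[float],
    predictors: pd.DataFrame,
    family: str = "gaussian",
) -> ModelRanking:
    """Rank every predictor subset (including the intercept-only model) by AICc.

    Gaussian subsets are fit by OLS with the closed-form ML log-likelihood;
    Poisson subsets use a GLM log-link fit.  k counts the intercept, the
    included predictors and (Gaussian only) the residual variance.  Akaike
    weights are normalized over all candidates.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    names = list(predictors.columns)
    if len(names) > 12:
        raise ValidationError("subset enumeration limited to 12 predictors")
    rows = []
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            x = sm.add_constant(predictors.loc[:, list(subset)].to_numpy(float), has_constant="add")
            if family == "gaussian":
                beta, *_ = np.linalg.lstsq(x, y, rcond=None)
                rss = float(np.sum((y - x @ beta) ** 2))
                ll = _gaussian_loglik(rss, n)
                k = x.shape[1] + 1  # + residual variance
            elif family == "poisson":
                fit = sm.GLM(y, x, family=sm.families.Poisson()).fit()
                ll = float(fit.llf)
                k = x.shape[1]
            else:
                raise ValueError(f"unknown family {family!r}")
            aic = -2.0 * ll + 2.0 * k
            rows.append({"predictors": subset, "k": k, "loglik": ll, "aic": aic,
                         "aicc": aic + aicc_correction(k, n)})
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    rel = np.exp(-0.5 * table["delta_aicc"].to_numpy())
    table["weight"] = rel / rel.sum()
    return ModelRanking(table=table, best_model=tuple(table["predictors"].iloc[0]))


def simple_regression(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """OLS of y on x: slope, R² and the slope t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("simple_regression needs >= 3 paired points")
    res = stats.linregress(x, y)
    return StatResult(
        test_name="simple linear regression",
        statistic_label="t",
        statistic_value=float(res.slope / res.stderr) if res.stderr > 0 else float("inf"),
        df=x.size - 2,
        p_value=float(res.pvalue),
        effect_summary=pd.DataFrame(
            [{"term": "slope", "estimate": float(res.slope), "se": float(res.stderr)}]
        ),
        extra={"r_squared": float(res.rvalue**2), "intercept": float(res.intercept)},
    )
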