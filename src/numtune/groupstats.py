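"""Group-level statistics for tuning-parameter summaries.

Covers four analyses downstream of the vertex-wise fits: linear
mixed-effects models of binned surface area or tuning width (preferred
numerosity and hemisphere as fixed effects, subject as a random
intercept); a categorical GLM control with one HRF regressor per
numerosity and the contrast "1-5 minus 20"; a vertex-wise one-sample
group t-test over contrast maps; and Bayesian Pearson correlations with
a uniform prior on [-1, 1], using the exact sampling distribution of the
correlation coefficient (appropriate at small n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import StimulusTimeline
from .forward import DEFAULT_DT, DEFAULT_T_REF, condition_indicators, volume_sample_indices

__all__ = [
    "lme_fit",
    "categorical_glm",
    "group_ttest",
    "bayes_correlation",
    "BayesCorrelationResult",
    "CONTRAST_SMALL_VS_BASELINE",
]

#: contrast "1-5 minus 20" over the six condition regressors (1,2,3,4,5,20)
CONTRAST_SMALL_VS_BASELINE = np.array([0.2, 0.2, 0.2, 0.2, 0.2, -1.0])


def lme_fit(table: pd.DataFrame, dv: str = "area_mm2") -> pd.DataFrame:
    """Mixed-effects model of a binned tuning summary.

    Fits ``dv ~ hemi + mu:hemi`` with a subject random intercept, i.e. a
    hemisphere offset and hemisphere-specific slopes of the dependent
    variable over preferred numerosity.  Requires columns ``subject``,
    ``hemi`` (L/R), ``mu`` (bin center) and the dependent variable.
    Returns a coefficient table with Wald z, p and 95 % CI.
    """
    for col in ("subject", "hemi", "mu", dv):
        if col not in table.columns:
            raise ValueError(f"long table is missing column {col!r}")
    if table["subject"].nunique() < 2:
        raise ValueError(
            "mixed model needs >= 2 subjects; with one subject the random "
            "intercept is unidentifiable (fit an ordinary regression instead)"
        )
    if table["hemi"].nunique() < 2:
        raise ValueError("both hemispheres must be present")
    if table.duplicated(["subject", "hemi", "mu"]).any():
        raise ValueError("duplicate (subject, hemi, bin) rows")

    import statsmodels.formula.api as smf

    formula = f"{dv} ~ C(hemi) + mu:C(hemi)"
    # degenerate (noise-free) data makes the mixed likelihood singular;
    # with zero residual/random variance the model reduces to OLS
    ols = smf.ols(formula, data=table).fit()
    if ols.mse_resid < 1e-12 * max(float(np.var(table[dv])), 1e-300):
        ci = ols.conf_int()
        return pd.DataFrame(
            {
                "term": list(ols.params.index),
                "estimate": ols.params.values,
                "z": ols.tvalues.values,
                "p": ols.pvalues.values,
                "ci_low": ci[0].values,
                "ci_high": ci[1].values,
            }
        )

    model = smf.mixedlm(formula, data=table, groups=table["subject"])
    fit = model.fit(reml=True, method="lbfgs")
    names = list(fit.fe_params.index)
    ci = fit.conf_int().loc[names]
    return pd.DataFrame(
        {
            "term": names,
            "estimate": fit.fe_params.values,
            "z": fit.tvalues.loc[names].values,
            "p": fit.pvalues.loc[names].values,
            "ci_low": ci[0].values,
            "ci_high": ci[1].values,
        }
    )


def categorical_glm(
    y,
    timeline: StimulusTimeline,
    confounds=None,
    hrf: np.ndarray | None = None,
    tr: float = 2.1,
    t_ref: float = DEFAULT_T_REF,
    dt: float = DEFAULT_DT,
    contrast: np.ndarray = CONTRAST_SMALL_VS_BASELINE,
):
    """Categorical GLM control: one convolved regressor per numerosity.

    Fits y on [intercept | six condition regressors | confounds] and
    returns (contrast estimate c'beta, full beta vector, condition levels).
    The default contrast tests small numerosities (1-5) against the
    20-dot baseline.
    """
    from .forward import canonical_hrf

    y = np.asarray(y, dtype=float)
    n_vol = y.size
    hrf = canonical_hrf() if hrf is None else np.asarray(hrf)
    span = max(timeline.span, (n_vol - 1) * tr + t_ref + dt)
    levels, indicators = condition_indicators(timeline, dt, span)
    if levels.size != contrast.size:
        raise ValueError(
            f"contrast has {contrast.size} weights but timeline has "
            f"{levels.size} numerosity levels"
        )
    idx = volume_sample_indices(dt, tr, n_vol, t_ref)
    regs = np.empty((n_vol, levels.size))
    for i in range(levels.size):
        conv = np.convolve(indicators[i], hrf)
        regs[:, i] = conv[np.minimum(idx, conv.size - 1)]
    X = [np.ones(n_vol), regs]
    if confounds is not None:
        X.append(np.asarray(confounds.matrix() if hasattr(confounds, "matrix") else confounds))
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("categorical design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    cond_beta = beta[1 : 1 + levels.size]
    return float(contrast @ cond_beta), beta, levels


def group_ttest(contrast_maps) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertex-wise one-sample t-test of contrast maps against zero.

    ``contrast_maps`` is subjects x vertices.  Returns (t, p_pos, p_neg):
    one-sided p-values for positive (small > baseline) and negative
    effects; df = n_subjects - 1.  Vertices with zero between-subject
    variance get NaN.
    """
    maps = np.atleast_2d(np.asarray(contrast_maps, dtype=float))
    n = maps.shape[0]
    if n < 2:
        raise ValueError("group t-test needs >= 2 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    t = np.full(mean.shape, np.nan)
    zero_var = sd <= 1e-300
    with np.errstate(invalid="ignore", divide="ignore"):
        t[~zero_var] = mean[~zero_var] / (sd[~zero_var] / np.sqrt(n))
    t[zero_var & (np.abs(mean) <= 1e-300)] = 0.0
    p_pos = stats.t.sf(t, n - 1)
    p_neg = stats.t.cdf(t, n - 1)
    return t, p_pos, p_neg


@dataclass
class BayesCorrelationResult:
    pearson_r: float
    posterior_median: float
    ci_low: float
    ci_high: float
    bf10: float
    n: int


def _r_density(r: float, rho: np.ndarray, n: int) -> np.ndarray:
    """Exact sampling density of the Pearson correlation r given the
    population correlation rho at sample size n (hypergeometric form)."""
    rho = np.asarray(rho, dtype=float)
    log_dens = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + (n - 1) / 2.0 * np.log1p(-(rho**2))
        + (n - 4) / 2.0 * np.log1p(-(r**2))
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)
    return np.exp(log_dens) * hyp


def bayes_correlation(
    x, y, grid_size: int = 4001, ci: float = 0.95
) -> BayesCorrelationResult:
    """Bayesian Pearson correlation with a uniform prior on [-1, 1].

    The posterior over the population correlation rho is proportional to
    the exact sampling density of the observed r times the flat prior,
    evaluated by numerical integration on a rho grid.  BF10 compares the
    marginal likelihood under the prior with the likelihood at rho = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n or n < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        med = 1.0 if r > 0 else -1.0
        return BayesCorrelationResult(r, med, med, med, np.inf, n)

    # open interval avoids the density's endpoint singularities
    rho = np.linspace(-1.0, 1.0, grid_size)[1:-1]
    like = _r_density(r, rho, n)
    norm = np.trapezoid(like, rho)
    marginal = norm / 2.0  # prior density is 1/2 on [-1, 1]
    bf10 = marginal / float(_r_density(r, np.array([0.0]), n)[0])

    post = like / norm
    cdf = np.concatenate([[0.0], np.cumsum((post[1:] + post[:-1]) / 2 * np.diff(rho))])
    cdf /= cdf[-1]
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    median = float(np.interp(0.5, cdf, rho))
    lo = float(np.interp(lo_q, cdf, rho))
    hi = float(np.interp(hi_q, cdf, rho))
    return BayesCorrelationResult(r, median, lo, hi, float(bf10), n)
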