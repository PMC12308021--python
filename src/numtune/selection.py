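"""Statistical selection of numerosity-tuned vertices.

Cross-validated variance explained is tested against zero with an F-test:
because tuning parameters are estimated on the independent half of the
data, the numerosity model has only p = 2 free parameters (beta0, beta)
against the intercept-only null, so

    F = (R^2 / (p - 1)) / ((1 - R^2) / (n - p)),   df = (p - 1, n - p)

with n = 145 scans per run.  Thresholds are Bonferroni-corrected for the
number of vertices per hemisphere; e.g. alpha = 0.05 with 100,000
vertices gives R^2* = 0.1625.  A vertex is numerosity-selective if it
additionally shows a positive scaling factor and a preferred numerosity
inside the presented range [1, 5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThresholdSpec",
    "f_from_r2",
    "r2_from_f",
    "r2_threshold",
    "select_vertices",
    "selection_summary",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Selection parameters for one hemisphere."""

    alpha: float = 0.05
    n_scans: int = 145
    n_params: int = 2
    n_vertices: int = 100_000
    mu_range: tuple = (1.0, 5.0)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_params < 2 or self.n_params >= self.n_scans:
            raise ValueError("need 2 <= n_params < n_scans")
        if self.n_vertices < 1:
            raise ValueError("n_vertices must be >= 1")

    @property
    def r2_threshold(self) -> float:
        return r2_threshold(self.alpha, self.n_scans, self.n_params, self.n_vertices)


def f_from_r2(r2, n: int, p: int):
    """F statistic of variance explained: (R^2/(p-1)) / ((1-R^2)/(n-p))."""
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 >= 1):
        raise ValueError("R^2 must be < 1")
    if p < 2 or n <= p:
        raise ValueError("need p >= 2 and n > p")
    out = (r2 / (p - 1)) / ((1.0 - r2) / (n - p))
    return float(out) if out.ndim == 0 else out


def r2_from_f(f, n: int, p: int):
    """Inverse of :func:`f_from_r2`."""
    f = np.asarray(f, dtype=float)
    out = (p - 1) * f / ((p - 1) * f + n - p)
    return float(out) if out.ndim == 0 else out


def r2_threshold(alpha: float, n: int, p: int, n_vertices: int) -> float:
    """Bonferroni-corrected variance-explained significance threshold.

    Inverts the F(p-1, n-p) quantile at 1 - alpha/n_vertices and maps it
    back to the R^2 scale.  Monotone decreasing in alpha, increasing in
    the number of vertices.
    """
    if n_vertices < 1:
        raise ValueError("n_vertices must be >= 1")
    level = alpha / n_vertices
    if level >= 1:
        raise ValueError("alpha/n_vertices must be < 1")
    f_crit = stats.f.ppf(1.0 - level, p - 1, n - p)
    return float(r2_from_f(f_crit, n, p))


def select_vertices(fits: pd.DataFrame, spec: ThresholdSpec) -> np.ndarray:
    """Numerosity-selective mask: beta > 0, mu in [1, 5], cvR^2 >= R^2*.

    NaN rows (masked vertices) never pass.
    """
    required = {"beta", "mu", "cv_r2"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fits table is missing columns: {sorted(missing)}")
    lo, hi = spec.mu_range
    beta_ok = fits["beta"].to_numpy() > 0
    mu_ok = (fits["mu"].to_numpy() >= lo) & (fits["mu"].to_numpy() <= hi)
    r2_ok = fits["cv_r2"].to_numpy() >= spec.r2_threshold
    return beta_ok & mu_ok & r2_ok


def selection_summary(fits: pd.DataFrame, spec: ThresholdSpec) -> dict:
    """Per-criterion counts, JSON-serializable."""
    lo, hi = spec.mu_range
    beta_ok = fits["beta"].to_numpy() > 0
    mu_ok = (fits["mu"].to_numpy() >= lo) & (fits["mu"].to_numpy() <= hi)
    r2_ok = fits["cv_r2"].to_numpy() >= spec.r2_threshold
    return {
        "n_vertices": int(len(fits)),
        "alpha": spec.alpha,
        "bonferroni_n": spec.n_vertices,
        "r2_threshold": spec.r2_threshold,
        "n_beta_positive": int(beta_ok.sum()),
        "n_mu_in_range": int(mu_ok.sum()),
        "n_r2_significant": int(r2_ok.sum()),
        "n_selected": int((beta_ok & mu_ok & r2_ok).sum()),
    }
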