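"""Topographic organization of preferred numerosity on the surface.

Two complementary summaries are computed over the numerosity-selective
vertex set:

* binned summaries over preferred numerosity (eight bins of width 0.5 on
  [1, 5]): cortical surface area per bin (triangles assigned by the mean
  preferred numerosity of their three vertices) and the mean/SEM of the
  FWHM tuning width per bin.  Across maps, surface area typically falls
  and tuning width grows with preferred numerosity.
* a coordinate-polynomial model of within-cluster topography: preferred
  numerosity regressed on powers (k = 1..d, default d = 5) of the
  mean-centered standard-space x, y, z coordinates (no cross terms),
  evaluated by 10-fold cross-validation; the correlation between actual
  and out-of-fold predicted numerosity (cv-r) quantifies topographic
  order, with a t-test on the correlation for significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .surface import SurfaceMesh

__all__ = [
    "NumerosityBins",
    "PolyTopoModel",
    "bin_by_mu",
    "area_mu_relation",
    "fwhm_mu_relation",
    "poly_topo_cv",
    "numerosity_range",
]


@dataclass
class NumerosityBins:
    """Binned area / tuning-width summaries over preferred numerosity."""

    edges: np.ndarray
    area_mm2: np.ndarray
    fwhm_mean: np.ndarray
    fwhm_sem: np.ndarray
    count: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    def to_frame(self, hemi: str = "L") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hemi": hemi,
                "bin_center": self.centers,
                "area_mm2": self.area_mm2,
                "fwhm_mean": self.fwhm_mean,
                "fwhm_sem": self.fwhm_sem,
                "n": self.count,
            }
        )


@dataclass
class PolyTopoModel:
    """Cross-validated coordinate-polynomial topography model."""

    degree: int
    intercept: float
    coefficients: np.ndarray  # 3*d values: [x^1..x^d, y^1..y^d, z^1..z^d]
    cv_r: float
    p_value: float
    n_vertices: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "intercept": self.intercept,
            "coefficients": list(map(float, self.coefficients)),
            "cv_r": self.cv_r,
            "p_value": self.p_value,
            "n_vertices": self.n_vertices,
            "seed": self.seed,
        }


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [a, b), last bin closed; -1 outside [edges[0], edges[-1]]."""
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[np.isclose(values, edges[-1])] = len(edges) - 2
    idx[(values < edges[0]) | (values > edges[-1])] = -1
    return idx


def bin_by_mu(
    mu: np.ndarray,
    fwhm: np.ndarray,
    mesh: SurfaceMesh,
    selected,
    width: float = 0.5,
    mu_range: tuple = (1.0, 5.0),
) -> NumerosityBins:
    """Bin selected vertices by preferred numerosity.

    Area per bin sums native triangle areas over triangles whose three
    vertices are all selected and whose vertex-average preferred
    numerosity falls in the bin.  FWHM mean and SEM are over selected
    vertices in the bin.  Bins are half-open [a, b) except the last,
    which includes its upper edge.
    """
    lo, hi = mu_range
    n_bins = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n_bins + 1)
    mu = np.asarray(mu, dtype=float)
    fwhm = np.asarray(fwhm, dtype=float)
    selected = np.asarray(selected, dtype=bool)

    count = np.zeros(n_bins, dtype=int)
    fwhm_mean = np.full(n_bins, np.nan)
    fwhm_sem = np.full(n_bins, np.nan)
    v_idx = _bin_index(mu[selected], edges)
    fw_sel = fwhm[selected]
    for b in range(n_bins):
        vals = fw_sel[v_idx == b]
        count[b] = vals.size
        if vals.size:
            fwhm_mean[b] = vals.mean()
        if vals.size >= 2:
            fwhm_sem[b] = vals.std(ddof=1) / np.sqrt(vals.size)

    area = np.zeros(n_bins)
    tri_ok = selected[mesh.triangles].all(axis=1)
    if tri_ok.any():
        tri_mu = mu[mesh.triangles[tri_ok]].mean(axis=1)
        tri_area = mesh.triangle_areas()[tri_ok]
        t_idx = _bin_index(tri_mu, edges)
        for b in range(n_bins):
            area[b] = tri_area[t_idx == b].sum()

    return NumerosityBins(edges, area, fwhm_mean, fwhm_sem, count)


def area_mu_relation(bins: NumerosityBins):
    """Pearson correlation and linear fit of bin area vs. bin center.

    Bins are included when they contain at least one vertex; their area
    may legitimately be zero (no fully-selected triangle).
    """
    ok = bins.count > 0
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-empty bins")
    x, y = bins.centers[ok], bins.area_mm2[ok]
    if np.allclose(y, y[0]):
        return 0.0, 0.0, float(y.mean())
    r = float(np.corrcoef(x, y)[0, 1])
    slope, intercept = np.polyfit(x, y, 1)
    return r, float(slope), float(intercept)


def fwhm_mu_relation(bins: NumerosityBins, order: int = 1):
    """Polynomial fit of per-bin mean FWHM on bin center.

    Returns (coefficients highest-power-first, R^2).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    ok = np.isfinite(bins.fwhm_mean)
    if ok.sum() < order + 2:
        raise ValueError(f"need at least {order + 2} non-empty bins for order {order}")
    x, y = bins.centers[ok], bins.fwhm_mean[ok]
    coefs = np.polyfit(x, y, order)
    pred = np.polyval(coefs, x)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return coefs, r2


def _poly_design(coords: np.ndarray, degree: int) -> np.ndarray:
    """[x^1..x^d | y^1..y^d | z^1..z^d] for mean-centered coords."""
    cols = [coords[:, ax] ** k for ax in range(3) for k in range(1, degree + 1)]
    return np.column_stack(cols)


def poly_topo_cv(
    coords_standard: np.ndarray,
    mu: np.ndarray,
    degree: int = 5,
    folds: int = 10,
    seed: int | None = 0,
) -> PolyTopoModel:
    """Coordinate-polynomial topography model with k-fold cross-validation.

    Coordinates are mean-centered within the cluster; regressors are the
    powers x^k, y^k, z^k for k = 1..degree (no interaction terms).  Folds
    are a seeded uniform partition; out-of-fold predictions are pooled
    and correlated with the actual preferred numerosities (cv-r), whose
    significance comes from the standard correlation t-test with
    n - 2 degrees of freedom.
    """
    coords = np.asarray(coords_standard, dtype=float)
    mu = np.asarray(mu, dtype=float)
    n = mu.size
    n_coef = 3 * degree
    if coords.shape != (n, 3):
        raise ValueError("coords must be n x 3 and match mu")
    if n < n_coef + 2:
        raise ValueError(f"need at least {n_coef + 2} vertices for degree {degree}")
    if np.allclose(mu, mu[0]):
        return PolyTopoModel(degree, float(mu[0]), np.zeros(n_coef), np.nan, np.nan, n, seed)

    coords = coords - coords.mean(axis=0)
    # per-column scaling for conditioning; scale-invariant predictions
    X = _poly_design(coords, degree)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    Xd = np.column_stack([np.ones(n), Xs])

    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(n) % folds
    pred = np.empty(n)
    for f in range(folds):
        test = fold_of == f
        if not test.any():
            continue
        coef, *_ = np.linalg.lstsq(Xd[~test], mu[~test], rcond=None)
        pred[test] = Xd[test] @ coef

    cv_r = float(np.corrcoef(mu, pred)[0, 1])
    t = cv_r * np.sqrt((n - 2) / max(1.0 - cv_r**2, 1e-15))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))

    coef_full, *_ = np.linalg.lstsq(Xd, mu, rcond=None)
    coefficients = coef_full[1:] / scale
    return PolyTopoModel(degree, float(coef_full[0]), coefficients, cv_r, p, n, seed)


def numerosity_range(mu_cluster) -> tuple[float, float]:
    """Min and max preferred numerosity represented in a cluster."""
    mu_cluster = np.asarray(mu_cluster, dtype=float)
    if mu_cluster.size == 0:
        raise ValueError("cluster is empty")
    return float(np.nanmin(mu_cluster)), float(np.nanmax(mu_cluster))
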