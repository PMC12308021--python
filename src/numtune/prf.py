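"""Grid-search maximum-likelihood estimation of numerosity tuning.

For every candidate (mu, sigma_log) on a dense grid, the predicted BOLD
signal is built by the forward model and the scaling parameters (beta,
beta0) are estimated by ordinary least squares; the Gaussian maximum
log-likelihood of each combination is then

    LL(mu, omega) = -n/2 * (ln(2 pi RSS / n) + 1),

so maximizing LL is equivalent to minimizing the residual sum of squares.
Cross-validated variance explained (cvR^2) comes from split-half
validation: tuning parameters fitted on one half of the runs generate the
predictor for the other half, where beta and beta0 are refit and the
coefficient of determination is computed; the two test R^2 values are
averaged.  Reported (mu, omega) estimates come from the all-runs-average
fit.

The module exposes low-level functions (:func:`ols_scaling`,
:func:`grid_fit`, :func:`crossval_fit`) and a model/results pair
(:class:`NumerosityPRF`, :class:`PRFResults`) wrapping the full
vertex-wise pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import signals as _signals
from .design import StimulusTimeline
from .forward import (
    DEFAULT_DT,
    DEFAULT_T_REF,
    HRFSpec,
    canonical_hrf,
    condition_indicators,
    volume_sample_indices,
)
from .tuning import FWHM_FACTOR, fwhm_from_sigma_log

__all__ = [
    "ParameterGrid",
    "VertexFit",
    "GridPredictions",
    "ols_scaling",
    "grid_fit",
    "crossval_fit",
    "NumerosityPRF",
    "PRFResults",
]


def gaussian_loglik(rss, n):
    """Maximum Gaussian log-likelihood given residual sum of squares."""
    rss = np.asarray(rss, dtype=float)
    with np.errstate(divide="ignore"):
        out = -n / 2.0 * (np.log(2.0 * np.pi * rss / n) + 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ParameterGrid:
    """Exhaustive search grid over tuning parameters.

    The default log-Gaussian grid covers preferred numerosity 0.8-5.2 in
    steps of 0.05 (89 values) and log-space width 0.05-3.0 in steps of
    0.05 (60 values), 5340 combinations.  For the linear tuning variant
    ``sigma`` holds linear-space SDs spanning the same FWHM range as the
    log grid evaluated at mu = 1.
    """

    mu: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.80, 5.2001, 0.05), 10)
    )
    sigma: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.05, 3.0001, 0.05), 10)
    )
    linear: bool = False

    def __post_init__(self):
        for name in ("mu", "sigma"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or v.size == 0 or np.any(np.diff(v) <= 0):
                raise ValueError(f"grid {name} values must be strictly increasing")
            object.__setattr__(self, name, v)

    @classmethod
    def linear_default(cls) -> "ParameterGrid":
        # sigma_lin grid spanning the same FWHM range as the log grid at mu=1
        log_grid = cls()
        omega = fwhm_from_sigma_log(1.0, log_grid.sigma)
        return cls(sigma=np.asarray(omega) / (2.0 * FWHM_FACTOR), linear=True)

    @property
    def n_combinations(self) -> int:
        return self.mu.size * self.sigma.size

    def combinations(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (mu, sigma) pairs, ordered by ascending sigma then mu.

        This ordering makes first-occurrence argmin/argmax tie-breaking
        deterministic: ties resolve toward sharper tuning (smaller
        sigma), then smaller preferred numerosity.
        """
        sig, mu = np.meshgrid(self.sigma, self.mu, indexing="ij")
        return mu.ravel(), sig.ravel()


@dataclass
class VertexFit:
    """Per-vertex tuning estimates and fit diagnostics."""

    mu_hat: float
    sigma_hat: float
    omega_hat: float
    beta_hat: float
    beta0_hat: float
    log_likelihood: float
    rss: float
    rss0: float
    cv_r2: float = np.nan

    @property
    def r2(self) -> float:
        """In-sample variance explained of the best-fitting combination."""
        return 1.0 - self.rss / self.rss0 if self.rss0 > 0 else np.nan


class GridPredictions:
    """Predicted BOLD time courses for every grid combination.

    Convolution is performed once per distinct numerosity level (the
    neuronal response is a tuning-weighted sum of per-level boxcars), so
    building all 5340 predictors costs six convolutions plus one matrix
    product.  Instances are reused across vertices and data halves.
    """

    def __init__(
        self,
        timeline: StimulusTimeline,
        grid: ParameterGrid | None = None,
        hrf: np.ndarray | None = None,
        tr: float = 2.1,
        n_volumes: int = 145,
        t_ref: float = DEFAULT_T_REF,
        dt: float = DEFAULT_DT,
        block_sustained: bool = False,
    ):
        self.grid = grid or ParameterGrid()
        self.tr = tr
        self.n_volumes = n_volumes
        hrf = canonical_hrf(HRFSpec(dt=dt)) if hrf is None else np.asarray(hrf)
        span = max(timeline.span, (n_volumes - 1) * tr + t_ref + dt)
        levels, indicators = condition_indicators(
            timeline, dt, span, block_sustained=block_sustained
        )
        idx = volume_sample_indices(dt, tr, n_volumes, t_ref)
        basis = np.empty((n_volumes, levels.size))
        for i in range(levels.size):
            conv = np.convolve(indicators[i], hrf)
            basis[:, i] = conv[np.minimum(idx, conv.size - 1)]
        mu_flat, sig_flat = self.grid.combinations()
        self.mu_flat, self.sigma_flat = mu_flat, sig_flat
        if self.grid.linear:
            z = (levels[:, None] - mu_flat[None, :]) / sig_flat[None, :]
        else:
            z = (np.log(levels)[:, None] - np.log(mu_flat)[None, :]) / sig_flat[None, :]
        weights = np.exp(-0.5 * z * z)
        #: n_volumes x n_combinations predictor matrix
        self.signals = basis @ weights
        self._s_mean = self.signals.mean(axis=0)
        self._s_centered = self.signals - self._s_mean
        self._s_ss = np.einsum("ij,ij->j", self._s_centered, self._s_centered)

    def omega(self) -> np.ndarray:
        if self.grid.linear:
            return 2.0 * FWHM_FACTOR * self.sigma_flat
        return fwhm_from_sigma_log(self.mu_flat, self.sigma_flat)


def ols_scaling(y, s):
    """OLS fit of y on [1, s]: returns (beta, beta0, rss, rss0, loglik).

    ``rss0`` is the residual sum of squares of the intercept-only model;
    ``loglik`` is the Gaussian maximum log-likelihood at the OLS solution.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    n = y.size
    if s.size != n:
        raise ValueError("y and s must have the same length")
    if n < 3:
        raise ValueError("need at least 3 samples")
    sc = s - s.mean()
    ss = sc @ sc
    if ss <= 1e-30:
        raise ValueError("predictor s is constant; scaling is not identifiable")
    yc = y - y.mean()
    beta = (yc @ sc) / ss
    beta0 = y.mean() - beta * s.mean()
    rss0 = float(yc @ yc)
    rss = float(max(rss0 - beta * (yc @ sc), 0.0))
    return float(beta), float(beta0), rss, rss0, gaussian_loglik(rss, n)


def _grid_rss(Y: np.ndarray, preds: GridPredictions):
    """Residual sums of squares for every vertex x grid combination.

    Returns ``(rss, rss0, cov)`` with rss of shape (V, C), using the
    closed-form simple-regression identity RSS = SS_y - cov^2 / SS_s.
    """
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ssy = np.einsum("ij,ij->i", Yc, Yc)
    cov = Yc @ preds._s_centered
    rss = np.maximum(ssy[:, None] - cov**2 / preds._s_ss[None, :], 0.0)
    return rss, ssy, cov


def _best_combination(Y: np.ndarray, preds: GridPredictions):
    """Vectorized argmin-RSS over the grid for each row of Y.

    Ties resolve to the first flat index, i.e. smallest sigma then
    smallest mu by the grid's combination ordering.
    """
    rss, ssy, cov = _grid_rss(Y, preds)
    best = np.argmin(rss, axis=1)
    rows = np.arange(Y.shape[0])
    beta = cov[rows, best] / preds._s_ss[best]
    beta0 = Y.mean(axis=1) - beta * preds._s_mean[best]
    return best, beta, beta0, rss[rows, best], ssy


def grid_fit(
    y_train,
    timeline: StimulusTimeline = None,
    grid: ParameterGrid | None = None,
    hrf: np.ndarray | None = None,
    tr: float = 2.1,
    n_volumes: int | None = None,
    predictions: GridPredictions | None = None,
) -> VertexFit:
    """Exhaustive grid search for one vertex series.

    Either a ``timeline`` (predictors built internally) or a prebuilt
    ``predictions`` object must be supplied.  Returns the combination
    maximizing the log-likelihood (equivalently minimizing RSS), with
    beta/beta0 from OLS at that combination.
    """
    y = np.asarray(y_train, dtype=float)
    if predictions is None:
        if timeline is None:
            raise ValueError("supply a timeline or a GridPredictions object")
        predictions = GridPredictions(
            timeline, grid=grid, hrf=hrf, tr=tr, n_volumes=n_volumes or y.size
        )
    if y.size != predictions.n_volumes:
        raise ValueError("training series length must equal n_volumes")
    if not np.all(np.isfinite(y)):
        return VertexFit(*([np.nan] * 8))
    best, beta, beta0, rss, ssy = _best_combination(y[None, :], predictions)
    b = int(best[0])
    return VertexFit(
        mu_hat=float(predictions.mu_flat[b]),
        sigma_hat=float(predictions.sigma_flat[b]),
        omega_hat=float(predictions.omega()[b]),
        beta_hat=float(beta[0]),
        beta0_hat=float(beta0[0]),
        log_likelihood=gaussian_loglik(rss[0], y.size),
        rss=float(rss[0]),
        rss0=float(ssy[0]),
    )


def _test_r2(Y_test: np.ndarray, preds: GridPredictions, best: np.ndarray):
    """R^2 on held-out data with beta, beta0 refit on the test series."""
    s = preds._s_centered[:, best].T  # V x T, centered columns
    ss = preds._s_ss[best]
    Yc = Y_test - Y_test.mean(axis=1, keepdims=True)
    ssy = np.einsum("ij,ij->i", Yc, Yc)
    cov = np.einsum("ij,ij->i", Yc, s)
    rss = np.maximum(ssy - cov**2 / ss, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 1.0 - rss / ssy


def crossval_fit(
    odd_mean,
    even_mean,
    timeline: StimulusTimeline = None,
    grid: ParameterGrid | None = None,
    hrf: np.ndarray | None = None,
    tr: float = 2.1,
    predictions: GridPredictions | None = None,
) -> VertexFit:
    """Split-half cross-validated fit for one vertex.

    Tuning parameters estimated on the odd-run average are evaluated on
    the even-run average (beta, beta0 refit there) and vice versa; cvR^2
    is the mean of the two test R^2 values.  The reported estimates come
    from the fit to the average of both halves (the all-runs average).
    """
    odd = np.asarray(odd_mean, dtype=float)
    even = np.asarray(even_mean, dtype=float)
    if odd.size != even.size:
        raise ValueError("both halves must have the same length")
    if predictions is None:
        if timeline is None:
            raise ValueError("supply a timeline or a GridPredictions object")
        predictions = GridPredictions(
            timeline, grid=grid, hrf=hrf, tr=tr, n_volumes=odd.size
        )
    if not (np.all(np.isfinite(odd)) and np.all(np.isfinite(even))):
        return VertexFit(*([np.nan] * 8), cv_r2=np.nan)
    fit = grid_fit((odd + even) / 2.0, predictions=predictions)
    best_odd, *_ = _best_combination(odd[None, :], predictions)
    best_even, *_ = _best_combination(even[None, :], predictions)
    r2_even = _test_r2(even[None, :], predictions, best_odd)[0]
    r2_odd = _test_r2(odd[None, :], predictions, best_even)[0]
    fit.cv_r2 = float((r2_even + r2_odd) / 2.0)
    return fit


# ---------------------------------------------------------------------------
# model / results interface


class NumerosityPRF:
    """Numerosity population receptive field model for a set of vertices.

    Parameters
    ----------
    runs : sequence of RunMatrix or 2-d arrays
        Per-run vertices x volumes signal matrices (same shape each run).
    timeline : StimulusTimeline
        Presentation events of one run (identical across runs).
    confounds : sequence of ConfoundSet, optional
        Per-run confound tables regressed out after percent-signal-change
        standardization.  If omitted the signals are assumed clean.
    grid : ParameterGrid, optional
    hrf_spec : HRFSpec, optional
    standardize : bool
        Apply percent signal change before confound regression (skip for
        signals already in percent units, e.g. simulated data).
    tuning : {"log", "linear"}
        Tuning-curve family; "linear" swaps in the linear-space Gaussian
        and its default grid.

    Examples
    --------
    >>> model = NumerosityPRF(runs, timeline)
    >>> res = model.fit()
    >>> res.frame[["mu", "fwhm", "cv_r2"]].head()
    """

    def __init__(
        self,
        runs,
        timeline: StimulusTimeline,
        confounds=None,
        grid: ParameterGrid | None = None,
        hrf_spec: HRFSpec | None = None,
        standardize: bool = True,
        tuning: str = "log",
        block_sustained: bool = False,
        t_ref: float = DEFAULT_T_REF,
        chunk_size: int = 2000,
    ):
        self.runs = [
            r if isinstance(r, _signals.RunMatrix) else _signals.RunMatrix(r)
            for r in runs
        ]
        if len({r.values.shape for r in self.runs}) != 1:
            raise ValueError("all runs must share one vertices x volumes shape")
        self.timeline = timeline
        self.confounds = list(confounds) if confounds is not None else None
        if self.confounds is not None and len(self.confounds) != len(self.runs):
            raise ValueError("need one confound table per run")
        if tuning not in ("log", "linear"):
            raise ValueError("tuning must be 'log' or 'linear'")
        if grid is None:
            grid = ParameterGrid.linear_default() if tuning == "linear" else ParameterGrid()
        self.grid = grid
        self.hrf_spec = hrf_spec or HRFSpec()
        self.standardize = standardize
        self.tuning = tuning
        self.block_sustained = block_sustained
        self.t_ref = t_ref
        self.chunk_size = chunk_size

    @classmethod
    def from_dataframes(cls, run_frames, events_frame: pd.DataFrame, **kwargs):
        """Build from pandas objects: one vertices x volumes DataFrame per
        run and a BIDS-style events table."""
        from .design import StimulusEvent

        events = [
            StimulusEvent(
                onset=float(r.onset),
                duration=float(r.duration),
                numerosity=float(r.trial_type),
                is_catch=bool(int(getattr(r, "catch", 0))),
            )
            for r in events_frame.itertuples()
        ]
        runs = [f.to_numpy(dtype=float) for f in run_frames]
        return cls(runs, StimulusTimeline(events), **kwargs)

    def _prepare(self):
        """PSC -> confound regression -> split-half / all-runs averages."""
        cleaned = []
        for i, run in enumerate(self.runs):
            r = _signals.percent_signal_change(run) if self.standardize else run
            if self.confounds is not None:
                r = _signals.regress_confounds(r, self.confounds[i])
            cleaned.append(r)
        return _signals.split_and_average(cleaned)

    def fit(self) -> "PRFResults":
        odd, even, allm = self._prepare()
        tr = self.runs[0].tr
        n_vol = self.runs[0].n_volumes
        preds = GridPredictions(
            self.timeline,
            grid=self.grid,
            hrf=canonical_hrf(self.hrf_spec),
            tr=tr,
            n_volumes=n_vol,
            t_ref=self.t_ref,
            dt=self.hrf_spec.dt,
            block_sustained=self.block_sustained,
        )
        V = allm.n_vertices
        cols = {
            k: np.full(V, np.nan)
            for k in (
                "mu",
                "sigma",
                "fwhm",
                "beta",
                "beta0",
                "log_likelihood",
                "rss",
                "rss0",
                "cv_r2",
            )
        }
        ok = allm.mask & np.isfinite(allm.values).all(axis=1)
        idx_ok = np.flatnonzero(ok)
        omega_flat = preds.omega()
        n = allm.n_volumes
        for start in range(0, idx_ok.size, self.chunk_size):
            sel = idx_ok[start : start + self.chunk_size]
            best, beta, beta0, rss, ssy = _best_combination(allm.values[sel], preds)
            cols["mu"][sel] = preds.mu_flat[best]
            cols["sigma"][sel] = preds.sigma_flat[best]
            cols["fwhm"][sel] = omega_flat[best]
            cols["beta"][sel] = beta
            cols["beta0"][sel] = beta0
            cols["rss"][sel] = rss
            cols["rss0"][sel] = ssy
            cols["log_likelihood"][sel] = gaussian_loglik(rss, n)
            best_odd, *_ = _best_combination(odd.values[sel], preds)
            best_even, *_ = _best_combination(even.values[sel], preds)
            r2_even = _test_r2(even.values[sel], preds, best_odd)
            r2_odd = _test_r2(odd.values[sel], preds, best_even)
            cols["cv_r2"][sel] = (r2_even + r2_odd) / 2.0
        frame = pd.DataFrame(cols)
        frame.insert(0, "vertex_id", np.arange(V))
        return PRFResults(self, frame, mask=ok)


class PRFResults:
    """Fitted vertex-wise tuning estimates.

    ``frame`` holds one row per vertex: preferred numerosity ``mu``,
    log-space width ``sigma``, linear FWHM ``fwhm``, scaling ``beta``,
    baseline ``beta0``, likelihood/RSS diagnostics and cross-validated
    variance explained ``cv_r2``.  Unanalyzable (masked) vertices carry
    NaN rows.
    """

    def __init__(self, model: NumerosityPRF, frame: pd.DataFrame, mask: np.ndarray):
        self.model = model
        self.frame = frame
        self.mask = np.asarray(mask, dtype=bool)

    @property
    def n_vertices(self) -> int:
        return len(self.frame)

    def select(self, threshold_spec=None, **kwargs) -> np.ndarray:
        """Numerosity-selective vertex mask (see :mod:`numtune.selection`)."""
        from .selection import ThresholdSpec, select_vertices

        spec = threshold_spec or ThresholdSpec(
            n_vertices=kwargs.pop("n_vertices", self.n_vertices), **kwargs
        )
        return select_vertices(self.frame, spec)

    def summary(self, threshold_spec=None) -> str:
        """Readable fit summary across analyzable vertices."""
        f = self.frame[self.mask]
        lines = [
            "Numerosity pRF grid-search fit",
            "=" * 38,
            f"vertices analyzed     {self.mask.sum()} / {self.n_vertices}",
            f"grid combinations     {self.model.grid.n_combinations}",
            f"tuning family         {self.model.tuning}-Gaussian",
            f"median cvR2           {f.cv_r2.median():.4f}",
            f"max cvR2              {f.cv_r2.max():.4f}",
            f"mu range (fitted)     [{f.mu.min():.2f}, {f.mu.max():.2f}]",
        ]
        if threshold_spec is not None:
            sel = self.select(threshold_spec)
            lines.append(f"selective vertices    {int(sel.sum())}")
        return "\n".join(lines)

    def to_tsv(self, path, hemi: str = "L", selected: np.ndarray | None = None):
        out = self.frame.rename(columns={"sigma": "sigma_log"}).copy()
        out.insert(1, "hemi", hemi)
        if selected is not None:
            out["selected"] = np.asarray(selected, dtype=int)
        out.to_csv(path, sep="\t", index=False)

    def plot_tuning(self, vertex_id: int, ax=None):
        """Plot the fitted tuning curve of one vertex over numerosity."""
        import matplotlib.pyplot as plt

        from .tuning import (
            LinearTuningParams,
            TuningParams,
            linear_gaussian_response,
            log_gaussian_response,
        )

        row = self.frame.iloc[vertex_id]
        x = np.linspace(0.5, 8, 200)
        if self.model.tuning == "linear":
            y = linear_gaussian_response(x, LinearTuningParams(row.mu, row.sigma))
        else:
            y = log_gaussian_response(x, TuningParams(row.mu, row.sigma))
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(x, y)
        ax.axvline(row.mu, ls="--", color="gray")
        ax.set(
            xlabel="numerosity",
            ylabel="normalized response",
            title=f"vertex {vertex_id}: mu={row.mu:.2f}, fwhm={row.fwhm:.2f}, "
            f"cvR2={row.cv_r2:.3f}",
        )
        return ax
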