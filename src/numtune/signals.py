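"""Signal standardization, confound regression, and split-half averaging.

Measured vertex time series are standardized to percent signal change,
cleaned by regressing out 12 confounds per run (six rigid-body motion
parameters; white-matter, CSF and global means; three discrete-cosine
drift regressors), then averaged across runs.  Split-half averages over
odd runs (1, 3, 5, 7) and even runs (2, 4, 6, 8) support cross-validated
model evaluation; the all-runs average is used for reported estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RunMatrix",
    "ConfoundSet",
    "MOTION_COLUMNS",
    "NUISANCE_COLUMNS",
    "percent_signal_change",
    "cosine_drift_regressors",
    "regress_confounds",
    "split_and_average",
    "read_signals_tsv",
    "write_signals_tsv",
    "read_confounds_tsv",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
NUISANCE_COLUMNS = ["white_matter", "csf", "global_signal"]


@dataclass
class RunMatrix:
    """Vertices x volumes signal matrix for one run.

    ``mask`` flags vertices that remain analyzable; vertices with zero
    temporal mean or non-finite values are masked out during percent
    signal change and propagated as missing downstream.
    """

    values: np.ndarray
    tr: float = 2.1
    run_index: int = 0
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.mask is None:
            self.mask = np.ones(self.values.shape[0], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.size != self.values.shape[0]:
                raise ValueError("mask length must equal vertex count")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass
class ConfoundSet:
    """Per-run confound matrix: 6 motion + WM/CSF/global + cosine drifts."""

    frame: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.frame, pd.DataFrame):
            self.frame = pd.DataFrame(np.asarray(self.frame))
        X = self.frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("confounds must be finite")
        design = np.column_stack([np.ones(X.shape[0]), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            bad = _collinear_columns(self.frame)
            raise ValueError(
                "confound matrix is rank deficient after adding an intercept; "
                f"collinear columns: {bad}"
            )

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


def _collinear_columns(frame: pd.DataFrame) -> list:
    """Name columns whose removal restores full rank (best effort)."""
    X = frame.to_numpy(dtype=float)
    base = np.column_stack([np.ones(X.shape[0]), X])
    full = np.linalg.matrix_rank(base)
    out = []
    for j, name in enumerate(frame.columns):
        reduced = np.delete(base, j + 1, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            out.append(str(name))
    return out


def percent_signal_change(run: RunMatrix) -> RunMatrix:
    """Map each vertex series to 100*(y - mean)/mean (temporal mean 0).

    Vertices with zero temporal mean or non-finite values cannot be
    standardized; they are set to NaN and masked out.
    """
    y = run.values
    mean = y.mean(axis=1, keepdims=True)
    ok = run.mask & np.isfinite(y).all(axis=1) & (np.abs(mean[:, 0]) > 1e-12)
    out = np.full_like(y, np.nan)
    out[ok] = 100.0 * (y[ok] - mean[ok]) / mean[ok]
    if not ok.all():
        import warnings

        warnings.warn(
            f"{int((~ok).sum())} vertices with zero/non-finite mean excluded "
            "from percent signal change",
            stacklevel=2,
        )
    return RunMatrix(out, tr=run.tr, run_index=run.run_index, mask=ok)


def cosine_drift_regressors(n_volumes: int, tr: float = 2.1, k: int = 3) -> np.ndarray:
    """Discrete cosine drift basis, excluding the constant term.

    Columns are ``c_j(t) = cos(pi * j * (2t + 1) / (2n))`` for j = 1..k
    (the DCT-II basis), which are mutually orthogonal and zero-mean.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n_volumes:
        raise ValueError(f"k={k} drift terms require more than {k} volumes")
    t = np.arange(n_volumes)
    j = np.arange(1, k + 1)
    return np.cos(np.pi * np.outer(2 * t + 1, j) / (2.0 * n_volumes))


def regress_confounds(run: RunMatrix, confounds: ConfoundSet) -> RunMatrix:
    """Residualize each vertex series against [intercept | confounds].

    Residuals are exactly orthogonal to every confound column and to the
    intercept (hence zero-mean).
    """
    if confounds.n_volumes != run.n_volumes:
        raise ValueError(
            f"confound rows ({confounds.n_volumes}) do not match "
            f"volumes ({run.n_volumes})"
        )
    X = np.column_stack([np.ones(run.n_volumes), confounds.matrix()])
    Y = run.values
    out = np.full_like(Y, np.nan)
    ok = run.mask & np.isfinite(Y).all(axis=1)
    coef, *_ = np.linalg.lstsq(X, Y[ok].T, rcond=None)
    out[ok] = (Y[ok].T - X @ coef).T
    return RunMatrix(out, tr=run.tr, run_index=run.run_index, mask=ok)


def split_and_average(runs) -> tuple[RunMatrix, RunMatrix, RunMatrix]:
    """Element-wise means over odd runs, even runs, and all runs.

    Odd/even refers to 1-based acquisition order: with 8 runs, odd =
    runs 1, 3, 5, 7 and even = runs 2, 4, 6, 8.  Vertices masked out in
    any run stay masked in every average.
    """
    runs = list(runs)
    if len(runs) < 2:
        raise ValueError("split-half averaging requires at least 2 runs")
    shape = runs[0].values.shape
    for r in runs[1:]:
        if r.values.shape != shape:
            raise ValueError("all runs must have identical shapes")
    mask = np.logical_and.reduce([r.mask for r in runs])
    stack = np.stack([r.values for r in runs])
    tr = runs[0].tr

    def _mean(sel) -> RunMatrix:
        return RunMatrix(stack[sel].mean(axis=0), tr=tr, mask=mask)

    odd = _mean(slice(0, None, 2))
    even = _mean(slice(1, None, 2))
    allm = _mean(slice(None))
    return odd, even, allm


def write_signals_tsv(run: RunMatrix, path) -> None:
    """Write a vertices x volumes matrix as headered TSV (columns vol_###)."""
    cols = [f"vol_{i:03d}" for i in range(run.n_volumes)]
    pd.DataFrame(run.values, columns=cols).to_csv(path, sep="\t", index=False)


def read_signals_tsv(path, tr: float = 2.1, run_index: int = 0) -> RunMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return RunMatrix(df.to_numpy(dtype=float), tr=tr, run_index=run_index)


def read_confounds_tsv(path, n_drift: int = 3, tr: float = 2.1) -> ConfoundSet:
    """Read an fMRIPrep-dialect confounds TSV and append cosine drifts.

    Expects the six motion columns (trans_x..rot_z) plus white_matter,
    csf and global_signal; the drift regressors are generated internally.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    wanted = MOTION_COLUMNS + NUISANCE_COLUMNS
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ValueError(f"confounds file {path} is missing columns: {missing}")
    out = df[wanted].copy()
    drifts = cosine_drift_regressors(len(df), tr=tr, k=n_drift)
    for j in range(n_drift):
        out[f"cosine{j:02d}"] = drifts[:, j]
    return ConfoundSet(out)
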