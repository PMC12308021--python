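"""Numerosity tuning functions and width conversions.

The primary tuning model is a Gaussian over the logarithm of numerosity:
a vertex's population responds with ``exp(-((ln x - ln mu)/sigma_log)^2/2)``
to ``x`` presented dots, peaking at the preferred numerosity ``mu``.  Tuning
width is reported as the full width at half maximum (FWHM, ``omega``) of
this curve in *linear* numerosity space,

    omega = exp(mu_log + sqrt(2 ln 2) * sigma_log)
          - exp(mu_log - sqrt(2 ln 2) * sigma_log)
          = 2 * mu * sinh(sqrt(2 ln 2) * sigma_log),

which is proportional to ``mu`` at fixed log-space width.  A linear-space
Gaussian variant is provided as an alternative model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuningParams",
    "LinearTuningParams",
    "log_gaussian_response",
    "linear_gaussian_response",
    "fwhm_from_sigma_log",
    "sigma_log_from_fwhm",
    "FWHM_FACTOR",
]

#: half-maximum half-width of a unit Gaussian: sqrt(2 ln 2)
FWHM_FACTOR = float(np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class TuningParams:
    """Log-Gaussian tuning: preferred numerosity and log-space width."""

    mu: float
    sigma_log: float

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError(f"preferred numerosity mu must be > 0, got {self.mu}")
        if self.sigma_log <= 0:
            raise ValueError(f"sigma_log must be > 0, got {self.sigma_log}")

    @property
    def mu_log(self) -> float:
        return float(np.log(self.mu))

    @property
    def omega(self) -> float:
        """FWHM tuning width in linear numerosity units."""
        return fwhm_from_sigma_log(self.mu, self.sigma_log)


@dataclass(frozen=True)
class LinearTuningParams:
    """Linear-space Gaussian tuning (alternative model)."""

    mu_lin: float
    sigma_lin: float

    def __post_init__(self):
        if self.sigma_lin <= 0:
            raise ValueError(f"sigma_lin must be > 0, got {self.sigma_lin}")

    @property
    def omega(self) -> float:
        return 2.0 * FWHM_FACTOR * self.sigma_lin


def log_gaussian_response(x, params: TuningParams):
    """Normalized neuronal response to numerosity ``x`` in (0, 1].

    Computes ``exp(-((ln x - ln mu) / sigma_log)^2 / 2)``; equals 1
    exactly when ``x == mu``.  Accepts scalars or arrays of numerosities.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("numerosity x must be > 0")
    z = (np.log(x) - np.log(params.mu)) / params.sigma_log
    out = np.exp(-0.5 * z * z)
    return float(out) if out.ndim == 0 else out


def linear_gaussian_response(x, params: LinearTuningParams):
    """Linear-space Gaussian response ``exp(-((x - mu_lin)/sigma_lin)^2/2)``."""
    x = np.asarray(x, dtype=float)
    z = (x - params.mu_lin) / params.sigma_lin
    out = np.exp(-0.5 * z * z)
    return float(out) if out.ndim == 0 else out


def fwhm_from_sigma_log(mu, sigma_log):
    """Linear-space FWHM of log-Gaussian tuning.

    The half-maximum crossings are at ``exp(ln mu +/- sqrt(2 ln 2) sigma_log)``,
    so the width is ``2 mu sinh(sqrt(2 ln 2) sigma_log)``.
    """
    mu = np.asarray(mu, dtype=float)
    sigma_log = np.asarray(sigma_log, dtype=float)
    if np.any(mu <= 0) or np.any(sigma_log <= 0):
        raise ValueError("mu and sigma_log must be > 0")
    out = 2.0 * mu * np.sinh(FWHM_FACTOR * sigma_log)
    return float(out) if out.ndim == 0 else out


def sigma_log_from_fwhm(mu, omega):
    """Invert :func:`fwhm_from_sigma_log`: log-space SD giving FWHM ``omega``
    at preferred numerosity ``mu``."""
    mu = np.asarray(mu, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if np.any(mu <= 0) or np.any(omega <= 0):
        raise ValueError("mu and omega must be > 0")
    out = np.arcsinh(omega / (2.0 * mu)) / FWHM_FACTOR
    return float(out) if out.ndim == 0 else out
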