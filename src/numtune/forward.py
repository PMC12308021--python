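"""Forward model: stimulus timeline + tuning parameters -> predicted BOLD.

The neuronal response z(t) is a boxcar train at microtime resolution:
during each dot presentation it equals the tuning-curve response to the
presented numerosity, zero during gaps and rest.  Convolution with the
canonical double-gamma HRF and sampling at volume acquisition times
yields the predicted signal s(t) entering the linear model
y = beta * s + beta0 + noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import StimulusTimeline
from .tuning import TuningParams, log_gaussian_response

__all__ = [
    "HRFSpec",
    "NeuronalTimecourse",
    "PredictedSignal",
    "canonical_hrf",
    "neuronal_timecourse",
    "predicted_bold",
    "DEFAULT_DT",
    "DEFAULT_T_REF",
]

#: microtime step (s); divides the 300 ms dot and 400 ms gap durations exactly
DEFAULT_DT = 0.05

#: volume sampling reference (s), matching slice-time correction to mid-acquisition
DEFAULT_T_REF = 1.025


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma hemodynamic response function parameters
    (SPM convention: 6 s response peak, 16 s undershoot, ratio 6)."""

    dt: float = DEFAULT_DT
    response_delay: float = 6.0
    undershoot_delay: float = 16.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    response_undershoot_ratio: float = 6.0
    length: float = 32.0

    def __post_init__(self):
        if self.dt <= 0 or self.length <= 0:
            raise ValueError("dt and length must be > 0")
        if min(
            self.response_delay,
            self.undershoot_delay,
            self.response_dispersion,
            self.undershoot_dispersion,
            self.response_undershoot_ratio,
        ) <= 0:
            raise ValueError("HRF shape parameters must be > 0")


@dataclass
class NeuronalTimecourse:
    """Stimulus-locked neuronal response on a uniform microtime grid."""

    values: np.ndarray
    dt: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("neuronal response values must lie in [0, 1]")

    @property
    def span(self) -> float:
        return self.values.size * self.dt


@dataclass
class PredictedSignal:
    """Model-predicted BOLD signal at volume acquisition times."""

    values: np.ndarray
    tr: float
    n_volumes: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_volumes:
            raise ValueError("signal length must equal n_volumes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("predicted signal must be finite")


def canonical_hrf(spec: HRFSpec | None = None) -> np.ndarray:
    """Sample the canonical double-gamma HRF on [0, length] at step dt.

    The kernel is the difference of two gamma densities (response minus
    undershoot/ratio), peak-normalized to 1 so that the scaling factor
    beta of the linear model carries percent-signal-change units.
    Returns ``floor(length/dt) + 1`` samples; the value at t=0 is 0.
    """
    spec = spec or HRFSpec()
    t = np.arange(int(np.floor(spec.length / spec.dt)) + 1) * spec.dt
    h = stats.gamma.pdf(
        t, spec.response_delay / spec.response_dispersion, scale=spec.response_dispersion
    ) - (
        stats.gamma.pdf(
            t,
            spec.undershoot_delay / spec.undershoot_dispersion,
            scale=spec.undershoot_dispersion,
        )
        / spec.response_undershoot_ratio
    )
    return h / h.max()


def _boxcar_indicator(
    timeline: StimulusTimeline, dt: float, span: float, mask=None
) -> np.ndarray:
    """0/1 microtime indicator of stimulus-on intervals (optionally masked
    to a subset of events)."""
    n = int(round(span / dt))
    box = np.zeros(n)
    for i, ev in enumerate(timeline):
        if mask is not None and not mask[i]:
            continue
        if ev.onset + ev.duration > span + 1e-9:
            raise ValueError(
                f"event at {ev.onset} s extends past the requested span {span} s"
            )
        i0 = int(round(ev.onset / dt))
        i1 = int(round((ev.onset + ev.duration) / dt))
        box[i0:i1] = 1.0
    return box


def condition_indicators(
    timeline: StimulusTimeline,
    dt: float,
    span: float,
    block_sustained: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-numerosity boxcar indicators.

    Returns ``(levels, indicators)`` where ``indicators[i]`` is the
    microtime 0/1 trace of all presentations of ``levels[i]``.  The
    neuronal timecourse for any tuning parameters is then a weighted sum
    of these indicators, which lets grid search precompute convolutions
    once per distinct numerosity instead of once per grid point.

    With ``block_sustained=True`` each presentation is extended to the
    onset of the next event of the same numerosity, so the response is
    held through within-block gaps.
    """
    source = timeline
    if block_sustained:
        from dataclasses import replace

        events = timeline.events
        extended = []
        for ev, nxt in zip(events, list(events[1:]) + [None]):
            end = ev.onset + ev.duration
            if nxt is not None and nxt.numerosity == ev.numerosity:
                end = nxt.onset
            extended.append(replace(ev, duration=end - ev.onset))
        source = StimulusTimeline(extended)
    nums = source.numerosities
    levels = np.unique(nums)
    if levels.size == 0:
        return levels, np.zeros((0, int(round(span / dt))))
    indicators = np.stack(
        [_boxcar_indicator(source, dt, span, mask=(nums == v)) for v in levels]
    )
    return levels, indicators


def neuronal_timecourse(
    timeline: StimulusTimeline,
    params: TuningParams,
    dt: float = DEFAULT_DT,
    span: float | None = None,
    block_sustained: bool = False,
) -> NeuronalTimecourse:
    """Tuning-weighted stimulus timecourse z(t) at microtime resolution.

    z(t) equals the log-Gaussian response to the numerosity presented at
    time t during each event, and 0 during gaps and rest.  With
    ``block_sustained=True`` the response is held through the 400 ms gaps
    within a block (each event extended to the onset of the next).
    """
    span = timeline.span if span is None else span
    levels, indicators = condition_indicators(
        timeline, dt, span, block_sustained=block_sustained
    )
    weights = log_gaussian_response(levels, params)
    return NeuronalTimecourse(weights @ indicators, dt)


def predicted_bold(
    z: NeuronalTimecourse,
    hrf: np.ndarray,
    tr: float,
    n_volumes: int,
    t_ref: float = DEFAULT_T_REF,
) -> PredictedSignal:
    """Convolve z with the HRF at microtime and sample at volume times
    ``t_k = k*TR + t_ref``."""
    if tr <= 0 or n_volumes <= 0:
        raise ValueError("tr and n_volumes must be > 0")
    s_micro = np.convolve(z.values, hrf)
    idx = volume_sample_indices(z.dt, tr, n_volumes, t_ref)
    idx = np.minimum(idx, s_micro.size - 1)
    return PredictedSignal(s_micro[idx], tr, n_volumes)


def volume_sample_indices(
    dt: float, tr: float, n_volumes: int, t_ref: float = DEFAULT_T_REF
) -> np.ndarray:
    """Microtime indices of the volume acquisition times."""
    t_k = np.arange(n_volumes) * tr + t_ref
    return np.round(t_k / dt).astype(int)
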