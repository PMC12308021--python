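"""Stimulus timeline construction and behavioral catch-trial scoring.

The blocked numerosity experiment presents dot arrays of 1-5 dots in
ascending then descending order, with long 20-dot baseline blocks after
each sweep.  One cycle is 1-2-3-4-5-20-5-4-3-2-1-20; each small-numerosity
block contains six 300 ms presentations separated by 400 ms gaps (4.2 s
per block), and each 20-dot block contains twenty-four presentations
(16.8 s).  Four cycles per run span 302.4 s, acquired in 145 volumes at
TR 2.1 s.  Ten percent of presentations are catch trials (white dots)
requiring a button press.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StimulusEvent",
    "DesignParams",
    "StimulusTimeline",
    "build_timeline",
    "assign_catch_trials",
    "score_detection",
    "read_events_tsv",
    "write_events_tsv",
]

#: numerosities shown in one stimulation cycle, in order
DEFAULT_CYCLE = (1, 2, 3, 4, 5, 20, 5, 4, 3, 2, 1, 20)

#: the large numerosity serving as the baseline condition
BASELINE_NUMEROSITY = 20


@dataclass(frozen=True)
class StimulusEvent:
    """A single dot-array presentation."""

    onset: float  # seconds from run start
    duration: float  # seconds
    numerosity: float  # dot count
    is_catch: bool = False

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"event duration must be > 0, got {self.duration}")
        if self.numerosity <= 0:
            raise ValueError(f"numerosity must be positive, got {self.numerosity}")


@dataclass(frozen=True)
class DesignParams:
    """Timing parameters of the blocked numerosity design.

    Defaults encode the study design: 300 ms dot presentations with
    400 ms gaps, six presentations per small-numerosity block (4.2 s),
    twenty-four per baseline block (16.8 s), four cycles per run,
    eight runs, 145 volumes at TR 2.1 s.
    """

    dot_on: float = 0.3
    gap: float = 0.4
    presentations_per_small_block: int = 6
    baseline_presentations: int = 24
    cycle: tuple = DEFAULT_CYCLE
    cycles_per_run: int = 4
    runs: int = 8
    tr: float = 2.1
    volumes_per_run: int = 145
    catch_rate: float = 0.10

    def __post_init__(self):
        if self.dot_on <= 0 or self.gap < 0:
            raise ValueError("dot_on must be > 0 and gap >= 0")
        if self.presentations_per_small_block < 1 or self.baseline_presentations < 1:
            raise ValueError("presentation counts must be >= 1")
        if self.cycles_per_run < 1 or self.runs < 1:
            raise ValueError("cycles_per_run and runs must be >= 1")
        if self.tr <= 0 or self.volumes_per_run < 1:
            raise ValueError("tr must be > 0 and volumes_per_run >= 1")
        if not 0 <= self.catch_rate < 1:
            raise ValueError("catch_rate must lie in [0, 1)")
        if self.cycles_per_run * self.cycle_duration > self.run_duration + 1e-9:
            raise ValueError(
                "stimulation does not fit in the acquisition: "
                f"{self.cycles_per_run} cycles x {self.cycle_duration} s "
                f"> {self.run_duration} s"
            )

    @property
    def soa(self) -> float:
        """Stimulus onset asynchrony (on + gap)."""
        return self.dot_on + self.gap

    @property
    def small_block_duration(self) -> float:
        return self.presentations_per_small_block * self.soa

    @property
    def baseline_block_duration(self) -> float:
        return self.baseline_presentations * self.soa

    @property
    def cycle_duration(self) -> float:
        n_small = sum(1 for v in self.cycle if v != BASELINE_NUMEROSITY)
        n_base = sum(1 for v in self.cycle if v == BASELINE_NUMEROSITY)
        return (
            n_small * self.small_block_duration + n_base * self.baseline_block_duration
        )

    @property
    def stimulation_span(self) -> float:
        """Total stimulated time per run, seconds."""
        return self.cycles_per_run * self.cycle_duration

    @property
    def run_duration(self) -> float:
        return self.volumes_per_run * self.tr


@dataclass
class StimulusTimeline:
    """Ordered, non-overlapping presentation events of one run."""

    events: list = field(default_factory=list)

    def __post_init__(self):
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.onset < prev.onset + prev.duration - 1e-12:
                raise ValueError("events must not overlap")

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events])

    @property
    def numerosities(self) -> np.ndarray:
        return np.array([e.numerosity for e in self.events])

    @property
    def catch_flags(self) -> np.ndarray:
        return np.array([e.is_catch for e in self.events], dtype=bool)

    @property
    def span(self) -> float:
        """End time of the last event's gap-less extent."""
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.onset + last.duration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": self.onsets,
                "duration": self.durations,
                "trial_type": [format(v, "g") for v in self.numerosities],
                "catch": self.catch_flags.astype(int),
            }
        )


def build_timeline(params: DesignParams | None = None) -> StimulusTimeline:
    """Construct the full presentation timeline of one run.

    Returns every individual dot-array presentation in temporal order.
    Small-numerosity blocks contribute ``presentations_per_small_block``
    events each, baseline (20-dot) blocks ``baseline_presentations``.
    """
    params = params or DesignParams()
    events = []
    t = 0.0
    for _ in range(params.cycles_per_run):
        for numerosity in params.cycle:
            if numerosity == BASELINE_NUMEROSITY:
                n_pres = params.baseline_presentations
            else:
                n_pres = params.presentations_per_small_block
            for i in range(n_pres):
                events.append(
                    StimulusEvent(
                        onset=t + i * params.soa,
                        duration=params.dot_on,
                        numerosity=float(numerosity),
                    )
                )
            t += n_pres * params.soa
    return StimulusTimeline(events)


def assign_catch_trials(
    timeline: StimulusTimeline, rate: float, seed: int
) -> StimulusTimeline:
    """Flag a seeded random subset of events as catch trials.

    Exactly ``round(rate * n_events)`` events are flagged, drawn
    uniformly without replacement.  Numerosities, onsets and event order
    are unchanged.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"catch rate must lie in [0, 1), got {rate}")
    n = len(timeline)
    n_catch = int(round(rate * n))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=n_catch, replace=False).tolist()) if n_catch else set()
    events = [
        replace(e, is_catch=(i in chosen)) for i, e in enumerate(timeline.events)
    ]
    return StimulusTimeline(events)


def score_detection(
    button_presses, timeline: StimulusTimeline, window: float = 1.5
) -> float:
    """Hit rate (%) for catch trials: a catch event counts as a hit if at
    least one button press falls within [onset, onset + window]."""
    if window <= 0:
        raise ValueError("response window must be > 0")
    presses = np.sort(np.asarray(button_presses, dtype=float))
    catch_onsets = [e.onset for e in timeline if e.is_catch]
    if not catch_onsets:
        raise ValueError("timeline contains no catch events; hit rate undefined")
    hits = 0
    for onset in catch_onsets:
        i = np.searchsorted(presses, onset, side="left")
        if i < presses.size and presses[i] <= onset + window:
            hits += 1
    return 100.0 * hits / len(catch_onsets)


def write_events_tsv(timeline: StimulusTimeline, path) -> None:
    """Write a BIDS-style events table (onset, duration, trial_type, catch)."""
    timeline.to_frame().to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> StimulusTimeline:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    events = [
        StimulusEvent(
            onset=float(row.onset),
            duration=float(row.duration),
            numerosity=float(row.trial_type),
            is_catch=bool(int(row.catch)) if "catch" in df.columns else False,
        )
        for row in df.itertuples()
    ]
    return StimulusTimeline(events)
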