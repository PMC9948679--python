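"""State-contingent stimulus gating.

Decides, frame by frame, whether a stimulus may be delivered.  The normal
contingency requires the background EMG of both the target and the
antagonist muscle to have stayed within configured ranges continuously for
a hold duration, and a minimum interval to have elapsed since the previous
stimulus.  Stimulus-test mode waives the range contingency and applies its
own (shorter) minimum interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .signal_core import BackgroundTrace

#: Tolerance for floating-point accumulation of elapsed time, seconds.
_TIME_EPS = 1e-9

#: Mode codes whose gating waives the range contingency.
STIMULUS_TEST_MODES = frozenset({"ST"})


@dataclass(frozen=True)
class RangeSpec:
    """Inclusive level range; a missing bound imposes no restriction."""

    low: Optional[float] = None
    high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ValueError("range low must not exceed high")

    def contains(self, level: float) -> bool:
        if level < 0:
            raise ValueError("background levels are non-negative")
        if self.low is not None and level < self.low:
            return False
        if self.high is not None and level > self.high:
            return False
        return True


def in_range(level: float, range_spec: RangeSpec) -> bool:
    """True iff low <= level <= high; blank bounds are unbounded."""
    return range_spec.contains(level)


@dataclass(frozen=True)
class TriggerConfig:
    """Contingency parameters for stimulus delivery.

    hold_duration_s is how long both muscles must stay in range
    continuously before a stimulus; min_interval_s is the minimum spacing
    between stimuli in normal modes, min_interval_stimulus_test_s the
    spacing used by stimulus-test mode.
    """

    target_range: RangeSpec = field(default_factory=RangeSpec)
    antagonist_range: RangeSpec = field(default_factory=RangeSpec)
    hold_duration_s: float = 2.0
    min_interval_s: float = 5.0
    min_interval_stimulus_test_s: float = 3.0

    def __post_init__(self) -> None:
        if self.hold_duration_s < 0:
            raise ValueError("hold_duration_s must be >= 0")
        if self.min_interval_s <= 0 or self.min_interval_stimulus_test_s <= 0:
            raise ValueError("minimum intervals must be positive")

    def min_interval_for(self, mode: str) -> float:
        if mode in STIMULUS_TEST_MODES:
            return self.min_interval_stimulus_test_s
        return self.min_interval_s


@dataclass
class TriggerState:
    """Elapsed-time bookkeeping between frames."""

    time_since_last_stimulus_s: float = math.inf
    in_range_elapsed_s: float = 0.0


@dataclass(frozen=True)
class StimulusEvent:
    """One delivered (or simulated) stimulus."""

    time_s: float
    intensity_mA: Optional[float] = None
    trial_index: int = 0


def step(
    state: TriggerState,
    level_target: float,
    level_antagonist: float,
    dt: float,
    config: TriggerConfig,
    mode: str = "CT",
    time_s: Optional[float] = None,
) -> tuple[TriggerState, Optional[StimulusEvent]]:
    """Advance the gate by one frame of duration dt.

    Returns the new state and a StimulusEvent if stimulation is permitted
    at the end of this frame.  ``time_s`` (time at frame end) is stamped
    onto the event; if omitted the event carries the accumulated
    time-since-last value, which is only meaningful relative to the
    previous stimulus.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if level_target < 0 or level_antagonist < 0:
        raise ValueError("background levels must be non-negative")

    since = state.time_since_last_stimulus_s + dt
    ok = config.target_range.contains(level_target) and config.antagonist_range.contains(
        level_antagonist
    )
    elapsed = state.in_range_elapsed_s + dt if ok else 0.0

    test_mode = mode in STIMULUS_TEST_MODES
    hold_met = test_mode or elapsed + _TIME_EPS >= config.hold_duration_s
    interval_met = since + _TIME_EPS >= config.min_interval_for(mode)

    if hold_met and interval_met:
        event = StimulusEvent(time_s=time_s if time_s is not None else since)
        return TriggerState(0.0, 0.0), event
    return TriggerState(since, elapsed), None


def _frames(duration_s: float, sample_rate: float) -> int:
    """Smallest frame count whose duration reaches duration_s."""
    return max(0, int(math.ceil(duration_s * sample_rate - 1e-6)))


def run_gate(
    trace_target: BackgroundTrace,
    trace_antagonist: BackgroundTrace,
    config: TriggerConfig,
    mode: str = "CT",
    start_time: float = 0.0,
) -> list[StimulusEvent]:
    """Batch gating over whole traces; equivalent to folding `step`.

    Implemented as a vectorized scan over in-range run lengths, in integer
    frames, for speed on long recordings; the frame-by-frame `step` is the
    behavioural reference.
    """
    t = np.asarray(trace_target.levels, dtype=float)
    a = np.asarray(trace_antagonist.levels, dtype=float)
    if t.shape != a.shape:
        raise ValueError("target and antagonist traces differ in length")
    if trace_target.sample_rate != trace_antagonist.sample_rate:
        raise ValueError("traces differ in sample rate")
    fs = trace_target.sample_rate
    n = t.size
    if n == 0:
        return []
    if np.any(t < 0) or np.any(a < 0):
        raise ValueError("background levels must be non-negative")

    if mode in STIMULUS_TEST_MODES:
        mask = np.ones(n, dtype=bool)
        hold_f = 0
    else:
        mask = mask_in_range(t, a, config)
        hold_f = _frames(config.hold_duration_s, fs)
    interval_f = _frames(config.min_interval_for(mode), fs)

    # Consecutive in-range run length ending at each frame.
    idx = np.arange(n)
    last_false = np.where(mask, -1, idx)
    np.maximum.accumulate(last_false, out=last_false)
    run_len = idx - last_false
    candidate = run_len >= hold_f  # all True when hold_f == 0

    # Fold semantics: an event fires at the end of frame i iff the in-range
    # time re-accumulated since the previous event (min(run_len[i], i - j)
    # frames, where j is the previous event frame) reaches the hold, and
    # i - j reaches the minimum interval; at run start only the hold applies.
    events: list[StimulusEvent] = []
    j: Optional[int] = None
    search_from = 0
    while search_from < n:
        if j is not None:
            search_from = max(search_from, j + max(interval_f, hold_f, 1))
            if search_from >= n:
                break
        hits = np.flatnonzero(candidate[search_from:])
        if hits.size == 0:
            break
        fe = search_from + int(hits[0])
        events.append(
            StimulusEvent(
                time_s=start_time + (fe + 1) / fs, trial_index=len(events) + 1
            )
        )
        j = fe
        search_from = fe + 1
    return events


def mask_in_range(
    levels_target: np.ndarray, levels_antagonist: np.ndarray, config: TriggerConfig
) -> np.ndarray:
    """Vectorized both-muscles-in-range predicate."""
    tr, ar = config.target_range, config.antagonist_range
    mask = np.ones(levels_target.shape, dtype=bool)
    if tr.low is not None:
        mask &= levels_target >= tr.low
    if tr.high is not None:
        mask &= levels_target <= tr.high
    if ar.low is not None:
        mask &= levels_antagonist >= ar.low
    if ar.high is not None:
        mask &= levels_antagonist <= ar.high
    return mask


class TriggerEngine:
    """Streaming gate that numbers trials and notifies a stimulator port.

    ``stimulator`` is any callable accepting a StimulusEvent; hardware or
    the virtual participant subscribes through it.
    """

    def __init__(
        self,
        config: TriggerConfig,
        mode: str = "CT",
        stimulator: Optional[Callable[[StimulusEvent], None]] = None,
    ):
        self.config = config
        self.mode = mode
        self.stimulator = stimulator
        self.state = TriggerState()
        self.events: list[StimulusEvent] = []
        self._time = 0.0

    def process_frame(
        self, level_target: float, level_antagonist: float, dt: float
    ) -> Optional[StimulusEvent]:
        self._time += dt
        self.state, event = step(
            self.state,
            level_target,
            level_antagonist,
            dt,
            self.config,
            self.mode,
            time_s=self._time,
        )
        if event is not None:
            event = replace(event, trial_index=len(self.events) + 1)
            self.events.append(event)
            if self.stimulator is not None:
                self.stimulator(event)
        return event
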