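"""Stimulus-locked epoch extraction and evoked-response quantification.

Each delivered stimulus yields an Epoch: a slice of the raw multichannel
signal around stimulus onset.  Within the post-stimulus span two analysis
windows are defined: the earlier *reference* window captures the M-wave
(direct motor response, used to verify constant effective stimulation) and
the later *target* window captures the H-reflex (the operantly conditioned
response).  Response size is either peak-to-peak or mean-rectified
amplitude of the windowed segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .signal_core import BackgroundTrace, DEFAULT_ROLES, ROLE_TARGET
from .trigger_engine import StimulusEvent

#: Size quantification methods.
METHOD_P2P = "peak_to_peak"
METHOD_MEAN_RECT = "mean_rectified"
_METHODS = (METHOD_P2P, METHOD_MEAN_RECT)

#: Default epoch span: covers soleus M-wave (~6-25 ms) and H-reflex
#: (~25-50 ms) latencies with pre-stimulus context.
DEFAULT_PRE_S = 0.050
DEFAULT_POST_S = 0.100


@dataclass(frozen=True)
class ResponseWindows:
    """Half-open [start, end) windows in ms post-stimulus.

    Defaults suit the soleus M-wave (reference) and H-reflex (target);
    they are meant to be adjusted per participant after inspecting the
    stimulus-locked overlay, then persisted.
    """

    reference_ms: tuple[float, float] = (6.0, 23.0)
    target_ms: tuple[float, float] = (28.0, 45.0)

    def __post_init__(self) -> None:
        r0, r1 = self.reference_ms
        t0, t1 = self.target_ms
        if not (0 <= r0 < r1 <= t0 < t1):
            raise ValueError(
                "windows must satisfy 0 <= ref.start < ref.end <= "
                "tgt.start < tgt.end"
            )


@dataclass
class Epoch:
    """Stimulus-locked waveform segment, one 1-D array per channel."""

    waveforms: np.ndarray  # channels x frames
    pre_s: float
    post_s: float
    sample_rate: float
    stimulus_event: StimulusEvent
    channel_roles: tuple[str, ...] = DEFAULT_ROLES
    background_at_trigger: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        expected = int(round((self.pre_s + self.post_s) * self.sample_rate))
        if self.waveforms.shape[-1] != expected:
            raise ValueError("waveform length inconsistent with pre/post span")

    @property
    def onset_index(self) -> int:
        """Frame index corresponding to stimulus onset (time 0)."""
        return int(round(self.pre_s * self.sample_rate))

    def channel(self, role: str) -> np.ndarray:
        return self.waveforms[self.channel_roles.index(role)]


@dataclass(frozen=True)
class ResponseSize:
    """A non-negative response amplitude with its method and window."""

    value: float
    method: str
    window: str  # "reference" | "target" | custom label

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("response size must be non-negative")


def extract_epoch(
    signals: np.ndarray,
    sample_rate: float,
    event: StimulusEvent,
    pre_s: float = DEFAULT_PRE_S,
    post_s: float = DEFAULT_POST_S,
    channel_roles: tuple[str, ...] = DEFAULT_ROLES,
    background: Optional[list[BackgroundTrace]] = None,
) -> Epoch:
    """Slice a stimulus-locked epoch out of a whole-run recording.

    ``signals`` is the full (channels x frames) run recording.  The sample
    at index round(pre_s * fs) of the epoch corresponds to stimulus onset.
    Events too close to the run edges are rejected with a diagnostic.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n = signals.shape[1]
    onset = int(round(event.time_s * sample_rate))
    pre_f = int(round(pre_s * sample_rate))
    span = int(round((pre_s + post_s) * sample_rate))
    start = onset - pre_f
    if start < 0 or start + span > n:
        raise ValueError(
            f"epoch for stimulus at {event.time_s:.4f}s extends outside the "
            f"recording ([{start}, {start + span}) of {n} frames)"
        )
    bg = None
    if background is not None:
        frame = min(onset, n - 1)
        bg = np.array([tr.levels[frame] for tr in background])
    return Epoch(
        waveforms=signals[:, start : start + span],
        pre_s=pre_s,
        post_s=post_s,
        sample_rate=sample_rate,
        stimulus_event=event,
        channel_roles=channel_roles,
        background_at_trigger=bg,
    )


def window_slice(epoch: Epoch, window_ms: tuple[float, float]) -> slice:
    """Frame slice for a half-open post-stimulus window in ms."""
    start_ms, end_ms = window_ms
    if start_ms < 0 or end_ms * 1e-3 > epoch.post_s + 1e-12:
        raise ValueError("window outside the epoch's post-stimulus span")
    fs = epoch.sample_rate
    lo = epoch.onset_index + int(np.floor(start_ms * fs / 1000.0))
    hi = epoch.onset_index + int(np.floor(end_ms * fs / 1000.0))
    if hi <= lo:
        raise ValueError("window empty after discretization")
    return slice(lo, hi)


def response_size(
    epoch: Epoch,
    window_ms: tuple[float, float],
    method: str = METHOD_P2P,
    role: str = ROLE_TARGET,
    window_label: str = "custom",
) -> ResponseSize:
    """Quantify the response in a post-stimulus window of one channel."""
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    seg = epoch.channel(role)[window_slice(epoch, window_ms)]
    if method == METHOD_P2P:
        value = float(np.max(seg) - np.min(seg))
    else:
        value = float(np.mean(np.abs(seg)))
    return ResponseSize(value=value, method=method, window=window_label)


def measure_trial(
    epoch: Epoch,
    windows: ResponseWindows,
    method: str = METHOD_P2P,
    role: str = ROLE_TARGET,
) -> tuple[ResponseSize, ResponseSize]:
    """Reference (M-wave) and target (H-reflex) sizes for one trial."""
    ref = response_size(epoch, windows.reference_ms, method, role, "reference")
    tgt = response_size(epoch, windows.target_ms, method, role, "target")
    return ref, tgt


def measure_run(
    signals: np.ndarray,
    sample_rate: float,
    events: list[StimulusEvent],
    windows: ResponseWindows,
    method: str = METHOD_P2P,
    pre_s: float = DEFAULT_PRE_S,
    post_s: float = DEFAULT_POST_S,
    channel_roles: tuple[str, ...] = DEFAULT_ROLES,
    background: Optional[list[BackgroundTrace]] = None,
) -> pd.DataFrame:
    """Per-trial measurement table for a whole run.

    Columns: trial, time_s, intensity_mA, reference_size, target_size,
    background_mV, success (filled later by the conditioning logic).
    Trials whose epochs fall outside the recording are dropped.
    """
    rows = []
    target_idx = channel_roles.index(ROLE_TARGET)
    for i, ev in enumerate(events, start=1):
        try:
            epoch = extract_epoch(
                signals, sample_rate, ev, pre_s, post_s, channel_roles, background
            )
        except ValueError:
            continue
        ref, tgt = measure_trial(epoch, windows, method)
        bg = (
            float(epoch.background_at_trigger[target_idx])
            if epoch.background_at_trigger is not None
            else np.nan
        )
        rows.append(
            {
                "trial": ev.trial_index if ev.trial_index else i,
                "time_s": ev.time_s,
                "intensity_mA": np.nan if ev.intensity_mA is None else ev.intensity_mA,
                "reference_size": ref.value,
                "target_size": tgt.value,
                "background_mV": bg,
                "success": pd.NA,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trial",
            "time_s",
            "intensity_mA",
            "reference_size",
            "target_size",
            "background_mV",
            "success",
        ],
    )
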