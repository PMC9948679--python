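"""Continuous background-EMG level estimation.

Converts raw multichannel EMG into per-channel background-activity traces:
causal high-pass filtering, full-wave rectification, and a trailing
sliding-window mean.  All stages are streaming-safe: processing a signal
block-by-block with carried filter state is bit-identical to processing the
concatenated signal in one shot, so the same code serves both online
triggering and offline reanalysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

#: Channel roles expected in a recording, in acquisition order.
ROLE_TARGET = "target"
ROLE_ANTAGONIST = "antagonist"
ROLE_TRIGGER = "trigger_loopback"
DEFAULT_ROLES = (ROLE_TARGET, ROLE_ANTAGONIST, ROLE_TRIGGER)

#: Default amplifier gain divided out so signals are millivolts at the skin.
DEFAULT_AMPLIFIER_GAIN = 500.0

#: Default processing block length; timing tolerances quantize to one block.
DEFAULT_BLOCK_S = 0.020


@dataclass(frozen=True)
class SignalConfig:
    """Parameters of the background-level pipeline.

    Attributes
    ----------
    sample_rate : float
        Acquisition rate in Hz.
    highpass_cutoff_hz : float
        Cutoff of the causal 2nd-order Butterworth high-pass that removes
        DC offset and motion artifact before rectification.
    background_window_s : float
        Length of the trailing averaging window, in seconds.
    """

    sample_rate: float = 2000.0
    highpass_cutoff_hz: float = 10.0
    background_window_s: float = 0.200

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0 < self.highpass_cutoff_hz < self.sample_rate / 2:
            raise ValueError("highpass_cutoff_hz must lie in (0, Nyquist)")
        if self.background_window_s <= 0:
            raise ValueError("background_window_s must be positive")
        if self.window_frames < 1:
            raise ValueError("background window shorter than one frame")

    @property
    def window_frames(self) -> int:
        return int(round(self.background_window_s * self.sample_rate))


@dataclass
class SampleBlock:
    """A chunk of raw multichannel signal (channels x frames, millivolts)."""

    samples: np.ndarray
    sample_rate: float
    channel_roles: tuple[str, ...] = DEFAULT_ROLES
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x frames)")
        if self.samples.shape[1] < 1:
            raise ValueError("block must contain at least one frame")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_frames(self) -> int:
        return self.samples.shape[1]


@dataclass
class BackgroundTrace:
    """Per-frame background level (mean rectified filtered EMG), millivolts."""

    levels: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1:
            raise ValueError("levels must be 1-D")


def _check_finite(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")


def highpass_coefficients(config: SignalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Butterworth high-pass (order 2) transfer-function coefficients."""
    return sps.butter(
        2, config.highpass_cutoff_hz, btype="highpass", fs=config.sample_rate
    )


def highpass(signal: np.ndarray, config: SignalConfig) -> np.ndarray:
    """Causal high-pass filter of a whole signal, starting from rest."""
    signal = np.asarray(signal, dtype=float)
    _check_finite(signal)
    b, a = highpass_coefficients(config)
    return sps.lfilter(b, a, signal)


def rectify(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(signal, dtype=float))


class SlidingMean:
    """Streaming trailing-window mean.

    The moving sum is a FIR filter with carried state, so block-wise
    processing is bit-identical to single-shot processing.  Frames earlier
    than one full window are averaged over the samples available so far.
    """

    def __init__(self, window_frames: int):
        if window_frames < 1:
            raise ValueError("window must span at least one frame")
        self.window_frames = int(window_frames)
        self._b = np.ones(self.window_frames)
        self._zi = np.zeros(self.window_frames - 1) if self.window_frames > 1 else None
        self._frames_seen = 0

    def process(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.window_frames == 1:
            self._frames_seen += x.size
            return x.copy()
        sums, self._zi = sps.lfilter(self._b, [1.0], x, zi=self._zi)
        idx = self._frames_seen + np.arange(1, x.size + 1)
        self._frames_seen += x.size
        return sums / np.minimum(idx, self.window_frames)


def sliding_mean(
    signal: np.ndarray, window_s: float, sample_rate: float
) -> BackgroundTrace:
    """Trailing-window mean of a whole signal."""
    n = int(round(window_s * sample_rate))
    if n < 1:
        raise ValueError("window_s * sample_rate must be >= 1")
    levels = SlidingMean(n).process(np.asarray(signal, dtype=float))
    return BackgroundTrace(levels=levels, sample_rate=sample_rate)


class ChannelPipeline:
    """highpass -> rectify -> sliding mean for one channel, with state."""

    def __init__(self, config: SignalConfig):
        self.config = config
        b, a = highpass_coefficients(config)
        self._b, self._a = b, a
        self._zi = np.zeros(max(len(a), len(b)) - 1)
        self._mean = SlidingMean(config.window_frames)

    def process(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        _check_finite(x)
        filtered, self._zi = sps.lfilter(self._b, self._a, x, zi=self._zi)
        return self._mean.process(np.abs(filtered))


class BackgroundProcessor:
    """Per-channel background-level pipeline over a stream of SampleBlocks."""

    def __init__(self, config: SignalConfig, n_channels: int):
        self.config = config
        self.n_channels = n_channels
        self._pipes = [ChannelPipeline(config) for _ in range(n_channels)]

    def process(self, block: SampleBlock) -> np.ndarray:
        """Return levels for this block, shaped (channels, frames)."""
        if block.n_channels != self.n_channels:
            raise ValueError(
                f"block has {block.n_channels} channels, expected {self.n_channels}"
            )
        return np.vstack([p.process(ch) for p, ch in zip(self._pipes, block.samples)])


def background_level(blocks, config: SignalConfig) -> list[BackgroundTrace]:
    """Background trace per channel for a stream of contiguous SampleBlocks."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("empty block stream")
    proc = BackgroundProcessor(config, blocks[0].n_channels)
    parts = [proc.process(b) for b in blocks]
    stacked = np.hstack(parts)
    return [
        BackgroundTrace(levels=stacked[c], sample_rate=config.sample_rate)
        for c in range(stacked.shape[0])
    ]


def blocks_from_array(
    samples: np.ndarray,
    sample_rate: float,
    block_s: float = DEFAULT_BLOCK_S,
    channel_roles: tuple[str, ...] = DEFAULT_ROLES,
) -> list[SampleBlock]:
    """Split a (channels x frames) array into contiguous SampleBlocks."""
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[1]
    step = max(1, int(round(block_s * sample_rate)))
    out = []
    for start in range(0, n, step):
        out.append(
            SampleBlock(
                samples=samples[:, start : start + step],
                sample_rate=sample_rate,
                channel_roles=channel_roles,
                start_time=start / sample_rate,
            )
        )
    return out
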