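"""Virtual participant: physiologically structured synthetic EMG.

The simulator stands in for the participant, amplifier and stimulator, so
the whole contingent-stimulation / conditioning pipeline can be exercised
closed-loop without hardware.  It emulates:

* ongoing background EMG: band-limited Gaussian noise (20-250 Hz) whose
  mean rectified level tracks a drive that relaxes (Ornstein-Uhlenbeck
  style) toward the level the participant is asked to hold, so in-range
  holds and occasional range exits both occur;
* stimulus-evoked responses: calibrated biphasic M-wave and H-reflex
  templates at fixed latencies, scaled by intensity-dependent recruitment
  -- the M-wave follows a logistic that rises then saturates, the
  H-reflex a logistic rise multiplied by a logistic collision suppression
  so it rises then falls;
* trial-to-trial variability: multiplicative Gaussian noise on response
  amplitudes;
* reinforcement-driven plasticity: a multiplicative H-reflex excitability
  state nudged on each rewarded trial.

The functional forms are modeling choices that reproduce the qualitative
recruitment shapes; every parameter is configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.special import expit

from . import response_analysis as ra
from . import run_analysis as rn
from .signal_core import (
    DEFAULT_BLOCK_S,
    DEFAULT_ROLES,
    SampleBlock,
    background_level,
    blocks_from_array,
)
from .session import (
    ModeCode,
    PlannedRun,
    ProtocolConfig,
    RunRecord,
    Session,
    SessionTemplate,
    start_or_continue_session,
)
from .trigger_engine import StimulusEvent, run_gate

#: Bounds on the multiplicative H-reflex excitability state.
EXCITABILITY_FLOOR = 0.2
EXCITABILITY_CEIL = 2.0

#: E|X| = sigma * sqrt(2/pi) for X ~ N(0, sigma^2); noise is scaled by the
#: inverse so its mean rectified value equals the requested drive.
_HALF_NORMAL_FACTOR = math.sqrt(math.pi / 2.0)


@dataclass
class VirtualParticipant:
    """Ground-truth parameters of the simulated physiology.

    Amplitudes are millivolts at the skin; intensities milliamps.  The
    default recruitment geometry places the H-reflex peak (~25 mA) on a
    near-complete logistic rise before collision suppression sets in, with
    a visible M-wave there, as in a typical soleus H-reflex setup.
    """

    m_max: float = 8.0
    h_max: float = 3.0
    i50_m: float = 30.0
    i50_h: float = 15.0
    i_collision: float = 35.0
    slope_m: float = 0.25
    slope_h: float = 0.5
    slope_c: float = 0.4
    latency_m_ms: float = 8.0
    latency_h_ms: float = 30.0
    duration_m_ms: float = 9.0
    duration_h_ms: float = 12.0
    background_drive: float = 0.05
    antagonist_drive: float = 0.01
    drive_noise: float = 0.2
    response_noise: float = 0.15
    plasticity_rate: float = 0.0
    h_excitability: float = 1.0

    def __post_init__(self) -> None:
        if min(self.m_max, self.h_max) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.latency_m_ms >= self.latency_h_ms:
            raise ValueError("M-wave latency must precede H-reflex latency")
        if self.h_excitability <= 0:
            raise ValueError("h_excitability must be positive")


def m_amplitude(intensity_mA: float, p: VirtualParticipant) -> float:
    """M-wave recruitment: logistic, rises then saturates at m_max."""
    return float(p.m_max * expit((np.asarray(intensity_mA) - p.i50_m) * p.slope_m))


def h_amplitude(intensity_mA: float, p: VirtualParticipant) -> float:
    """H-reflex recruitment: logistic rise suppressed at high intensity by
    antidromic collision, so the curve rises then falls; scaled by the
    current excitability state."""
    i = np.asarray(intensity_mA, dtype=float)
    rise = expit((i - p.i50_h) * p.slope_h)
    suppression = 1.0 - expit((i - p.i_collision) * p.slope_c)
    return float(p.h_excitability * p.h_max * rise * suppression)


def apply_reinforcement(
    p: VirtualParticipant, success: bool, direction: str
) -> VirtualParticipant:
    """Update H-reflex excitability after one rewarded trial.

    On success the excitability moves by plasticity_rate in the trained
    direction (down: multiplied by 1 - rate; up: by 1 + rate), clipped to
    [0.2, 2.0]; failures leave it unchanged.  Returns the updated
    participant (also mutated in place).
    """
    if success and p.plasticity_rate != 0.0:
        factor = (
            1.0 - p.plasticity_rate
            if direction == rn.DIRECTION_DOWN
            else 1.0 + p.plasticity_rate
        )
        p.h_excitability = float(
            np.clip(p.h_excitability * factor, EXCITABILITY_FLOOR, EXCITABILITY_CEIL)
        )
    return p


# --------------------------------------------------------------------------
# Waveform synthesis


def biphasic_template(duration_ms: float, sample_rate: float) -> np.ndarray:
    """Unit biphasic evoked-response template, calibrated to peak-to-peak 1.

    One sine cycle under a Hann envelope: starts and ends at zero, one
    positive and one negative lobe.
    """
    n = max(4, int(round(duration_ms * 1e-3 * sample_rate)))
    t = np.arange(n) / n
    w = np.sin(2 * np.pi * t) * np.sin(np.pi * t) ** 2
    return w / (w.max() - w.min())


def _bandlimited_unit_noise(
    n: int, sample_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise band-passed 20-250 Hz, normalized to unit sample SD."""
    white = rng.standard_normal(n)
    high = min(250.0, 0.45 * sample_rate)
    b, a = sps.butter(2, [20.0, high], btype="bandpass", fs=sample_rate)
    x = sps.lfilter(b, a, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _drive_trajectory(
    n_frames: int,
    sample_rate: float,
    mean_drive: float,
    relative_sd: float,
    rng: np.random.Generator,
    block_s: float = DEFAULT_BLOCK_S,
    relaxation_s: float = 0.5,
) -> np.ndarray:
    """Per-frame drive level: OU relaxation toward mean_drive.

    Simulated at block resolution and held constant within each block,
    which is how the participant's slow level adjustments look after
    200 ms smoothing anyway.
    """
    if relative_sd == 0 or mean_drive == 0:
        return np.full(n_frames, mean_drive)
    block_frames = max(1, int(round(block_s * sample_rate)))
    n_blocks = -(-n_frames // block_frames)
    theta = 1.0 / relaxation_s
    sigma = relative_sd * mean_drive * math.sqrt(2.0 * theta)
    d = np.empty(n_blocks)
    x = mean_drive
    sq = math.sqrt(block_s)
    eps = rng.standard_normal(n_blocks)
    for k in range(n_blocks):
        x += theta * (mean_drive - x) * block_s + sigma * sq * eps[k]
        x = max(x, 0.0)
        d[k] = x
    return np.repeat(d, block_frames)[:n_frames]


def synth_background(
    p: VirtualParticipant,
    duration_s: float,
    sample_rate: float,
    rng: np.random.Generator,
    drive_target: Optional[float] = None,
) -> np.ndarray:
    """Three-channel background signal (target, antagonist, silent loopback).

    The target channel's mean rectified level tracks the drive trajectory;
    the antagonist carries low-level stationary noise.
    """
    n = int(round(duration_s * sample_rate))
    mean_drive = p.background_drive if drive_target is None else drive_target
    drive = _drive_trajectory(n, sample_rate, mean_drive, p.drive_noise, rng)
    target = _bandlimited_unit_noise(n, sample_rate, rng) * drive * _HALF_NORMAL_FACTOR
    if p.antagonist_drive > 0:
        antagonist = (
            _bandlimited_unit_noise(n, sample_rate, rng)
            * p.antagonist_drive
            * _HALF_NORMAL_FACTOR
        )
    else:
        antagonist = np.zeros(n)
    return np.vstack([target, antagonist, np.zeros(n)])


def inject_response(
    signals: np.ndarray,
    sample_rate: float,
    event_frame: int,
    m_amp: float,
    h_amp: float,
    p: VirtualParticipant,
    loopback_amplitude: float = 5.0,
) -> None:
    """Add calibrated M/H templates and a loopback pulse at one stimulus.

    Templates are calibrated so the peak-to-peak of the injected waveform
    equals the requested amplitude exactly.
    """
    fs = sample_rate
    for amp, latency_ms, dur_ms in (
        (m_amp, p.latency_m_ms, p.duration_m_ms),
        (h_amp, p.latency_h_ms, p.duration_h_ms),
    ):
        tpl = biphasic_template(dur_ms, fs) * amp
        start = event_frame + int(round(latency_ms * 1e-3 * fs))
        end = min(start + tpl.size, signals.shape[1])
        if end > start:
            signals[0, start:end] += tpl[: end - start]
    pulse_len = max(1, int(round(1e-3 * fs)))
    end = min(event_frame + pulse_len, signals.shape[1])
    signals[2, event_frame:end] += loopback_amplitude


def synth_continuous(
    p: VirtualParticipant,
    events: Sequence[tuple[float, float]],
    duration_s: float,
    sample_rate: float,
    rng: np.random.Generator,
    block_s: float = DEFAULT_BLOCK_S,
    drive_target: Optional[float] = None,
) -> list[SampleBlock]:
    """Open-loop synthesis: background plus evoked responses at the given
    (time_s, intensity_mA) events, as a contiguous SampleBlock stream."""
    times = [t for t, _ in events]
    if any(t < 0 or t > duration_s for t in times):
        raise ValueError("events must lie within the synthesized duration")
    if any(
        b - a < ra.DEFAULT_POST_S for a, b in zip(times, times[1:])
    ):
        warnings.warn("stimulus events closer than the epoch span overlap", stacklevel=2)
    signals = synth_background(p, duration_s, sample_rate, rng, drive_target)
    for t, intensity in events:
        m_amp = m_amplitude(intensity, p)
        h_amp = h_amplitude(intensity, p)
        if p.response_noise > 0:
            m_amp = max(0.0, m_amp * (1.0 + p.response_noise * rng.standard_normal()))
            h_amp = max(0.0, h_amp * (1.0 + p.response_noise * rng.standard_normal()))
        inject_response(signals, sample_rate, int(round(t * sample_rate)), m_amp, h_amp, p)
    return blocks_from_array(signals, sample_rate, block_s)


# --------------------------------------------------------------------------
# Trial-level sweep synthesis (fast path for recruitment studies)


def simulate_sweep_epochs(
    p: VirtualParticipant,
    intensities: Sequence[float],
    trials_per_intensity: int,
    cfg: ProtocolConfig,
    rng: np.random.Generator,
):
    """Recruitment sweep as independent stimulus-locked epochs.

    Yields (intensity, Epoch) per trial; each epoch carries background
    noise plus noisy evoked templates, and is measured downstream exactly
    like a slice of a continuous recording.
    """
    fs = cfg.signal.sample_rate
    pre, post = ra.DEFAULT_PRE_S, ra.DEFAULT_POST_S
    span = pre + post
    out = []
    trial = 0
    for intensity in intensities:
        for _ in range(trials_per_intensity):
            trial += 1
            signals = synth_background(p, span + 2 / fs, fs, rng)
            m_amp = m_amplitude(intensity, p)
            h_amp = h_amplitude(intensity, p)
            if p.response_noise > 0:
                m_amp = max(0.0, m_amp * (1 + p.response_noise * rng.standard_normal()))
                h_amp = max(0.0, h_amp * (1 + p.response_noise * rng.standard_normal()))
            onset = int(round(pre * fs))
            inject_response(signals, fs, onset, m_amp, h_amp, p)
            event = StimulusEvent(time_s=pre, intensity_mA=intensity, trial_index=trial)
            epoch = ra.extract_epoch(signals, fs, event, pre, post)
            out.append((intensity, epoch))
    return out


def simulate_recruitment_table(
    p: VirtualParticipant,
    cfg: ProtocolConfig,
    rng: np.random.Generator,
):
    """Measured trial table for a full recruitment sweep, using the
    intensity schedule from the protocol config."""
    import pandas as pd

    intensities = cfg.rc_intensities()
    rows = []
    for intensity, epoch in simulate_sweep_epochs(
        p, intensities, cfg.rc_trials_per_intensity, cfg, rng
    ):
        ref, tgt = ra.measure_trial(epoch, cfg.windows, cfg.method)
        rows.append(
            {
                "trial": epoch.stimulus_event.trial_index,
                "time_s": epoch.stimulus_event.time_s,
                "intensity_mA": intensity,
                "reference_size": ref.value,
                "target_size": tgt.value,
                "background_mV": np.nan,
                "success": pd.NA,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Closed-loop simulation


@dataclass
class SimulatedRun:
    """In-memory result of one closed-loop run."""

    record: RunRecord
    planned: PlannedRun


def _simulate_contingent_run(
    p: VirtualParticipant,
    planned: PlannedRun,
    cfg: ProtocolConfig,
    rng: np.random.Generator,
    criterion: Optional[rn.ConditioningCriterion],
    run_number: int,
) -> RunRecord:
    """Simulate one EMG-contingent run (RC, CT or TT) end-to-end.

    The gate operates on the background trace of the ongoing EMG; evoked
    templates are superimposed at the gated stimulus times, then every
    trial is measured from the final composite signal.
    """
    import pandas as pd

    fs = cfg.signal.sample_rate
    if planned.mode is ModeCode.RC:
        n_trials = cfg.rc_trials_per_intensity * len(cfg.rc_intensities())
    else:
        n_trials = planned.trials if planned.trials is not None else 20

    tr = cfg.trigger.target_range
    mids = [v for v in (tr.low, tr.high) if v is not None]
    drive_target = float(np.mean(mids)) if mids else p.background_drive
    per_trial_s = cfg.trigger.min_interval_s + cfg.trigger.hold_duration_s + 3.0
    duration = n_trials * per_trial_s + 10.0

    signals = synth_background(p, duration, fs, rng, drive_target)
    blocks = [SampleBlock(signals[:2], fs, DEFAULT_ROLES[:2], 0.0)]
    traces = background_level(blocks, cfg.signal)
    events = run_gate(traces[0], traces[1], cfg.trigger, planned.mode.value)
    events = events[:n_trials]

    if planned.mode is ModeCode.RC:
        schedule = np.repeat(cfg.rc_intensities(), cfg.rc_trials_per_intensity)
    else:
        schedule = np.full(n_trials, cfg.conditioning_intensity_mA)

    feedback = planned.mode is ModeCode.TT and criterion is not None
    rows = []
    kept_events = []
    for i, ev in enumerate(events):
        intensity = float(schedule[i])
        frame = int(round(ev.time_s * fs))
        if frame + int(ra.DEFAULT_POST_S * fs) >= signals.shape[1]:
            break
        m_amp = m_amplitude(intensity, p)
        h_amp = h_amplitude(intensity, p)
        if p.response_noise > 0:
            m_amp = max(0.0, m_amp * (1 + p.response_noise * rng.standard_normal()))
            h_amp = max(0.0, h_amp * (1 + p.response_noise * rng.standard_normal()))
        inject_response(signals, fs, frame, m_amp, h_amp, p)
        ev = replace(ev, intensity_mA=intensity, trial_index=i + 1)
        kept_events.append(ev)
        epoch = ra.extract_epoch(signals, fs, ev, background=traces)
        ref, tgt = ra.measure_trial(epoch, cfg.windows, cfg.method)
        success: object = pd.NA
        if feedback:
            success = rn.classify_trial(tgt.value, criterion)
            apply_reinforcement(p, success, criterion.direction)
        rows.append(
            {
                "trial": i + 1,
                "time_s": ev.time_s,
                "intensity_mA": intensity,
                "reference_size": ref.value,
                "target_size": tgt.value,
                "background_mV": float(traces[0].levels[min(frame, traces[0].levels.size - 1)]),
                "success": success,
            }
        )

    if kept_events:
        last_frame = int(round(kept_events[-1].time_s * fs)) + int(0.3 * fs)
        signals = signals[:, : min(signals.shape[1], last_frame)]
    trials = pd.DataFrame(
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
    return RunRecord(
        mode=planned.mode,
        run_number=run_number,
        signals=signals,
        sample_rate=fs,
        events=kept_events,
        trials=trials,
        config_snapshot=cfg.to_dict(),
    )


def _simulate_vc_run(
    p: VirtualParticipant,
    cfg: ProtocolConfig,
    rng: np.random.Generator,
    run_number: int,
    duration_s: float = 10.0,
) -> RunRecord:
    """Voluntary-contraction run: effort ramps up to a maximal burst."""
    fs = cfg.signal.sample_rate
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    # rest -> ramp -> maximal plateau -> release
    profile = np.interp(
        t,
        [0, 2, 4, 6, 8, duration_s],
        [1.0, 1.0, 4.0, 8.0, 8.0, 1.0],
    )
    drive = p.background_drive * profile
    target = _bandlimited_unit_noise(n, fs, rng) * drive * _HALF_NORMAL_FACTOR
    antagonist = (
        _bandlimited_unit_noise(n, fs, rng) * p.antagonist_drive * _HALF_NORMAL_FACTOR
    )
    signals = np.vstack([target, antagonist, np.zeros(n)])
    return RunRecord(
        mode=ModeCode.VC,
        run_number=run_number,
        signals=signals,
        sample_rate=fs,
        config_snapshot=cfg.to_dict(),
    )


def run_closed_loop(
    p: VirtualParticipant,
    templates: Sequence[SessionTemplate],
    cfg: ProtocolConfig,
    seed: int,
    data_root: Optional[Path | str] = None,
    participant_id: str = "SIM01",
    direction: str = rn.DIRECTION_DOWN,
    start_time: Optional[datetime] = None,
) -> list[list[SimulatedRun]]:
    """Drive the full pipeline for a list of session templates.

    Each session gets its own simulated visit (4 h apart, so sessions
    never merge via the continuation rule).  Within a conditioning-style
    session the criterion for training runs is set from that session's
    most recent control-trials run at the configured percentile.  When
    ``data_root`` is given every run is persisted through the session
    module; otherwise runs are kept in memory only.

    Returns one list of SimulatedRun per session.
    """
    rng = np.random.default_rng(seed)
    clock = start_time or datetime(2024, 1, 8, 9, 0)
    out: list[list[SimulatedRun]] = []
    for template in templates:
        session: Optional[Session] = None
        if data_root is not None:
            meta = start_or_continue_session(participant_id, clock, data_root)
            session = Session(meta, clock=lambda c=clock: c)
        criterion: Optional[rn.ConditioningCriterion] = None
        run_number = session.next_run_number() if session else 1
        session_runs: list[SimulatedRun] = []
        for planned in template.runs:
            if planned.mode is ModeCode.VC:
                record = _simulate_vc_run(p, cfg, rng, run_number)
            else:
                record = _simulate_contingent_run(
                    p, planned, cfg, rng, criterion, run_number
                )
            if planned.mode is ModeCode.CT and len(record.trials):
                dist = rn.compute_distribution(
                    record.trials["target_size"].to_numpy(), cfg.target_percentile
                )
                criterion = rn.criterion_from_distribution(
                    dist, cfg.target_percentile, direction
                )
                if session is not None:
                    session.log_distribution_summary(dist)
                    session.log_criterion_adoption(criterion)
            if session is not None:
                session._active = record
                session.stop_run()
            session_runs.append(SimulatedRun(record=record, planned=planned))
            run_number += 1
        out.append(session_runs)
        clock = clock + timedelta(hours=4)
    return out
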