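"""Session and run orchestration: modes, templates, persistence, logging.

A *session* is one visit; it owns a time-stamped data directory and a
sequential run counter.  A *run* is one continuous recording in one of
five operating modes:

==  =====================  =============================================
ST  Stimulus Test          periodic stimulation, not EMG-contingent
VC  Voluntary Contraction  background recording to establish MVC
RC  Recruitment Curve      intensity sweep for M/H recruitment
CT  Control Trials         contingent stimulation, no response feedback
TT  Training Trials        contingent stimulation with criterion feedback
==  =====================  =============================================

Run containers are HDF5 files (raw signals, event tables, per-trial
measurements, config snapshot) with a JSON sidecar of human-readable
metadata.  File names carry the session date-time stamp, participant id,
mode code and sequential run number, and are never overwritten.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Callable, Optional

import h5py
import numpy as np
import pandas as pd

from .response_analysis import METHOD_P2P, ResponseWindows
from .signal_core import (
    DEFAULT_ROLES,
    ROLE_TARGET,
    SignalConfig,
    background_level,
    blocks_from_array,
)
from .trigger_engine import RangeSpec, StimulusEvent, TriggerConfig

#: A session may be continued only within this window after it started.
CONTINUATION_WINDOW = timedelta(hours=3)

_STAMP_FMT = "%Y%m%d-%H%M"

_TRIAL_COLUMNS = [
    "trial",
    "time_s",
    "intensity_mA",
    "reference_size",
    "target_size",
    "background_mV",
    "success",
]


class ModeCode(str, Enum):
    ST = "ST"
    VC = "VC"
    RC = "RC"
    CT = "CT"
    TT = "TT"


@dataclass
class SessionMeta:
    participant_id: str
    start_timestamp: datetime
    data_dir: Path
    continuation: bool = False

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be nonempty")

    @property
    def stamp(self) -> str:
        return self.start_timestamp.strftime(_STAMP_FMT)


@dataclass
class RunRecord:
    """Everything recorded for one run."""

    mode: ModeCode
    run_number: int
    signals: np.ndarray  # channels x frames, mV
    sample_rate: float
    channel_roles: tuple[str, ...] = DEFAULT_ROLES
    events: list[StimulusEvent] = field(default_factory=list)
    trials: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_TRIAL_COLUMNS)
    )
    config_snapshot: dict = field(default_factory=dict)
    notes: str = ""


# --------------------------------------------------------------------------
# Session lifecycle


def _session_dirs(root: Path, participant_id: str) -> list[tuple[datetime, Path]]:
    found = []
    for p in sorted(root.glob(f"*_{participant_id}")):
        try:
            stamp = datetime.strptime(p.name.split("_")[0], _STAMP_FMT)
        except ValueError:
            continue
        found.append((stamp, p))
    return found


def start_or_continue_session(
    participant_id: str,
    now: datetime,
    root: Path | str,
    continue_if_possible: bool = True,
) -> SessionMeta:
    """Create a new time-stamped session directory, or rebind to a recent one.

    Continuation (e.g. after a software relaunch) is only possible if a
    session for the same participant started within the last three hours;
    otherwise a fresh session directory is created.
    """
    if not participant_id:
        raise ValueError("participant_id must be nonempty")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    if continue_if_possible:
        for stamp, path in reversed(_session_dirs(root, participant_id)):
            if timedelta(0) <= now - stamp <= CONTINUATION_WINDOW:
                return SessionMeta(participant_id, stamp, path, continuation=True)
    data_dir = root / f"{now.strftime(_STAMP_FMT)}_{participant_id}"
    data_dir.mkdir(parents=True, exist_ok=False)
    return SessionMeta(participant_id, now, data_dir, continuation=False)


class Session:
    """Run counter, persistence and logging for one session.

    ``clock`` is injected so timestamps are deterministic under test.
    """

    def __init__(self, meta: SessionMeta, clock: Optional[Callable[[], datetime]] = None):
        self.meta = meta
        self.clock = clock or datetime.now
        self._active: Optional[RunRecord] = None

    # -- run numbering ------------------------------------------------

    def next_run_number(self) -> int:
        existing = self.meta.data_dir.glob(f"{self.meta.stamp}_{self.meta.participant_id}_??*.h5")
        numbers = []
        for p in existing:
            suffix = p.stem.split("_")[-1]
            digits = suffix[2:]
            if digits.isdigit():
                numbers.append(int(digits))
        return max(numbers, default=0) + 1

    def run_filename(self, mode: ModeCode, run_number: int) -> Path:
        name = (
            f"{self.meta.stamp}_{self.meta.participant_id}_"
            f"{mode.value}{run_number:02d}.h5"
        )
        return self.meta.data_dir / name

    # -- run lifecycle ------------------------------------------------

    def start_run(
        self,
        mode: ModeCode,
        sample_rate: float,
        config_snapshot: Optional[dict] = None,
        channel_roles: tuple[str, ...] = DEFAULT_ROLES,
    ) -> RunRecord:
        if self._active is not None:
            raise RuntimeError("a run is already in progress")
        record = RunRecord(
            mode=mode,
            run_number=self.next_run_number(),
            signals=np.empty((len(channel_roles), 0)),
            sample_rate=sample_rate,
            channel_roles=channel_roles,
            config_snapshot=dict(config_snapshot or {}),
        )
        self._active = record
        return record

    def stop_run(self) -> Path:
        """Persist the active run; run files never overwrite each other."""
        if self._active is None:
            raise RuntimeError("no run in progress")
        record = self._active
        path = self.run_filename(record.mode, record.run_number)
        save_run(record, path)
        self._active = None
        return path

    # -- logging ------------------------------------------------------

    @property
    def log_path(self) -> Path:
        return self.meta.data_dir / (
            f"{self.meta.stamp}_{self.meta.participant_id}_log.txt"
        )

    def append_log(self, text: str, timestamp: Optional[datetime] = None) -> Path:
        """Append a timestamped line to the session's plain-text log."""
        ts = timestamp or self.clock()
        with open(self.log_path, "a") as f:
            for line in text.splitlines() or [""]:
                f.write(f"[{ts.isoformat(timespec='seconds')}] {line}\n")
        return self.log_path

    def log_criterion_adoption(self, criterion) -> Path:
        """Criterion adoptions are always logged automatically."""
        return self.append_log(
            f"criterion adopted: direction={criterion.direction} "
            f"percentile={criterion.target_percentile:g} "
            f"threshold={criterion.threshold:.6g} mV"
        )

    def log_distribution_summary(self, dist) -> Path:
        s = dist.summary()
        lines = "\n".join(f"  {k}: {v:.6g}" if isinstance(v, float) else f"  {k}: {v}"
                          for k, v in s.items())
        return self.append_log("distribution summary:\n" + lines)


# --------------------------------------------------------------------------
# Persistence (HDF5 container + JSON sidecar)


def save_run(record: RunRecord, path: Path | str) -> Path:
    path = Path(path)
    if path.exists():
        raise FileExistsError(f"run file {path} already exists; runs never overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w-") as f:
        f.attrs["mode"] = record.mode.value
        f.attrs["run_number"] = record.run_number
        f.attrs["sample_rate"] = record.sample_rate
        f.attrs["channel_roles"] = json.dumps(list(record.channel_roles))
        f.attrs["config_snapshot"] = json.dumps(record.config_snapshot, sort_keys=True)
        f.attrs["notes"] = record.notes
        f.create_dataset("signals", data=np.asarray(record.signals, dtype=float))
        ev = f.create_group("events")
        ev.create_dataset(
            "time_s", data=np.array([e.time_s for e in record.events], dtype=float)
        )
        ev.create_dataset(
            "intensity_mA",
            data=np.array(
                [np.nan if e.intensity_mA is None else e.intensity_mA
                 for e in record.events],
                dtype=float,
            ),
        )
        ev.create_dataset(
            "trial_index",
            data=np.array([e.trial_index for e in record.events], dtype=np.int64),
        )
        tg = f.create_group("trials")
        trials = record.trials
        for col in _TRIAL_COLUMNS:
            if col == "success":
                vals = np.array(
                    [-1 if pd.isna(v) else int(bool(v)) for v in trials[col]],
                    dtype=np.int8,
                )
            elif col == "trial":
                vals = trials[col].to_numpy(dtype=np.int64)
            else:
                vals = trials[col].to_numpy(dtype=float)
            tg.create_dataset(col, data=vals)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "file": path.name,
                "mode": record.mode.value,
                "run_number": record.run_number,
                "sample_rate": record.sample_rate,
                "channels": list(record.channel_roles),
                "n_frames": int(np.asarray(record.signals).shape[-1]),
                "n_trials": int(len(record.trials)),
                "notes": record.notes,
            },
            indent=2,
        )
    )
    return path


def load_run(path: Path | str) -> RunRecord:
    """Open a stored run for offline reanalysis."""
    with h5py.File(path, "r") as f:
        roles = tuple(json.loads(f.attrs["channel_roles"]))
        events = [
            StimulusEvent(
                time_s=float(t),
                intensity_mA=None if np.isnan(i) else float(i),
                trial_index=int(k),
            )
            for t, i, k in zip(
                f["events/time_s"][()],
                f["events/intensity_mA"][()],
                f["events/trial_index"][()],
            )
        ]
        trials = pd.DataFrame(
            {col: f[f"trials/{col}"][()] for col in _TRIAL_COLUMNS}
        )
        trials["success"] = pd.array(
            [pd.NA if v < 0 else bool(v) for v in trials["success"]],
            dtype="boolean",
        )
        return RunRecord(
            mode=ModeCode(f.attrs["mode"]),
            run_number=int(f.attrs["run_number"]),
            signals=f["signals"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            channel_roles=roles,
            events=events,
            trials=trials,
            config_snapshot=json.loads(f.attrs["config_snapshot"]),
            notes=str(f.attrs["notes"]),
        )


# --------------------------------------------------------------------------
# Analyses bound to whole runs


def mvc_level(run: RunRecord, config: Optional[SignalConfig] = None) -> float:
    """Maximum voluntary contraction: peak target-muscle background level."""
    if run.mode is not ModeCode.VC:
        raise ValueError("MVC is estimated from a Voluntary Contraction run")
    config = config or SignalConfig(sample_rate=run.sample_rate)
    blocks = blocks_from_array(run.signals, run.sample_rate, channel_roles=run.channel_roles)
    traces = background_level(blocks, config)
    target = traces[run.channel_roles.index(ROLE_TARGET)]
    return float(np.max(target.levels))


# --------------------------------------------------------------------------
# Session templates and protocol planning


@dataclass(frozen=True)
class PlannedRun:
    mode: ModeCode
    trials: Optional[int] = None  # None: operator-stopped (e.g. RC sweeps)


@dataclass(frozen=True)
class SessionTemplate:
    kind: str  # baseline | conditioning | follow_up
    runs: tuple[PlannedRun, ...]


def baseline_template() -> SessionTemplate:
    """Recruitment curve, 3 x 75 control trials, recruitment curve."""
    return SessionTemplate(
        kind="baseline",
        runs=(
            PlannedRun(ModeCode.RC),
            PlannedRun(ModeCode.CT, 75),
            PlannedRun(ModeCode.CT, 75),
            PlannedRun(ModeCode.CT, 75),
            PlannedRun(ModeCode.RC),
        ),
    )


def conditioning_template() -> SessionTemplate:
    """Recruitment curve, 20 control trials, 3 x 75 training trials,
    recruitment curve."""
    return SessionTemplate(
        kind="conditioning",
        runs=(
            PlannedRun(ModeCode.RC),
            PlannedRun(ModeCode.CT, 20),
            PlannedRun(ModeCode.TT, 75),
            PlannedRun(ModeCode.TT, 75),
            PlannedRun(ModeCode.TT, 75),
            PlannedRun(ModeCode.RC),
        ),
    )


def follow_up_template(style: str = "baseline") -> SessionTemplate:
    """Follow-up sessions mirror baseline or conditioning sessions."""
    if style == "baseline":
        base = baseline_template()
    elif style == "conditioning":
        base = conditioning_template()
    else:
        raise ValueError("follow-up style must be 'baseline' or 'conditioning'")
    return SessionTemplate(kind="follow_up", runs=base.runs)


def plan_protocol(
    impairment: bool = False, follow_up_style: str = "baseline"
) -> list[SessionTemplate]:
    """Full study plan: 6 baseline, 24 (or 30 for neurological impairment)
    conditioning, and 4 follow-up sessions, in order."""
    n_conditioning = 30 if impairment else 24
    return (
        [baseline_template()] * 6
        + [conditioning_template()] * n_conditioning
        + [follow_up_template(follow_up_style)] * 4
    )


def run_auto_complete(planned: PlannedRun, trials_done: int) -> bool:
    """True when a CT/TT run with a configured trial count should stop."""
    return planned.trials is not None and trials_done >= planned.trials


# --------------------------------------------------------------------------
# Declarative protocol configuration


@dataclass
class ProtocolConfig:
    """Everything a session needs, loadable from a YAML protocol file.

    The recruitment-sweep defaults (start 5 mA, step 2 mA every 4 trials)
    follow the worked H-reflex protocol; they are examples to be tailored
    per participant.
    """

    signal: SignalConfig = field(default_factory=SignalConfig)
    trigger: TriggerConfig = field(
        default_factory=lambda: TriggerConfig(
            target_range=RangeSpec(0.02, 0.1),
            antagonist_range=RangeSpec(None, 0.05),
        )
    )
    windows: ResponseWindows = field(default_factory=ResponseWindows)
    method: str = METHOD_P2P
    pool_size: int = 4
    target_percentile: float = 66.0
    conditioning_intensity_mA: float = 24.0
    rc_start_mA: float = 5.0
    rc_step_mA: float = 2.0
    rc_n_intensities: int = 21
    rc_trials_per_intensity: int = 4

    def rc_intensities(self) -> np.ndarray:
        """Stimulus-intensity schedule of a recruitment-curve sweep."""
        return self.rc_start_mA + self.rc_step_mA * np.arange(self.rc_n_intensities)

    def to_dict(self) -> dict:
        def _range(r: RangeSpec) -> dict:
            return {"low": r.low, "high": r.high}

        return {
            "signal": {
                "sample_rate": self.signal.sample_rate,
                "highpass_cutoff_hz": self.signal.highpass_cutoff_hz,
                "background_window_s": self.signal.background_window_s,
            },
            "trigger": {
                "target_range": _range(self.trigger.target_range),
                "antagonist_range": _range(self.trigger.antagonist_range),
                "hold_duration_s": self.trigger.hold_duration_s,
                "min_interval_s": self.trigger.min_interval_s,
                "min_interval_stimulus_test_s": self.trigger.min_interval_stimulus_test_s,
            },
            "windows": {
                "reference_ms": list(self.windows.reference_ms),
                "target_ms": list(self.windows.target_ms),
            },
            "method": self.method,
            "pool_size": self.pool_size,
            "target_percentile": self.target_percentile,
            "conditioning_intensity_mA": self.conditioning_intensity_mA,
            "rc_start_mA": self.rc_start_mA,
            "rc_step_mA": self.rc_step_mA,
            "rc_n_intensities": self.rc_n_intensities,
            "rc_trials_per_intensity": self.rc_trials_per_intensity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        sig = d.get("signal", {})
        trg = d.get("trigger", {})
        win = d.get("windows", {})
        return cls(
            signal=SignalConfig(**sig) if sig else SignalConfig(),
            trigger=TriggerConfig(
                target_range=RangeSpec(**trg.get("target_range", {})),
                antagonist_range=RangeSpec(**trg.get("antagonist_range", {})),
                hold_duration_s=trg.get("hold_duration_s", 2.0),
                min_interval_s=trg.get("min_interval_s", 5.0),
                min_interval_stimulus_test_s=trg.get(
                    "min_interval_stimulus_test_s", 3.0
                ),
            )
            if trg
            else ProtocolConfig.__dataclass_fields__["trigger"].default_factory(),
            windows=ResponseWindows(
                reference_ms=tuple(win.get("reference_ms", (6.0, 23.0))),
                target_ms=tuple(win.get("target_ms", (28.0, 45.0))),
            )
            if win
            else ResponseWindows(),
            method=d.get("method", METHOD_P2P),
            pool_size=d.get("pool_size", 4),
            target_percentile=d.get("target_percentile", 66.0),
            conditioning_intensity_mA=d.get("conditioning_intensity_mA", 24.0),
            rc_start_mA=d.get("rc_start_mA", 5.0),
            rc_step_mA=d.get("rc_step_mA", 2.0),
            rc_n_intensities=d.get("rc_n_intensities", 21),
            rc_trials_per_intensity=d.get("rc_trials_per_intensity", 4),
        )


def load_protocol(path: Path | str) -> ProtocolConfig:
    import yaml

    with open(path) as f:
        return ProtocolConfig.from_dict(yaml.safe_load(f) or {})


def save_protocol(config: ProtocolConfig, path: Path | str) -> Path:
    import yaml

    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path
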