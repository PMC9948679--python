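"""Session lifecycle, run naming/persistence, templates, logging."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from reflexloop.run_analysis import compute_distribution, criterion_from_distribution
from reflexloop.session import (
    ModeCode,
    PlannedRun,
    ProtocolConfig,
    RunRecord,
    Session,
    baseline_template,
    conditioning_template,
    follow_up_template,
    load_protocol,
    load_run,
    mvc_level,
    plan_protocol,
    run_auto_complete,
    save_protocol,
    save_run,
    start_or_continue_session,
)
from reflexloop.signal_core import SignalConfig, background_level, blocks_from_array
from reflexloop.simulator import VirtualParticipant, run_closed_loop
from reflexloop.trigger_engine import StimulusEvent

T0 = datetime(2024, 3, 1, 10, 0)


class TestSessionLifecycle:
    def test_first_session_creates_stamped_directory(self, tmp_path):
        meta = start_or_continue_session("P001", T0, tmp_path)
        assert meta.data_dir.name == "20240301-1000_P001"
        assert not meta.continuation
        assert Session(meta).next_run_number() == 1

    def test_relaunch_within_three_hours_continues(self, tmp_path):
        start_or_continue_session("P001", T0, tmp_path)
        meta = start_or_continue_session("P001", T0 + timedelta(hours=2), tmp_path)
        assert meta.continuation
        assert meta.stamp == "20240301-1000"

    def test_relaunch_after_three_hours_starts_new(self, tmp_path):
        start_or_continue_session("P001", T0, tmp_path)
        meta = start_or_continue_session("P001", T0 + timedelta(hours=4), tmp_path)
        assert not meta.continuation
        assert meta.stamp == "20240301-1400"

    def test_other_participant_never_continues(self, tmp_path):
        start_or_continue_session("P001", T0, tmp_path)
        meta = start_or_continue_session("P002", T0 + timedelta(hours=1), tmp_path)
        assert not meta.continuation

    def test_empty_id_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            start_or_continue_session("", T0, tmp_path)


def small_record(mode=ModeCode.CT, run_number=1, seed=0):
    rng = np.random.default_rng(seed)
    trials = pd.DataFrame(
        {
            "trial": [1, 2],
            "time_s": [2.0, 7.0],
            "intensity_mA": [24.0, 24.0],
            "reference_size": [1.4, 1.5],
            "target_size": [2.8, 2.9],
            "background_mV": [0.05, 0.05],
            "success": [True, pd.NA],
        }
    )
    return RunRecord(
        mode=mode,
        run_number=run_number,
        signals=rng.normal(size=(3, 500)),
        sample_rate=2000.0,
        events=[
            StimulusEvent(2.0, 24.0, 1),
            StimulusEvent(7.0, None, 2),
        ],
        trials=trials,
        config_snapshot={"hold": 2.0},
        notes="practice",
    )


class TestRunPersistence:
    def test_filenames_number_sequentially_across_modes(self, tmp_path):
        meta = start_or_continue_session("P001", T0, tmp_path)
        session = Session(meta, clock=lambda: T0)
        names = []
        for mode in (ModeCode.RC, ModeCode.CT, ModeCode.TT):
            session.start_run(mode, 2000.0)
            session._active = small_record(mode, session._active.run_number)
            names.append(session.stop_run().name)
        assert names == [
            "20240301-1000_P001_RC01.h5",
            "20240301-1000_P001_CT02.h5",
            "20240301-1000_P001_TT03.h5",
        ]

    def test_overwrite_is_a_hard_error(self, tmp_path):
        path = tmp_path / "20240301-1000_P001_CT01.h5"
        save_run(small_record(), path)
        with pytest.raises(FileExistsError):
            save_run(small_record(), path)

    def test_round_trip_is_bit_exact(self, tmp_path):
        record = small_record()
        path = save_run(record, tmp_path / "r.h5")
        loaded = load_run(path)
        np.testing.assert_array_equal(loaded.signals, record.signals)
        assert loaded.mode is record.mode
        assert loaded.sample_rate == record.sample_rate
        assert [e.time_s for e in loaded.events] == [2.0, 7.0]
        assert loaded.events[1].intensity_mA is None
        for col in ("time_s", "reference_size", "target_size", "background_mV"):
            np.testing.assert_array_equal(loaded.trials[col], record.trials[col])
        assert loaded.trials["success"][0] == True  # noqa: E712
        assert pd.isna(loaded.trials["success"][1])
        assert loaded.config_snapshot == {"hold": 2.0}
        assert loaded.notes == "practice"
        assert path.with_suffix(".json").exists()  # human-readable sidecar

    def test_only_one_active_run(self, tmp_path):
        session = Session(start_or_continue_session("P001", T0, tmp_path))
        session.start_run(ModeCode.CT, 2000.0)
        with pytest.raises(RuntimeError):
            session.start_run(ModeCode.CT, 2000.0)


class TestLogging:
    def test_appends_preserve_order_with_timestamps(self, tmp_path):
        session = Session(
            start_or_continue_session("P001", T0, tmp_path), clock=lambda: T0
        )
        session.append_log("first note")
        session.append_log("second note", timestamp=T0 + timedelta(minutes=5))
        text = session.log_path.read_text()
        assert text.index("first note") < text.index("second note")
        assert "[2024-03-01T10:05:00]" in text

    def test_criterion_adoption_logged_automatically(self, tmp_path):
        session = Session(
            start_or_continue_session("P001", T0, tmp_path), clock=lambda: T0
        )
        crit = criterion_from_distribution([1.0, 2.0, 3.0], 66.0, "down")
        session.log_criterion_adoption(crit)
        text = session.log_path.read_text()
        assert "direction=down" in text and "percentile=66" in text
        assert f"{crit.threshold:.6g}" in text

    def test_distribution_summary_appended(self, tmp_path):
        session = Session(
            start_or_continue_session("P001", T0, tmp_path), clock=lambda: T0
        )
        session.log_distribution_summary(compute_distribution([1.0, 2.0, 3.0]))
        assert "median" in session.log_path.read_text()


class TestMvc:
    def test_requires_vc_mode(self):
        with pytest.raises(ValueError):
            mvc_level(small_record(ModeCode.CT))

    def test_matches_brute_force_trace_maximum(self, rng, signal_config):
        record = RunRecord(
            mode=ModeCode.VC,
            run_number=1,
            signals=rng.normal(size=(3, 6000)) * np.linspace(0.5, 2.0, 6000),
            sample_rate=signal_config.sample_rate,
        )
        traces = background_level(
            blocks_from_array(record.signals, record.sample_rate),
            signal_config,
        )
        assert mvc_level(record, signal_config) == np.max(traces[0].levels)


class TestTemplatesAndPlanning:
    def test_baseline_template_composition(self):
        runs = baseline_template().runs
        assert [r.mode for r in runs] == [
            ModeCode.RC, ModeCode.CT, ModeCode.CT, ModeCode.CT, ModeCode.RC
        ]
        assert [r.trials for r in runs[1:4]] == [75, 75, 75]

    def test_conditioning_template_composition(self):
        runs = conditioning_template().runs
        assert [r.mode for r in runs] == [
            ModeCode.RC, ModeCode.CT, ModeCode.TT, ModeCode.TT, ModeCode.TT, ModeCode.RC
        ]
        assert runs[1].trials == 20
        assert [r.trials for r in runs[2:5]] == [75, 75, 75]

    def test_auto_complete_thresholds(self):
        tt = PlannedRun(ModeCode.TT, 75)
        assert not run_auto_complete(tt, 74)
        assert run_auto_complete(tt, 75)
        ct = PlannedRun(ModeCode.CT, 20)
        assert run_auto_complete(ct, 20)
        assert not run_auto_complete(PlannedRun(ModeCode.RC), 10_000)

    def test_protocol_session_counts(self):
        plan = plan_protocol(impairment=False)
        assert len(plan) == 34
        assert [t.kind for t in plan[:6]] == ["baseline"] * 6
        assert sum(t.kind == "conditioning" for t in plan) == 24
        assert [t.kind for t in plan[-4:]] == ["follow_up"] * 4
        assert len(plan_protocol(impairment=True)) == 40

    def test_follow_up_style_configurable(self):
        assert follow_up_template("baseline").runs == baseline_template().runs
        assert follow_up_template("conditioning").runs == conditioning_template().runs
        with pytest.raises(ValueError):
            follow_up_template("other")


class TestProtocolConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = ProtocolConfig()
        path = save_protocol(cfg, tmp_path / "protocol.yaml")
        loaded = load_protocol(path)
        assert loaded.to_dict() == cfg.to_dict()

    def test_rc_intensity_schedule(self):
        sched = ProtocolConfig().rc_intensities()
        assert sched[0] == 5.0 and sched[1] - sched[0] == 2.0

    def test_defaults_carry_protocol_constants(self):
        cfg = ProtocolConfig()
        assert cfg.trigger.hold_duration_s == 2.0
        assert cfg.trigger.min_interval_s == 5.0
        assert cfg.trigger.min_interval_stimulus_test_s == 3.0
        assert cfg.target_percentile == 66.0
        assert cfg.pool_size == 4


class TestClosedLoopPersistence:
    def test_runs_persisted_and_reloadable(self, tmp_path):
        from reflexloop.session import SessionTemplate

        template = SessionTemplate(
            kind="mini", runs=(PlannedRun(ModeCode.CT, 3),)
        )
        sessions = run_closed_loop(
            VirtualParticipant(),
            [template],
            ProtocolConfig(),
            seed=5,
            data_root=tmp_path,
        )
        record = sessions[0][0].record
        files = list(tmp_path.glob("*/*.h5"))
        assert len(files) == 1
        loaded = load_run(files[0])
        np.testing.assert_array_equal(loaded.signals, record.signals)
        assert len(loaded.trials) == 3
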