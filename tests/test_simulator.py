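"""Virtual participant: recruitment shapes, plasticity, determinism."""

import numpy as np
import pytest

from reflexloop.run_analysis import build_recruitment_curve
from reflexloop.session import ModeCode, PlannedRun, ProtocolConfig, SessionTemplate
from reflexloop.simulator import (
    EXCITABILITY_FLOOR,
    VirtualParticipant,
    apply_reinforcement,
    biphasic_template,
    h_amplitude,
    m_amplitude,
    run_closed_loop,
    simulate_recruitment_table,
    synth_background,
    synth_continuous,
)


class TestRecruitmentFunctions:
    def test_m_wave_tail_and_midpoint(self):
        p = VirtualParticipant()
        assert m_amplitude(0.0, p) < 1e-2 * p.m_max
        assert m_amplitude(p.i50_m, p) == pytest.approx(p.m_max / 2)

    def test_m_wave_monotone_nondecreasing(self):
        p = VirtualParticipant()
        grid = np.linspace(0, 60, 601)
        vals = np.array([m_amplitude(i, p) for i in grid])
        assert np.all(np.diff(vals) >= 0)

    def test_h_reflex_small_at_zero_and_unimodal(self):
        p = VirtualParticipant()
        grid = np.linspace(0, 60, 601)
        vals = np.array([h_amplitude(i, p) for i in grid])
        assert vals[0] < 1e-2 * p.h_max
        diffs = np.sign(np.diff(vals))
        # rises, then falls: exactly one sign change in the derivative
        changes = np.count_nonzero(np.diff(diffs[diffs != 0]) != 0)
        assert changes == 1
        assert 0 < np.argmax(vals) < len(grid) - 1

    def test_h_scales_linearly_with_excitability(self):
        p = VirtualParticipant()
        base = np.array([h_amplitude(i, p) for i in range(0, 50, 5)])
        p.h_excitability = 0.5
        halved = np.array([h_amplitude(i, p) for i in range(0, 50, 5)])
        np.testing.assert_allclose(halved, 0.5 * base, rtol=1e-12)


class TestReinforcement:
    def test_zero_rate_never_changes_state(self):
        p = VirtualParticipant(plasticity_rate=0.0)
        for _ in range(50):
            apply_reinforcement(p, True, "down")
        assert p.h_excitability == 1.0

    def test_hundred_down_successes_closed_form(self):
        p = VirtualParticipant(plasticity_rate=0.01)
        for _ in range(100):
            apply_reinforcement(p, True, "down")
        assert p.h_excitability == pytest.approx(0.99**100, rel=1e-9)

    def test_failures_leave_state_unchanged(self):
        p = VirtualParticipant(plasticity_rate=0.05)
        apply_reinforcement(p, False, "up")
        assert p.h_excitability == 1.0

    def test_clip_floor_under_unlimited_successes(self):
        p = VirtualParticipant(plasticity_rate=0.2)
        for _ in range(200):
            apply_reinforcement(p, True, "down")
        assert p.h_excitability == EXCITABILITY_FLOOR

    def test_up_direction_increases_and_clips(self):
        p = VirtualParticipant(plasticity_rate=0.2)
        for _ in range(200):
            apply_reinforcement(p, True, "up")
        assert p.h_excitability == 2.0


class TestSynthesis:
    def test_template_is_biphasic_unit_p2p(self):
        w = biphasic_template(9.0, 2000.0)
        assert w.max() > 0 > w.min()
        assert w.max() - w.min() == pytest.approx(1.0, abs=1e-12)

    def test_zero_drive_no_events_is_silent(self, quiet_participant, rng):
        blocks = synth_continuous(quiet_participant, [], 1.0, 2000.0, rng)
        sig = np.hstack([b.samples for b in blocks])
        assert np.all(sig == 0)

    def test_fixed_seed_repeats_bit_identically(self):
        p = VirtualParticipant()
        a = synth_background(p, 2.0, 2000.0, np.random.default_rng(42))
        b = synth_background(p, 2.0, 2000.0, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_overlapping_events_warn(self, rng):
        p = VirtualParticipant()
        with pytest.warns(UserWarning, match="overlap"):
            synth_continuous(p, [(0.5, 20.0), (0.55, 20.0)], 1.0, 2000.0, rng)

    def test_loopback_pulse_marks_each_event(self, quiet_participant, rng):
        blocks = synth_continuous(
            quiet_participant, [(0.5, 20.0), (1.5, 20.0)], 2.0, 2000.0, rng
        )
        loop = np.hstack([b.samples for b in blocks])[2]
        onsets = np.flatnonzero(np.diff(np.concatenate([[0.0], loop])) > 0)
        np.testing.assert_array_equal(onsets, [1000, 3000])


class TestRecruitmentSweep:
    def test_noise_free_sweep_reproduces_qualitative_shapes(self):
        """Pooled M sizes nondecreasing; pooled H sizes rise then fall."""
        p = VirtualParticipant(
            background_drive=0.0, antagonist_drive=0.0,
            drive_noise=0.0, response_noise=0.0,
        )
        cfg = ProtocolConfig()
        table = simulate_recruitment_table(p, cfg, np.random.default_rng(0))
        curve = build_recruitment_curve(table, pool_size=cfg.pool_size)
        ref = curve.points["reference_size"].to_numpy()
        tgt = curve.points["target_size"].to_numpy()
        assert np.all(np.diff(ref) >= -1e-12)
        peak = int(np.argmax(tgt))
        assert 0 < peak < len(tgt) - 1
        assert np.all(np.diff(tgt[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(tgt[peak:]) <= 1e-12)

    def test_noise_free_pipeline_recovers_programmed_extrema(self):
        p = VirtualParticipant(
            background_drive=0.0, antagonist_drive=0.0,
            drive_noise=0.0, response_noise=0.0,
        )
        cfg = ProtocolConfig()
        table = simulate_recruitment_table(p, cfg, np.random.default_rng(0))
        curve = build_recruitment_curve(table, pool_size=cfg.pool_size)
        grid = cfg.rc_intensities()
        true_m = max(m_amplitude(i, p) for i in grid)
        true_h = max(h_amplitude(i, p) for i in grid)
        assert curve.m_max == pytest.approx(true_m, rel=1e-6)
        assert curve.h_max == pytest.approx(true_h, rel=1e-6)


class TestClosedLoop:
    @pytest.fixture(scope="class")
    @staticmethod
    def mini_sessions():
        """One scaled control+training session, plasticity enabled."""
        template = SessionTemplate(
            kind="mini",
            runs=(PlannedRun(ModeCode.CT, 10), PlannedRun(ModeCode.TT, 25)),
        )
        p = VirtualParticipant(plasticity_rate=0.02)
        cfg = ProtocolConfig()
        out = run_closed_loop(p, [template], cfg, seed=11)
        return p, out[0]

    def test_runs_complete_their_trial_counts(self, mini_sessions):
        _, runs = mini_sessions
        assert len(runs[0].record.trials) == 10
        assert len(runs[1].record.trials) == 25

    def test_training_run_has_feedback_and_reinforcement(self, mini_sessions):
        p, runs = mini_sessions
        tt = runs[1].record.trials
        assert tt["success"].notna().all()
        n_success = int(tt["success"].sum())
        assert p.h_excitability == pytest.approx(0.98**n_success, rel=1e-9)

    def test_event_spacing_respects_min_interval(self, mini_sessions):
        _, runs = mini_sessions
        cfg = ProtocolConfig()
        for run in runs:
            times = [e.time_s for e in run.record.events]
            assert all(
                b - a >= cfg.trigger.min_interval_s - 1e-6
                for a, b in zip(times, times[1:])
            )

    def test_m_wave_constant_at_fixed_intensity(self, mini_sessions):
        """Constant stimulus intensity keeps the reference response within
        the stability tolerance of its programmed size."""
        from reflexloop.run_analysis import assess_reference_stability

        _, runs = mini_sessions
        p_nominal = m_amplitude(24.0, VirtualParticipant())
        report = assess_reference_stability(
            runs[1].record.trials["reference_size"].to_numpy(), p_nominal
        )
        assert not report.flagged

    def test_same_seed_identical_payloads(self):
        template = SessionTemplate(kind="mini", runs=(PlannedRun(ModeCode.CT, 4),))
        cfg = ProtocolConfig()
        outs = []
        for _ in range(2):
            p = VirtualParticipant()
            outs.append(run_closed_loop(p, [template], cfg, seed=3)[0][0].record)
        np.testing.assert_array_equal(outs[0].signals, outs[1].signals)
        assert outs[0].trials.equals(outs[1].trials)
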