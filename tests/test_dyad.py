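"""Dyad simulator: Kuramoto step, envelopes, trials, sessions, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from syncspeech._utils import plv, wrap_phase
from syncspeech.dyad import (
    Condition,
    DyadConfig,
    OscillatorState,
    count_syllable_onsets,
    phase_to_envelope,
    simulate_session,
    simulate_trial,
    step_kuramoto,
)


class TestPhaseWrapping:
    @given(st.floats(-50.0, 50.0))
    @settings(derandomize=True, deadline=None)
    def test_wrap_into_half_open_interval(self, x):
        w = wrap_phase(x)
        assert -np.pi < w <= np.pi

    @given(st.floats(-np.pi + 1e-9, np.pi))
    @settings(derandomize=True, deadline=None)
    def test_wrap_is_identity_on_wrapped_values(self, x):
        assert wrap_phase(x) == pytest.approx(x, abs=1e-12)

    def test_unwrap_rewrap_round_trip(self, rng):
        phases = wrap_phase(np.cumsum(rng.normal(0.07, 0.02, size=500)))
        assert np.allclose(wrap_phase(np.unwrap(phases)), phases, atol=1e-12)


class TestKuramotoStep:
    def test_coupling_vanishes_at_preferred_phase(self):
        # VP exactly at its preferred offset: both advance by tick * omega
        cfg = DyadConfig(k_participant=0.0)
        cond = Condition.from_k(-0.09)
        vp = OscillatorState(0.5 + cond.psi)
        p = OscillatorState(0.5)
        new_vp, new_p = step_kuramoto(vp, p, cfg, 0.0, cond)
        assert new_vp.phase == pytest.approx(wrap_phase(vp.phase + cfg.tick * cfg.omega))
        assert new_p.phase == pytest.approx(wrap_phase(p.phase + cfg.tick * cfg.omega))

    def test_zero_coupling_identity(self):
        cfg = DyadConfig(k_participant=0.0)
        cond = Condition("neutral", 0.0, 0.0)
        vp, p = OscillatorState(1.0), OscillatorState(-2.0)
        new_vp, new_p = step_kuramoto(vp, p, cfg, 0.0, cond)
        assert new_vp.phase - vp.phase == pytest.approx(cfg.tick * cfg.omega)
        assert wrap_phase(new_p.phase - p.phase) == pytest.approx(cfg.tick * cfg.omega)

    def test_nonfinite_phase_rejected(self):
        with pytest.raises(ValueError):
            OscillatorState(np.nan)

    def test_sync_coupling_decays_phase_error(self):
        """|delta phi| decays monotonically toward 0 for k=-0.09, checked
        against a fine-step reference integration of the same ODE."""
        cfg = DyadConfig(k_participant=0.15, phase_noise_sd=0.0)
        cond = Condition.from_k(-0.09)
        vp, p = OscillatorState(0.5), OscillatorState(0.0)
        deltas = [abs(wrap_phase(vp.phase - p.phase))]
        for _ in range(2500):
            vp, p = step_kuramoto(vp, p, cfg, 0.0, cond)
            deltas.append(abs(wrap_phase(vp.phase - p.phase)))
        deltas = np.array(deltas)
        assert np.all(np.diff(deltas) <= 1e-12)
        assert deltas[-1] < 0.02

        def ode(t, y):
            dvp = cfg.omega + 0.09 * cfg.omega * math.sin(y[1] - y[0])
            dp = cfg.omega + 0.15 * cfg.omega * math.sin(y[0] - y[1])
            return [dvp, dp]

        ref = solve_ivp(ode, (0, 2500 * cfg.tick), [0.5, 0.0], rtol=1e-10, atol=1e-12)
        ref_delta = abs(wrap_phase(ref.y[0, -1] - ref.y[1, -1]))
        assert deltas[-1] == pytest.approx(ref_delta, abs=5e-3)

    def test_step_matches_trial_integrator(self):
        """The fast trial loop reproduces repeated step_kuramoto calls exactly."""
        cfg = DyadConfig(phase_noise_sd=0.0)
        cond = Condition.from_k(-0.09)
        trial = simulate_trial(cfg, cond, seed=3)
        vp = OscillatorState(trial.vp_phase[0])
        p = OscillatorState(trial.participant_phase[0])
        for i in range(1, 50):
            vp, p = step_kuramoto(vp, p, cfg, 0.0, cond)
            assert vp.phase == pytest.approx(trial.vp_phase[i], abs=1e-10)
            assert p.phase == pytest.approx(trial.participant_phase[i], abs=1e-10)


class TestEnvelope:
    @pytest.mark.parametrize("phase,expected", [(0.0, 1.0), (np.pi, 0.0)])
    def test_peak_and_trough(self, phase, expected):
        assert phase_to_envelope(phase) == pytest.approx(expected, abs=1e-12)

    def test_bounded_unit_interval(self, rng):
        env = phase_to_envelope(rng.uniform(-np.pi, np.pi, 1000), q=3.0)
        assert np.all(env >= 0) and np.all(env <= 1)

    def test_one_peak_per_cycle_at_3hz(self):
        fs, f0 = 250.0, 3.0
        t = np.arange(int(2 * fs)) / fs  # 2 s = 6 cycles
        # half-cycle offset keeps every peak interior to the series
        env = phase_to_envelope(wrap_phase(2 * np.pi * f0 * t - np.pi))
        peaks, _ = find_peaks(env, height=0.5)
        assert len(peaks) == 6

    def test_sharpening_exponent_validated(self):
        with pytest.raises(ValueError):
            phase_to_envelope(0.0, q=0.5)


class TestTrial:
    def test_series_length_and_rate(self):
        trial = simulate_trial(DyadConfig(), seed=1)
        assert len(trial.vp_phase) == 3500  # 14 s at 250 Hz
        assert trial.fs == 250.0

    def test_identical_start_zero_noise_perfect_locking(self):
        cfg = DyadConfig(phase_noise_sd=0.0)
        cond = Condition.from_k(-0.09)
        from syncspeech.dyad import _integrate

        phi_vp, phi_p = _integrate(cfg, cond, 0.3, 0.3, np.zeros(cfg.n_samples))
        assert plv(phi_vp - phi_p) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_given_seed(self):
        t1 = simulate_trial(DyadConfig(), seed=42)
        t2 = simulate_trial(DyadConfig(), seed=42)
        assert np.array_equal(t1.vp_envelope, t2.vp_envelope)
        assert np.array_equal(t1.participant_phase, t2.participant_phase)

    def test_sync_locks_tighter_than_shifted(self):
        """Monte-Carlo: oscillator-phase PLV higher under the synchrony
        coupling than under the shifted coupling, same seed family."""
        cfg = DyadConfig()
        sync, shifted = Condition.from_k(-0.09), Condition.from_k(0.09)
        wins = 0
        n = 100
        for seed in range(n):
            a = simulate_trial(cfg, sync, seed=seed)
            b = simulate_trial(cfg, shifted, seed=seed)
            wins += plv(a.vp_phase - a.participant_phase) > plv(b.vp_phase - b.participant_phase)
        assert wins >= 0.85 * n


class TestSession:
    def test_thirds_schedule(self):
        session = simulate_session(DyadConfig(seed=5))
        counts = session.log["condition"].value_counts()
        assert counts["sync"] == counts["neutral"] == counts["shifted"] == 8

    def test_neutral_trials_alternate_sign(self):
        session = simulate_session(DyadConfig(seed=5))
        ks = sorted(session.log.loc[session.log.condition == "neutral", "k"].tolist())
        assert ks == [-0.01] * 4 + [0.01] * 4

    def test_indivisible_schedule_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            simulate_session(DyadConfig(n_trials=25))

    def test_session_deterministic(self):
        s1 = simulate_session(DyadConfig(seed=9))
        s2 = simulate_session(DyadConfig(seed=9))
        assert s1.log.equals(s2.log)
        for a, b in zip(s1.trials, s2.trials):
            assert np.array_equal(a.vp_envelope, b.vp_envelope)

    def test_syllable_count_near_thousand(self):
        session = simulate_session(DyadConfig(seed=5))
        n = count_syllable_onsets(session)
        assert abs(n - 24 * 14 * 3) <= 30

    def test_condition_ordering_of_session_mean_plv(self):
        """Mean VCI ordering sync > neutral > shifted over 30 sessions."""
        by_cond = {"sync": [], "neutral": [], "shifted": []}
        for seed in range(30):
            session = simulate_session(DyadConfig(seed=1000 + seed))
            for trial in session.trials:
                v = plv(trial.vp_phase - trial.participant_phase)
                by_cond[trial.condition.name].append(v)
        means = {c: np.mean(v) for c, v in by_cond.items()}
        assert means["sync"] > means["neutral"] > means["shifted"]
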