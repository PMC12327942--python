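"""Coordination metrics: envelope, phase, PLV/VCI, surrogates, delay, contrast."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram
from scipy.stats import kstest

from syncspeech._utils import wrap_phase
from syncspeech.coordination import (
    PhaseSeries,
    compare_conditions,
    compute_vci,
    estimate_delay,
    extract_envelope,
    instantaneous_phase,
    plv_all_shifts,
    split_by_delay,
    surrogate_null,
)
from syncspeech.dyad import DyadConfig, phase_to_envelope, simulate_trial, Condition

FS = 250.0


def _raised_cosine(f0=3.0, dur=14.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return phase_to_envelope(wrap_phase(2 * np.pi * f0 * t)), t


class TestExtractEnvelope:
    def test_3hz_content_dominates(self):
        env, _ = _raised_cosine(3.0)
        out, fs = extract_envelope(env, FS)
        f, p = periodogram(out, fs)
        band = (f >= 2.5) & (f <= 3.5)
        assert p[band].sum() / p.sum() > 0.90

    def test_10hz_attenuated_by_20db(self):
        t = np.arange(int(14 * FS)) / FS
        in3 = np.cos(2 * np.pi * 3 * t)
        in10 = np.cos(2 * np.pi * 10 * t)
        out3, _ = extract_envelope(in3, FS)
        out10, _ = extract_envelope(in10, FS)
        assert 20 * np.log10(out3.std() / out10.std()) >= 20

    def test_dc_removed(self):
        out, _ = extract_envelope(np.full(3500, 0.7), FS)
        assert np.max(np.abs(out)) < 1e-6

    def test_too_short_signal_names_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            extract_envelope(np.ones(100), FS)

    def test_audio_path_resamples_to_control_rate(self):
        fs_audio = 16000.0
        t = np.arange(int(4 * fs_audio)) / fs_audio
        audio = np.cos(2 * np.pi * 200 * t) * (1 + np.cos(2 * np.pi * 3 * t)) / 2
        out, fs = extract_envelope(audio, fs_audio)
        assert fs == 250.0
        f, p = periodogram(out, fs)
        assert abs(f[np.argmax(p)] - 3.0) < 0.3


class TestInstantaneousPhase:
    def test_linear_phase_of_cosine(self):
        t = np.arange(int(14 * FS)) / FS
        ph = instantaneous_phase(np.cos(2 * np.pi * 3 * t), FS)
        inner = slice(200, -200)
        expected = wrap_phase(2 * np.pi * 3 * t)
        err = np.abs(wrap_phase(ph.values[inner] - expected[inner]))
        assert err.max() < 0.05

    def test_quadrature_and_negation_identities(self):
        t = np.arange(int(14 * FS)) / FS
        base = instantaneous_phase(np.cos(2 * np.pi * 3 * t), FS).values
        quad = instantaneous_phase(np.sin(2 * np.pi * 3 * t), FS).values
        neg = instantaneous_phase(-np.cos(2 * np.pi * 3 * t), FS).values
        inner = slice(200, -200)
        assert np.abs(wrap_phase(quad - base + np.pi / 2))[inner].max() < 0.05
        assert np.abs(wrap_phase(neg - base + np.pi))[inner].max() < 0.05

    def test_values_wrapped(self, rng):
        ph = instantaneous_phase(rng.normal(size=1000), FS)
        assert np.all(ph.values > -np.pi) and np.all(ph.values <= np.pi)


class TestVci:
    def test_identical_phases_fully_locked(self, rng):
        a = rng.uniform(-np.pi, np.pi, 1000)
        assert compute_vci(a, a) == pytest.approx(1.0)

    def test_constant_offset_fully_locked(self, rng):
        a = rng.uniform(-np.pi, np.pi, 1000)
        assert compute_vci(a, wrap_phase(a - np.pi / 2)) == pytest.approx(1.0)

    def test_uniform_sweep_vanishes(self):
        n = 3500
        a = wrap_phase(np.linspace(0, 10 * 2 * np.pi, n, endpoint=False))
        assert compute_vci(a, np.zeros(n)) < 1e-6

    def test_matches_complex_mean_oracle(self, rng):
        """PLV equals the direct complex-mean formula to 1e-12 (trig-sum oracle)."""
        for _ in range(100):
            a = rng.uniform(-np.pi, np.pi, 200)
            b = rng.uniform(-np.pi, np.pi, 200)
            d = a - b
            oracle = np.hypot(np.cos(d).mean(), np.sin(d).mean())
            assert compute_vci(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_expected_plv_of_independent_phases(self, rng):
        """E[PLV] ~ sqrt(pi / (4 n)) for n independent uniform differences."""
        n, reps = 500, 4000
        vals = np.abs(np.mean(np.exp(1j * rng.uniform(-np.pi, np.pi, (reps, n))), axis=1))
        assert vals.mean() == pytest.approx(np.sqrt(np.pi / (4 * n)), rel=0.04)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_vci(np.zeros(10), np.zeros(11))

    @given(st.floats(-np.pi, np.pi))
    @settings(derandomize=True, deadline=None, max_examples=25)
    def test_invariant_under_common_rotation(self, rot):
        rng = np.random.default_rng(99)
        a = rng.uniform(-np.pi, np.pi, 300)
        b = rng.uniform(-np.pi, np.pi, 300)
        assert compute_vci(wrap_phase(a + rot), wrap_phase(b + rot)) == pytest.approx(
            compute_vci(a, b), abs=1e-12
        )


class TestSurrogates:
    def test_all_shift_plv_matches_direct_recomputation(self, rng):
        a = rng.uniform(-np.pi, np.pi, 257)
        b = rng.uniform(-np.pi, np.pi, 257)
        allp = plv_all_shifts(a, b)
        for s in range(0, 257, 17):
            assert allp[s] == pytest.approx(compute_vci(a, np.roll(b, s)), abs=1e-12)

    def test_locked_periodic_pair_keeps_p_one(self):
        t = np.arange(3500) / FS
        a = PhaseSeries(2 * np.pi * 3 * t, FS)
        b = PhaseSeries(2 * np.pi * 3 * t - 0.7, FS)
        res = surrogate_null(a, b, n_surrogates=200, seed=0)
        assert res.p_value == pytest.approx(1.0)
        assert np.all(res.null_distribution > 1 - 1e-9)

    def test_coupled_trial_detected(self):
        """Sync-coupled trials beat their surrogate chance level.

        Under the calibrated participant noise the per-trial power is
        moderate (the dyad's mean phase diffuses, widening the circular-shift
        null); coordination above chance is nevertheless detected in a clear
        majority of single trials.
        """
        cfg = DyadConfig()
        detected = 0
        n = 60
        for seed in range(n):
            trial = simulate_trial(cfg, Condition.from_k(-0.09), seed=seed)
            res = surrogate_null(
                PhaseSeries(trial.vp_phase, FS),
                PhaseSeries(trial.participant_phase, FS),
                n_surrogates=200,
                seed=seed,
            )
            detected += res.p_value <= 0.05
        assert detected >= 0.6 * n

    def test_every_simulated_patient_above_chance(self):
        """Combined across a session, coordination is above chance for every
        simulated participant (Stouffer combination of per-trial p-values)."""
        from scipy.stats import norm

        from syncspeech.coordination import analyse_session
        from syncspeech.dyad import simulate_session

        for s in range(3):
            sess = simulate_session(DyadConfig(seed=3000 + s))
            res = analyse_session(sess, n_surrogates=200, seed=s)
            z = norm.isf([min(r.p_value, 0.999) for r in res]).sum() / np.sqrt(len(res))
            assert z > 3.0

    def test_null_p_values_uniform(self, rng):
        """Surrogate p roughly uniform for independent random-walk phases."""
        ps = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            a = wrap_phase(np.cumsum(r.normal(0.075, 0.15, 3500)))
            b = wrap_phase(np.cumsum(r.normal(0.075, 0.15, 3500)))
            ps.append(surrogate_null(a, b, n_surrogates=100, seed=seed, fs=FS).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestDelay:
    def test_zero_lag_for_identical_envelopes(self):
        env, _ = _raised_cosine()
        assert estimate_delay(env, env) == 0.0

    def test_constructed_50ms_lead_detected(self):
        env, _ = _raised_cosine()
        lead = int(0.05 * FS)
        participant = np.roll(env, -lead)  # participant events 50 ms early
        assert estimate_delay(env, participant) == pytest.approx(-0.050, abs=0.004)

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            estimate_delay(np.ones(1000), np.ones(1000))


class TestDelaySplit:
    def test_even_split(self):
        labels = split_by_delay([-0.030, -0.010, 0.010, 0.030])
        assert list(labels) == ["anticipatory", "anticipatory", "compensatory", "compensatory"]

    def test_ties_go_anticipatory(self):
        assert set(split_by_delay([0.01] * 6)) == {"anticipatory"}

    def test_class_sizes_balanced(self, rng):
        delays = rng.normal(0, 0.02, 24)
        labels = split_by_delay(delays)
        n_a = np.sum(labels == "anticipatory")
        assert abs(n_a - (24 - n_a)) <= 1


class TestConditionContrast:
    def test_identical_vectors_null_effect(self):
        vci = np.array([0.5] * 8 + [0.5] * 8)
        labels = np.array(["sync"] * 8 + ["shifted"] * 8)
        res = compare_conditions(vci, labels, n_perm=200, seed=0)
        assert res.effect == 0.0
        assert res.p_value > 0.9

    def test_shuffled_labels_rejection_near_alpha(self, rng):
        rejections = 0
        n_runs = 200
        for i in range(n_runs):
            r = np.random.default_rng(i)
            vci = r.uniform(0, 1, 16)
            labels = r.permutation(["sync"] * 8 + ["shifted"] * 8)
            res = compare_conditions(vci, labels, n_perm=200, seed=i)
            rejections += res.p_value <= 0.05
        assert 0.01 <= rejections / n_runs <= 0.10

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="present"):
            compare_conditions([0.1, 0.2], ["sync", "sync"])
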