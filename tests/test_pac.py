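"""Phase-amplitude coupling: HFa extraction, MVL metric, surrogates, ROI tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, pearsonr

from syncspeech._utils import wrap_phase
from syncspeech.pac import (
    DelaySplitPac,
    _mvl_all_shifts,
    behaviour_phase,
    compare_pac_types,
    compute_pac,
    hfa_amplitude,
    pac_by_delay_sign,
    pac_vs_surrogates,
)
from syncspeech.preprocess import EpochSet
from syncspeech.dyad import DyadConfig, simulate_trial


def _epochs(data, fs=1000.0, kind="rest"):
    times = np.arange(data.shape[2]) / fs
    return EpochSet(data, times, fs, kind, pd.DataFrame())


class TestHfaAmplitude:
    def test_100hz_tone_amplitude_recovered(self):
        fs = 1000.0
        t = np.arange(int(6 * fs)) / fs
        x = 2.5 * np.sin(2 * np.pi * 100 * t)[None, None, :]
        amp = hfa_amplitude(_epochs(x))
        inner = amp[0, 0, 100:-100]
        assert inner.mean() == pytest.approx(2.5, rel=0.10)

    def test_10hz_tone_suppressed(self):
        fs = 1000.0
        t = np.arange(int(6 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t)[None, None, :]
        amp = hfa_amplitude(_epochs(x))
        assert amp[0, 0, 100:-100].mean() < 0.1  # >= 20 dB below unit input

    def test_modulated_carrier_tracks_modulator(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        mod = 1.0 + 0.8 * np.cos(2 * np.pi * 3 * t)
        x = (mod * np.sin(2 * np.pi * 100 * t))[None, None, :]
        amp = hfa_amplitude(_epochs(x))[0, 0]
        mod250 = mod[::4][100:-100]
        r = pearsonr(amp[100:-100], mod250).statistic
        assert r >= 0.95

    def test_output_at_control_rate(self, rng):
        amp = hfa_amplitude(_epochs(rng.normal(size=(2, 3, 4000))))
        assert amp.shape == (2, 3, 1000)


class TestBehaviourPhase:
    def test_identical_speakers_zero_difference(self):
        trial = simulate_trial(DyadConfig(phase_noise_sd=0.0, k_participant=0.15), seed=0)
        trial.participant_envelope = trial.vp_envelope.copy()
        ph = behaviour_phase(trial, "phase_difference")
        assert np.abs(ph.values).max() < 1e-9

    def test_vp_speech_cycles_at_3hz(self):
        trial = simulate_trial(DyadConfig(phase_noise_sd=0.0), seed=1)
        ph = behaviour_phase(trial, "vp_speech")
        cycles = np.unwrap(ph.values)[-1] - np.unwrap(ph.values)[0]
        assert cycles / (2 * np.pi) == pytest.approx(3.0 * 14, rel=0.05)

    def test_unknown_mode_rejected(self):
        trial = simulate_trial(DyadConfig(), seed=2)
        with pytest.raises(ValueError, match="mode"):
            behaviour_phase(trial, "bogus")


class TestComputePac:
    def test_constant_amplitude_vanishes(self):
        t = np.arange(3500) / 250.0
        ph = wrap_phase(2 * np.pi * 3 * t)
        assert compute_pac(ph, np.ones_like(ph)) < 0.05

    def test_analytic_half_for_cosine_modulation(self):
        """amplitude = 1 + cos(phase) gives PAC = 1/2 exactly in the
        continuous limit (integral identity), within 0.02 at 14 s x 3 Hz."""
        t = np.arange(int(14 * 250)) / 250.0
        ph = wrap_phase(2 * np.pi * 3 * t)
        pac = compute_pac(ph, 1.0 + np.cos(ph))
        assert pac == pytest.approx(0.5, abs=0.02)

    def test_phase_offset_invariance(self):
        t = np.arange(3500) / 250.0
        ph = wrap_phase(2 * np.pi * 3 * t)
        a = compute_pac(ph, 1.0 + np.cos(ph))
        b = compute_pac(ph, 1.0 + np.cos(wrap_phase(ph + np.pi)))
        assert a == pytest.approx(b, abs=1e-12)

    def test_amplitude_rescaling_invariance(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 2000)
        amp = rng.lognormal(size=2000)
        assert compute_pac(ph, amp) == pytest.approx(compute_pac(ph, 42.0 * amp), abs=1e-12)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compute_pac(np.zeros(100), np.zeros(100))

    def test_tort_metric_detects_same_modulation(self):
        t = np.arange(int(14 * 250)) / 250.0
        ph = wrap_phase(2 * np.pi * 3 * t)
        mod = compute_pac(ph, 1.0 + np.cos(ph), metric="tort")
        flat = compute_pac(ph, np.ones_like(ph), metric="tort")
        assert mod > 10 * max(flat, 1e-6)


class TestSurrogates:
    def test_all_shift_mvl_matches_direct(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 311)
        a = rng.lognormal(size=311)
        allv = _mvl_all_shifts(ph, a)
        for s in range(0, 311, 23):
            assert allv[s] == pytest.approx(compute_pac(ph, np.roll(a, s)), abs=1e-12)

    def test_strictly_periodic_phase_null_is_degenerate(self):
        """For an exactly linear periodic phase every circular amplitude
        shift yields the same mean vector length (the phasor is a pure
        complex exponential), so the surrogate test is conservative (p = 1).
        Realistic behavioural phases are irregular and avoid this."""
        t = np.arange(int(14 * 250)) / 250.0
        ph = wrap_phase(2 * np.pi * 3 * t)
        r = np.random.default_rng(0)
        amp = (1 + 0.5 * np.cos(ph)) * r.lognormal(0, 0.3, len(ph))
        res = pac_vs_surrogates(ph, amp, n_surrogates=100, seed=0, fs=250.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.pct_increase == pytest.approx(0.0, abs=1e-6)

    def test_injected_coupling_detected_on_simulated_phase(self):
        """Modulation by the phase of a simulated trial's speech envelope is
        detected against circular-shift surrogates."""
        detected = 0
        n = 20
        for seed in range(n):
            trial = simulate_trial(DyadConfig(), seed=seed)
            ph = behaviour_phase(trial, "vp_speech").values
            r = np.random.default_rng(seed)
            amp = (1 + 0.5 * np.cos(ph)) * r.lognormal(0, 0.3, len(ph))
            res = pac_vs_surrogates(ph, amp, n_surrogates=200, seed=seed, fs=250.0)
            detected += res.p_value <= 0.05
        assert detected >= 0.9 * n

    def test_null_p_uniform_on_simulated_phase(self):
        ps = []
        for seed in range(200):
            trial = simulate_trial(DyadConfig(), seed=5000 + seed)
            ph = behaviour_phase(trial, "vp_speech").values
            r = np.random.default_rng(seed)
            amp = r.lognormal(0, 0.3, len(ph))
            ps.append(pac_vs_surrogates(ph, amp, n_surrogates=100, seed=seed, fs=250.0).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestRoiComparison:
    def test_identical_pairs_give_p_one(self):
        df = pd.DataFrame(
            {
                "roi": ["STG_BA22"] * 12,
                "channel": [f"c{i}" for i in range(6)] * 2,
                "phase_source": ["vp_speech"] * 6 + ["phase_difference"] * 6,
                "pac": [0.3] * 12,
                "pct_increase": [50.0] * 12,
            }
        )
        res = compare_pac_types(df)
        assert res.loc[0, "p"] == 1.0
        assert res.loc[0, "direction"] == "none"

    def test_direction_reported(self):
        df = pd.DataFrame(
            {
                "roi": ["IFG_BA44"] * 12,
                "channel": [f"c{i}" for i in range(6)] * 2,
                "phase_source": ["vp_speech"] * 6 + ["phase_difference"] * 6,
                "pac": np.r_[np.full(6, 0.1), np.full(6, 0.4)],
                "pct_increase": np.r_[np.arange(6) + 1.0, np.arange(6) + 30.0],
            }
        )
        res = compare_pac_types(df)
        assert res.loc[0, "direction"] == "phase_difference"
        assert res.loc[0, "p"] <= 0.05


class TestDelaySplitPac:
    def _session(self, n_trials=8, depth_anticipatory=0.0, seed=0):
        cfg = DyadConfig(phase_noise_sd=0.0)
        trials = [simulate_trial(cfg, seed=seed + i) for i in range(n_trials)]
        rng = np.random.default_rng(seed)
        n_amp = 3550  # epoch samples at 250 Hz (-0.2 to 14 s)
        hfa = np.empty((n_trials, 1, n_amp))
        labels = np.array(["anticipatory", "compensatory"] * (n_trials // 2))
        for i, tr in enumerate(trials):
            base = rng.lognormal(0, 0.3, n_amp)
            if labels[i] == "anticipatory" and depth_anticipatory > 0:
                ph = behaviour_phase(tr, "vp_speech").values
                mod = np.ones(n_amp)
                mod[175 : 175 + len(ph) - 125] = 1 + depth_anticipatory * np.cos(ph[125:])
                base = base * mod
            hfa[i, 0] = base
        return trials, hfa, labels

    def test_asymmetric_coupling_detected(self):
        trials, hfa, labels = self._session(depth_anticipatory=0.6, seed=3)
        res = pac_by_delay_sign(trials, hfa, 0, labels, mode="vp_speech",
                                n_perm=400, seed=3)
        assert res.difference > 0
        assert res.p_value <= 0.05

    def test_single_trial_class_skipped(self):
        trials, hfa, _ = self._session(seed=4)
        labels = np.array(["anticipatory"] + ["compensatory"] * 7)
        with pytest.warns(UserWarning, match="skipped"):
            assert pac_by_delay_sign(trials, hfa, 0, labels) is None

    def test_same_process_rejection_near_alpha(self):
        """With both classes drawn from the same process the permutation test
        rejects at roughly the nominal rate."""
        rejections = 0
        n_runs = 25
        for seed in range(n_runs):
            trials, hfa, labels = self._session(depth_anticipatory=0.0, seed=100 + seed)
            res = pac_by_delay_sign(trials, hfa, 0, labels, mode="vp_speech",
                                    n_perm=200, seed=seed)
            rejections += res.p_value <= 0.05
        assert rejections <= 4  # ~alpha of 25, generous margin
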