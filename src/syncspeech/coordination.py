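"""Behavioural coordination metrics.

Implements the speech-signal analysis chain: band-limited (2.25-5 Hz) speech
envelope extraction, instantaneous Hilbert phase, the verbal coordination
index (VCI; the phase-locking value between the two speakers' envelope
phases), its surrogate chance level by circular time-shifting, the
cross-correlation delay between speakers, the anticipatory/compensatory
median split, and the condition contrast with a label-permutation test.

The surrogate machinery evaluates the PLV at *every* circular shift in a
single FFT pass (the PLV at shift s is a circular cross-correlation of the
two unit-phasor series), then samples the requested number of random shifts
from it; this is numerically identical to recomputing each surrogate
directly, which the tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, correlate, correlation_lags, hilbert, resample_poly, sosfiltfilt

from ._utils import plv as _plv_direct
from ._utils import wrap_phase

SPEECH_BAND = (2.25, 5.0)  # Hz, syllable-rate band of the speech envelope
CONTROL_RATE = 250.0  # Hz, envelope/behaviour sample rate
AUDIO_RATE = 16_000.0  # Hz, raw audio is first brought to this rate


@dataclass
class PhaseSeries:
    """Wrapped instantaneous-phase series with its sample rate and source label."""

    values: np.ndarray
    sample_rate: float
    source: str = "vp"  # vp | participant | difference

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values > np.pi) or np.any(self.values <= -np.pi):
            self.values = wrap_phase(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CoordinationResult:
    """Per-trial coordination summary: VCI, surrogate null, p-value, delay."""

    trial_index: int
    vci: float
    null_distribution: np.ndarray
    p_value: float
    delay_s: float
    condition: str = ""


def _min_samples(fs: float) -> int:
    # three time constants of the 2.25 Hz high-pass edge
    return int(np.ceil(3.0 * fs / SPEECH_BAND[0]))


def extract_envelope(signal, fs: float):
    """Band-limited (2.25-5 Hz) speech envelope at the 250 Hz control rate.

    For raw audio (fs > 1 kHz): resample to 16 kHz, take the magnitude of the
    analytic signal, low-pass at 40 Hz, decimate to 250 Hz, then zero-phase
    band-pass 2.25-5 Hz. For already-extracted envelopes at the control rate,
    only the zero-phase band-pass applies. The mean is removed.

    Returns ``(envelope, 250.0)``.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if fs <= 10:
        raise ValueError("sample rate must exceed 10 Hz")
    if fs > 1000.0:
        if fs != AUDIO_RATE:
            x = resample_poly(x, int(AUDIO_RATE), int(round(fs)))
        env = np.abs(hilbert(x))
        sos_lp = butter(4, 40.0, btype="low", fs=AUDIO_RATE, output="sos")
        env = sosfiltfilt(sos_lp, env)
        env = resample_poly(env, int(CONTROL_RATE), int(AUDIO_RATE))
        fs = CONTROL_RATE
    elif fs != CONTROL_RATE:
        x = resample_poly(x, int(CONTROL_RATE), int(round(fs)))
        fs = CONTROL_RATE
        env = x
    else:
        env = x
    need = _min_samples(fs)
    if len(env) < need:
        raise ValueError(
            f"signal too short for the {SPEECH_BAND[0]}-{SPEECH_BAND[1]} Hz band-pass: "
            f"need at least {need} samples at {fs:g} Hz ({need / fs:.2f} s)"
        )
    sos = butter(4, SPEECH_BAND, btype="bandpass", fs=fs, output="sos")
    out = sosfiltfilt(sos, env - env.mean())
    return out - out.mean(), fs


def instantaneous_phase(envelope, fs: float = CONTROL_RATE, source: str = "vp") -> PhaseSeries:
    """Instantaneous phase of a band-limited envelope via the Hilbert transform."""
    env = np.asarray(envelope, dtype=float)
    return PhaseSeries(wrap_phase(np.angle(hilbert(env))), fs, source)


def _as_phase(p) -> np.ndarray:
    return p.values if isinstance(p, PhaseSeries) else np.asarray(p, dtype=float)


def compute_vci(phase_a, phase_b) -> float:
    """Verbal coordination index: PLV between two wrapped phase series.

    PLV = | mean_t exp(i (phi_a - phi_b)) |, in [0, 1].
    """
    a, b = _as_phase(phase_a), _as_phase(phase_b)
    if len(a) != len(b):
        raise ValueError(f"phase series length mismatch: {len(a)} vs {len(b)}")
    if (
        isinstance(phase_a, PhaseSeries)
        and isinstance(phase_b, PhaseSeries)
        and phase_a.sample_rate != phase_b.sample_rate
    ):
        raise ValueError("phase series sample rates differ")
    return _plv_direct(a - b)


def plv_all_shifts(phase_a, phase_b) -> np.ndarray:
    """PLV between phase_a and phase_b circularly delayed by every shift s.

    Computed in one FFT pass: out[s] = |(1/n) sum_t exp(i phi_a[t]) *
    exp(-i phi_b[t - s])|, identical to shifting phase_b sample-wise.
    """
    a, b = _as_phase(phase_a), _as_phase(phase_b)
    n = len(a)
    u = np.exp(1j * a)
    v = np.exp(-1j * b)
    # out[s] = (1/n) sum_t u[t] v[t-s]  (circular) -- a convolution of u with
    # the circularly time-reversed v, evaluated for all s at once.
    v_rev = np.roll(v[::-1], 1)
    out = np.fft.ifft(np.fft.fft(u) * np.fft.fft(v_rev)) / n
    return np.abs(out)


@dataclass
class SurrogateResult:
    vci: float
    null_distribution: np.ndarray
    p_value: float
    shifts_s: np.ndarray = field(default_factory=lambda: np.empty(0))


def surrogate_null(
    phase_a,
    phase_b,
    n_surrogates: int = 500,
    seed: int = 0,
    min_shift_s: float = 0.5,
    fs: float | None = None,
) -> SurrogateResult:
    """Chance level of the VCI by random circular time-shifts of phase_b.

    Each surrogate shifts phase_b by a uniform random offset at least
    ``min_shift_s`` away from zero (in either direction) and recomputes the
    PLV. p = (1 + #{null >= observed}) / (1 + n_surrogates).
    """
    a, b = _as_phase(phase_a), _as_phase(phase_b)
    if fs is None:
        fs = phase_a.sample_rate if isinstance(phase_a, PhaseSeries) else CONTROL_RATE
    n = len(a)
    m = int(round(min_shift_s * fs))
    if n <= 2 * m:
        raise ValueError("series too short for the minimum surrogate shift")
    obs = compute_vci(a, b)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(m, n - m, size=n_surrogates, endpoint=True)
    null = plv_all_shifts(a, b)[shifts]
    # tolerance so exact ties (e.g. a perfectly locked periodic pair) count as >=
    p = (1.0 + np.sum(null >= obs - 1e-12)) / (1.0 + n_surrogates)
    return SurrogateResult(obs, null, float(p), shifts / fs)


def estimate_delay(env_vp, env_p, fs: float = CONTROL_RATE, max_lag_s: float = 0.3) -> float:
    """Signed lag (s) of the cross-correlation maximum within +/- max_lag_s.

    Negative values mean the participant leads the VP (anticipatory
    behaviour); positive values mean the participant trails (compensatory).
    """
    a = np.asarray(env_vp, dtype=float)
    b = np.asarray(env_p, dtype=float)
    if len(a) != len(b):
        raise ValueError("envelope length mismatch")
    a = a - a.mean()
    b = b - b.mean()
    if np.max(np.abs(a)) == 0 or np.max(np.abs(b)) == 0:
        raise ValueError("flat envelope: delay undefined")
    # c[lag] = sum_t env_p[t + lag] * env_vp[t]; if the participant reproduces
    # the VP delayed by d (env_p[t] = env_vp[t - d]) the maximum sits at +d.
    c = correlate(b, a, mode="full")
    lags = correlation_lags(len(b), len(a), mode="full")
    w = int(round(max_lag_s * fs))
    keep = np.abs(lags) <= w
    return float(lags[keep][np.argmax(c[keep])] / fs)


def split_by_delay(delays) -> np.ndarray:
    """Median split of per-trial delays into behavioural classes.

    Trials at or below the (participant-specific) median are labelled
    ``anticipatory``; trials strictly above it ``compensatory``. Ties at the
    median go to the anticipatory class (fixed, documented tie-break).
    """
    d = np.asarray(delays, dtype=float)
    if len(d) < 4:
        raise ValueError("need at least 4 trials for a median split")
    med = np.median(d)
    return np.where(d <= med, "anticipatory", "compensatory")


@dataclass
class ConditionContrast:
    effect: float  # mean VCI difference, condition a minus condition b
    p_value: float
    mean_a: float
    mean_b: float
    n_perm: int


def compare_conditions(
    vci,
    labels,
    cond_a: str = "sync",
    cond_b: str = "shifted",
    n_perm: int = 1000,
    seed: int = 0,
) -> ConditionContrast:
    """Contrast per-trial VCI between two coupling conditions.

    Statistic: difference of condition means (a - b). Significance: two-sided
    permutation of the condition labels (N = n_perm, seeded), with the +1
    finite-permutation correction.
    """
    v = np.asarray(vci, dtype=float)
    lab = np.asarray(labels)
    mask = (lab == cond_a) | (lab == cond_b)
    if not np.any(lab == cond_a) or not np.any(lab == cond_b):
        raise ValueError(f"both conditions {cond_a!r} and {cond_b!r} must be present")
    v = v[mask]
    is_a = lab[mask] == cond_a
    n_a = int(is_a.sum())
    obs = float(v[is_a].mean() - v[~is_a].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(v))
        pa = v[perm[:n_a]]
        pb = v[perm[n_a:]]
        null[i] = pa.mean() - pb.mean()
    p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (1.0 + n_perm)
    return ConditionContrast(obs, float(p), float(v[is_a].mean()), float(v[~is_a].mean()), n_perm)


def analyse_session(session, n_surrogates: int = 500, seed: int = 0) -> list[CoordinationResult]:
    """Run the full per-trial coordination analysis on a simulated session.

    For each trial: band-limit both envelopes, extract phases, compute the
    VCI, its surrogate null and p-value, and the cross-correlation delay.
    """
    results = []
    seeds = np.random.SeedSequence(seed).generate_state(len(session.trials)) % (2**31)
    for i, trial in enumerate(session.trials):
        env_vp, fs = extract_envelope(trial.vp_envelope, trial.fs)
        env_p, _ = extract_envelope(trial.participant_envelope, trial.fs)
        pa = instantaneous_phase(env_vp, fs, "vp")
        pb = instantaneous_phase(env_p, fs, "participant")
        sur = surrogate_null(pa, pb, n_surrogates=n_surrogates, seed=int(seeds[i]))
        delay = estimate_delay(env_vp, env_p, fs)
        results.append(
            CoordinationResult(
                trial_index=trial.trial_index,
                vci=sur.vci,
                null_distribution=sur.null_distribution,
                p_value=sur.p_value,
                delay_s=delay,
                condition=trial.condition.name,
            )
        )
    return results
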