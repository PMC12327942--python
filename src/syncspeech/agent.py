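"""Offline re-implementation of the adaptive virtual partner's control loop.

The agent runs a loop at a fixed 4 ms tick. Each iteration it:

1. extracts a feature vector from the latest 25 ms chunk of the incoming
   (participant) envelope;
2. estimates the participant's position in the syllabic cycle by aligning the
   recent feature history to one or more model utterances with dynamic time
   warping (DTW) and reading off the phase of the best-matching model instant;
3. applies a Kuramoto-style control law to the phase difference, converting it
   into a playback-rate multiplier (chunk lengthening/shortening);
4. advances its read position in the stimulus at that rate and emits the
   interpolated stimulus sample (cyclic repetition at the stimulus end).

The original system streamed real audio and resynthesised it with WSOLA;
here the loop operates directly on 250 Hz speech envelopes, with interpolated
cyclic read-out in place of waveform synthesis — sufficient for every
downstream envelope-domain analysis. The envelope feature vector (mean,
mean first difference, RMS) is an engineering choice and a documented swap
point; the real system's features are unspecified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._utils import TWO_PI, wrap_phase
from .dyad import OMEGA_DEFAULT, phase_to_envelope


@dataclass
class AgentConfig:
    """Control-loop parameters of the virtual partner.

    tick: loop interval (s); the envelope control rate is 1/tick = 250 Hz.
    chunk_len: analysis window (s) for feature extraction (25 ms).
    history_len: length (s) of the feature history aligned by DTW.
    k: coupling strength; its magnitude scales the rate correction.
    preferred_phase: target offset psi of (participant phase - VP phase).
    n_model_utterances: stored templates used for the phase lookup.
    rate_min/rate_max: clamp on the playback-rate multiplier.
    silence_rms: chunk RMS below which the agent dead-reckons phase at omega.
    dtw_stride: run the DTW lookup every this many ticks (dead-reckoning in
        between); 1 reproduces the per-tick loop of the original system.
    """

    tick: float = 0.004
    chunk_len: float = 0.025
    history_len: float = 0.25
    k: float = -0.09
    preferred_phase: float = 0.0
    n_model_utterances: int = 3
    rate_min: float = 0.5
    rate_max: float = 2.0
    omega: float = OMEGA_DEFAULT
    silence_rms: float = 1e-4
    dtw_stride: int = 1

    def __post_init__(self) -> None:
        if self.chunk_len < self.tick:
            raise ValueError("chunk_len must be >= tick")
        if self.n_model_utterances < 1:
            raise ValueError("need at least one model utterance")

    @property
    def fs(self) -> float:
        return 1.0 / self.tick

    @property
    def chunk_samples(self) -> int:
        return max(2, int(round(self.chunk_len * self.fs)))

    @property
    def history_samples(self) -> int:
        return max(2, int(round(self.history_len * self.fs)))


@dataclass
class ModelUtterance:
    """A stimulus-aligned template: envelope, per-tick features and phase map.

    ``phase`` assigns each stimulus instant its position in the syllabic
    cycle; ``phase_unwrapped`` is the monotone version used for interpolated
    read-out. Feature and phase sequences have one entry per tick.
    """

    envelope: np.ndarray
    phase: np.ndarray
    features: np.ndarray  # (n_ticks, 3)
    fs: float = 250.0

    def __post_init__(self) -> None:
        if len(self.envelope) != len(self.phase) or len(self.features) != len(self.phase):
            raise ValueError("feature and phase sequences must be equal length")
        self.phase = wrap_phase(np.asarray(self.phase, dtype=float))
        self.phase_unwrapped = np.unwrap(self.phase)
        if np.any(np.diff(self.phase_unwrapped) < 0):
            raise ValueError("model phase must be monotonically increasing before wrapping")

    def __len__(self) -> int:
        return len(self.envelope)


@dataclass
class AgentState:
    """Mutable loop state: stimulus read position (samples), VP phase, rate."""

    stimulus_position: float = 0.0
    vp_phase: float = 0.0
    rate: float = 1.0


def extract_features(chunk) -> np.ndarray:
    """Fixed-length feature vector of an envelope chunk.

    Components: mean amplitude, mean first difference, RMS. Deterministic;
    an all-zero chunk maps to the zero vector.
    """
    c = np.asarray(chunk, dtype=float)
    if len(c) < 2:
        raise ValueError("chunk too short for feature extraction")
    return np.array([c.mean(), np.diff(c).mean(), math.sqrt(float(np.mean(c * c)))])


def _feature_sequence(envelope: np.ndarray, chunk_samples: int) -> np.ndarray:
    """Per-tick features of the trailing chunk ending at each sample
    (zero-padded at the stream start)."""
    n = len(envelope)
    padded = np.concatenate([np.zeros(chunk_samples - 1), envelope])
    feats = np.empty((n, 3))
    for i in range(n):
        feats[i] = extract_features(padded[i : i + chunk_samples])
    return feats


@njit(cache=True)
def _subseq_dtw(history, model):  # pragma: no cover - exercised via wrapper
    """Open-begin subsequence DTW: best end column and its cumulative cost.

    D[i, j] = d(i, j) + min(D[i-1, j], D[i-1, j-1], D[i, j-1]) with a free
    start along the model (D[0, :] = 0); returns (best_cost, best_end_index)
    over the final history row. Ties break toward the earliest model index.
    """
    H = history.shape[0]
    M = model.shape[0]
    F = history.shape[1]
    prev = np.zeros(M)
    curr = np.empty(M)
    for i in range(H):
        for j in range(M):
            d = 0.0
            for f in range(F):
                diff = history[i, f] - model[j, f]
                d += diff * diff
            d = math.sqrt(d)
            best = prev[j]
            if j > 0:
                if prev[j - 1] < best:
                    best = prev[j - 1]
                if curr[j - 1] < best:
                    best = curr[j - 1]
            curr[j] = d + best
        for j in range(M):
            prev[j] = curr[j]
    best_j = 0
    best_c = prev[0]
    for j in range(1, M):
        if prev[j] < best_c:
            best_c = prev[j]
            best_j = j
    return best_c, best_j


def dtw_phase_lookup(history, models) -> float:
    """Phase of the model instant to which the history endpoint aligns.

    The recent feature history (one vector per tick) is aligned to each model
    utterance by subsequence DTW (the model is tiled twice so alignments may
    wrap the cyclic stimulus boundary); the model with the lowest alignment
    cost wins, ties broken by model order, and the phase at the best end
    column is returned, wrapped to (-pi, pi].
    """
    hist = np.ascontiguousarray(np.atleast_2d(np.asarray(history, dtype=float)))
    if hist.shape[0] == 0:
        raise ValueError("empty feature history")
    if not models:
        raise ValueError("need at least one model utterance")
    best = (np.inf, 0, 0)  # cost, model index, end column
    for mi, model in enumerate(models):
        tiled = np.ascontiguousarray(np.vstack([model.features, model.features]))
        cost, j = _subseq_dtw(hist, tiled)
        if cost < best[0]:
            best = (cost, mi, j)
    model = models[best[1]]
    return float(model.phase[best[2] % len(model)])


def build_stimulus(
    n_syllables: int = 6,
    fs: float = 250.0,
    syllable_rate: float = 3.0,
    q: float = 2.0,
    syllable_gains=None,
    chunk_samples: int = 6,
) -> ModelUtterance:
    """Synthetic stimulus utterance: a train of raised-cosine syllables.

    ``syllable_gains`` (one per syllable) imitates the amplitude variation of
    a natural sentence; the phase map is the underlying syllabic phase.
    """
    n = int(round(n_syllables * fs / syllable_rate))
    t = np.arange(n) / fs
    phase = wrap_phase(TWO_PI * syllable_rate * t)
    env = phase_to_envelope(phase, q)
    if syllable_gains is not None:
        gains = np.asarray(syllable_gains, dtype=float)
        idx = np.minimum((t * syllable_rate).astype(int), len(gains) - 1)
        env = env * gains[idx]
    return ModelUtterance(env, phase, _feature_sequence(env, chunk_samples), fs)


def make_model_utterances(
    stimulus: ModelUtterance, n: int = 3, seed: int = 0, jitter: float = 0.08
) -> list[ModelUtterance]:
    """Derive n templates from the stimulus with smooth amplitude jitter,
    standing in for the speaker-tailored model utterances of the real system.
    The first model is the stimulus itself."""
    models = [stimulus]
    rng = np.random.default_rng(seed)
    m = len(stimulus)
    chunk = stimulus.features.shape[0] and max(2, int(round(0.025 * stimulus.fs)))
    for _ in range(n - 1):
        nodes = rng.normal(1.0, jitter, size=8)
        gain = np.interp(np.arange(m), np.linspace(0, m - 1, 8), nodes)
        env = stimulus.envelope * np.clip(gain, 0.5, 1.5)
        models.append(ModelUtterance(env, stimulus.phase.copy(), _feature_sequence(env, chunk), stimulus.fs))
    return models


def control_step(state: AgentState, participant_phase: float, config: AgentConfig, stimulus: ModelUtterance) -> AgentState:
    """One tick of the rate-control law.

    rate = 1 + |k| * sin(participant_phase - vp_phase - psi), clamped to
    [rate_min, rate_max]; the stimulus position advances by rate * 1 sample
    (the control rate equals the envelope rate) and the VP phase is re-read
    from the stimulus phase map at the new position (cyclic).
    """
    err = participant_phase - state.vp_phase - config.preferred_phase
    rate = 1.0 + abs(config.k) * math.sin(err)
    rate = min(max(rate, config.rate_min), config.rate_max)
    pos = state.stimulus_position + rate
    vp_phase = _read_phase(stimulus, pos)
    return AgentState(stimulus_position=pos, vp_phase=vp_phase, rate=rate)


def _read_phase(stimulus: ModelUtterance, pos: float) -> float:
    """Interpolated syllabic phase at a fractional (cyclic) stimulus position."""
    m = len(stimulus)
    cycles, frac_pos = divmod(pos, m)
    i = int(frac_pos)
    frac = frac_pos - i
    pu = stimulus.phase_unwrapped
    if i + 1 < m:
        ph = pu[i] + frac * (pu[i + 1] - pu[i])
    else:
        step = pu[-1] - pu[-2] if m > 1 else 0.0
        ph = pu[i] + frac * step
    return float(wrap_phase(ph))


def _read_envelope(stimulus: ModelUtterance, pos: float) -> float:
    m = len(stimulus)
    frac_pos = pos % m
    i = int(frac_pos)
    frac = frac_pos - i
    e = stimulus.envelope
    return float(e[i] + frac * (e[(i + 1) % m] - e[i]))


@dataclass
class AgentTrace:
    """Output of a closed- or open-loop agent run."""

    vp_envelope: np.ndarray
    vp_phase: np.ndarray
    participant_phase_est: np.ndarray
    rate: np.ndarray

    def as_frame(self):
        import pandas as pd

        n = len(self.rate)
        return pd.DataFrame(
            {
                "tick": np.arange(n),
                "vp_phase": self.vp_phase,
                "participant_phase_est": self.participant_phase_est,
                "delta_phase": wrap_phase(self.participant_phase_est - self.vp_phase),
                "rate": self.rate,
            }
        )


def run_agent(
    participant_envelope,
    stimulus: ModelUtterance,
    config: AgentConfig,
    models: list[ModelUtterance] | None = None,
    seed: int = 0,
) -> AgentTrace:
    """Run the agent over a participant envelope at the control rate.

    One control step per tick. When the input chunk is silent (RMS below
    ``silence_rms``) the participant phase is dead-reckoned at omega, so a
    silent input yields the unwarped stimulus cycle. Output duration equals
    input duration.
    """
    env_in = np.asarray(participant_envelope, dtype=float)
    n = len(env_in)
    if len(stimulus) < config.chunk_samples:
        raise ValueError("stimulus shorter than one analysis chunk")
    if models is None:
        models = make_model_utterances(stimulus, config.n_model_utterances, seed=seed)

    chunk_n = config.chunk_samples
    hist_n = config.history_samples
    feats = _feature_sequence(env_in, chunk_n)
    d_phase = config.omega * config.tick

    state = AgentState(stimulus_position=0.0, vp_phase=float(stimulus.phase[0]), rate=1.0)
    p_phase = float(stimulus.phase[0])
    out_env = np.empty(n)
    out_vp_phase = np.empty(n)
    out_p_phase = np.empty(n)
    out_rate = np.empty(n)

    padded = np.concatenate([np.zeros(chunk_n - 1), env_in])
    for t in range(n):
        out_env[t] = _read_envelope(stimulus, state.stimulus_position)
        out_vp_phase[t] = state.vp_phase
        chunk = padded[t : t + chunk_n]
        rms = math.sqrt(float(np.mean(chunk * chunk)))
        if rms < config.silence_rms:
            if t > 0:  # the initial estimate is already the phase at t = 0
                p_phase = float(wrap_phase(p_phase + d_phase))
        elif t % config.dtw_stride == 0:
            lo = max(0, t + 1 - hist_n)
            p_phase = dtw_phase_lookup(feats[lo : t + 1], models)
        else:
            p_phase = float(wrap_phase(p_phase + d_phase))
        out_p_phase[t] = p_phase
        state = control_step(state, p_phase, config, stimulus)
        out_rate[t] = state.rate
    return AgentTrace(out_env, out_vp_phase, out_p_phase, out_rate)
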