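"""Dyad simulator: a virtual partner (VP) and a participant as mutually coupled
phase oscillators producing syllable-rate speech envelopes.

The synchronous-speech task is modelled at the level of the syllabic cycle.
Each speaker is a phase oscillator with natural frequency ~3 Hz (the task's
syllable rate). The VP adjusts its phase toward the participant with a
condition-dependent coupling strength ``k``:

* ``k = -0.09`` — moderate coupling toward synchrony (preferred offset 0),
* ``k = +/-0.01`` — neutral, near-zero coupling,
* ``k = +0.09`` — moderate coupling toward an anti-phase ("180° shift")
  relation, i.e. the VP aims to place its syllables between those of the
  participant.

The participant is modelled symmetrically as an oscillator attracted toward
the VP (coupling ``k_participant``) with Wiener phase noise representing human
timing variability. Phases map to syllable-like amplitude envelopes through a
sharpened raised cosine, so the downstream envelope/phase analysis chain sees
realistic input.

Sessions consist of ``n_trials`` trials of 14 s, one third per coupling
condition, in an order shuffled by the session seed. All randomness is
deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import TWO_PI, check_finite, wrap_phase

#: natural angular frequency of the syllabic cycle (rad/s), ~3 Hz syllable rate
OMEGA_DEFAULT = TWO_PI * 3.0

#: coupling strengths of the three task conditions
K_SYNC = -0.09
K_NEUTRAL = 0.01  # used as +/-0.01, alternating sign across neutral trials
K_SHIFTED = +0.09

CONDITION_NAMES = ("sync", "neutral", "shifted")


def psi_effective(k: float, shifted_target: float = np.pi) -> float:
    """Preferred phase offset implied by the sign of the coupling strength.

    Negative ``k`` encodes the synchrony target (offset 0); positive ``k``
    encodes the shifted target (default anti-phase, ``pi``): the VP aims to
    speak between the participant's syllables.
    """
    return 0.0 if k < 0 else float(shifted_target)


@dataclass
class OscillatorState:
    """Phase oscillator state: current phase (wrapped) and natural frequency."""

    phase: float
    omega: float = OMEGA_DEFAULT

    def __post_init__(self) -> None:
        if not math.isfinite(self.phase):
            raise ValueError("oscillator phase must be finite")
        if not (self.omega > 0):
            raise ValueError("omega must be > 0")
        self.phase = float(wrap_phase(self.phase))


@dataclass(frozen=True)
class Condition:
    """A (k, preferred phase) coupling condition of the VP."""

    name: str
    k: float
    psi: float

    @classmethod
    def from_k(cls, k: float, shifted_target: float = np.pi) -> "Condition":
        if k <= -0.05:
            name = "sync"
        elif k >= 0.05:
            name = "shifted"
        else:
            name = "neutral"
        return cls(name=name, k=float(k), psi=psi_effective(k, shifted_target))


@dataclass
class DyadConfig:
    """Configuration of a simulated synchronous-speech session.

    Parameters
    ----------
    omega : rad/s, natural angular frequency of both oscillators (2*pi*3).
    k_vp : VP coupling strength for single-trial use (one of the task values).
    k_participant : participant coupling toward the VP, dimensionless, >= 0.
    phase_noise_sd : participant Wiener phase noise, rad per sqrt(s). The
        default is calibrated so sessions reproduce the broad verbal
        coordination index distribution of the task (mean ~0.5).
    trial_duration, tick : trial length (s) and integration/control step (s).
        The control rate is 1/tick = 250 Hz.
    n_trials : trials per session; must divide by 3 for the thirds schedule.
    shifted_target : preferred offset of the positive-k condition (anti-phase).
    envelope_q : sharpening exponent of the raised-cosine envelope.
    """

    omega: float = OMEGA_DEFAULT
    k_vp: float = K_SYNC
    k_participant: float = 0.15
    phase_noise_sd: float = 2.25
    trial_duration: float = 14.0
    tick: float = 0.004
    n_trials: int = 24
    shifted_target: float = np.pi
    envelope_q: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trial_duration <= 0 or self.tick <= 0:
            raise ValueError("trial_duration and tick must be > 0")
        if self.k_participant < 0:
            raise ValueError("k_participant must be >= 0")
        if self.envelope_q < 1:
            raise ValueError("envelope_q must be >= 1")

    @property
    def fs(self) -> float:
        """Control/sample rate in Hz (1/tick)."""
        return 1.0 / self.tick

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration / self.tick))

    def conditions(self) -> list[Condition]:
        """The three task conditions at this config's shifted target."""
        return [
            Condition.from_k(K_SYNC, self.shifted_target),
            Condition.from_k(K_NEUTRAL, self.shifted_target),
            Condition.from_k(K_SHIFTED, self.shifted_target),
        ]


@dataclass
class DyadTrial:
    """One simulated trial: envelopes and phases of both speakers at 250 Hz."""

    vp_envelope: np.ndarray
    participant_envelope: np.ndarray
    vp_phase: np.ndarray
    participant_phase: np.ndarray
    condition: Condition
    trial_index: int
    fs: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.vp_phase)
        for arr in (self.participant_phase, self.vp_envelope, self.participant_envelope):
            if abs(len(arr) - n) > 1:
                raise ValueError("trial series lengths disagree")


def phase_to_envelope(phase, q: float = 2.0):
    """Map oscillator phase to a syllable-like amplitude envelope in [0, 1].

    envelope = ((1 + cos(phase)) / 2) ** q, peaking at phase 0 once per cycle;
    q >= 1 sharpens the peaks toward syllable-like pulses.
    """
    if q < 1:
        raise ValueError("sharpening exponent q must be >= 1")
    return ((1.0 + np.cos(np.asarray(phase, dtype=float))) / 2.0) ** q


def step_kuramoto(
    vp: OscillatorState,
    participant: OscillatorState,
    config: DyadConfig,
    noise_draw=(0.0, 0.0),
    condition: Condition | None = None,
) -> tuple[OscillatorState, OscillatorState]:
    """Advance both oscillators by one tick of the coupled Kuramoto dynamics.

    The VP's coupling term is ``|k| * omega * sin(phi_p + psi_eff - phi_vp)``
    (vanishing at the preferred offset phi_vp - phi_p = psi_eff, with psi_eff
    selected by the sign of k); the participant's term pulls symmetrically
    toward the VP. ``noise_draw`` is the per-step phase increment in radians,
    either a scalar applied to the participant or a (vp, participant) pair.
    """
    if condition is None:
        condition = Condition.from_k(config.k_vp, config.shifted_target)
    noise = np.atleast_1d(np.asarray(noise_draw, dtype=float))
    noise_vp, noise_p = (0.0, float(noise[0])) if noise.size == 1 else (float(noise[0]), float(noise[1]))
    check_finite("step_kuramoto inputs", vp.phase, participant.phase, noise_vp, noise_p, condition.k)

    dphi_vp = vp.omega + abs(condition.k) * vp.omega * math.sin(
        participant.phase + condition.psi - vp.phase
    )
    dphi_p = participant.omega + config.k_participant * participant.omega * math.sin(
        vp.phase - participant.phase
    )
    new_vp = OscillatorState(wrap_phase(vp.phase + config.tick * dphi_vp + noise_vp), vp.omega)
    new_p = OscillatorState(
        wrap_phase(participant.phase + config.tick * dphi_p + noise_p), participant.omega
    )
    return new_vp, new_p


def _integrate(
    config: DyadConfig,
    condition: Condition,
    phi_vp0: float,
    phi_p0: float,
    noise: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-integrate the dyad at tick resolution; returns wrapped phase series.

    Mirrors :func:`step_kuramoto` exactly (asserted by tests) but runs as a
    tight scalar loop for speed.
    """
    n = config.n_samples
    tick = config.tick
    omega = config.omega
    kv = abs(condition.k) * omega
    kp = config.k_participant * omega
    psi = condition.psi
    phi_vp = np.empty(n)
    phi_p = np.empty(n)
    a, b = float(phi_vp0), float(phi_p0)
    sin = math.sin
    for i in range(n):
        phi_vp[i] = a
        phi_p[i] = b
        da = omega + kv * sin(b + psi - a)
        db = omega + kp * sin(a - b)
        a = a + tick * da
        b = b + tick * db + noise[i]
    return wrap_phase(phi_vp), wrap_phase(phi_p)


def simulate_trial(
    config: DyadConfig,
    condition: Condition | None = None,
    trial_index: int = 0,
    seed: int = 0,
) -> DyadTrial:
    """Simulate one 14 s trial; deterministic given the seed.

    The VP starts at phase 0 (its stimulus onset); the participant starts at a
    random phase and converges (or not) according to the condition's coupling.
    """
    if condition is None:
        condition = Condition.from_k(config.k_vp, config.shifted_target)
    rng = np.random.default_rng(seed)
    phi_p0 = rng.uniform(-np.pi, np.pi)
    noise = rng.normal(0.0, config.phase_noise_sd * math.sqrt(config.tick), size=config.n_samples)
    phi_vp, phi_p = _integrate(config, condition, 0.0, phi_p0, noise)
    return DyadTrial(
        vp_envelope=phase_to_envelope(phi_vp, config.envelope_q),
        participant_envelope=phase_to_envelope(phi_p, config.envelope_q),
        vp_phase=phi_vp,
        participant_phase=phi_p,
        condition=condition,
        trial_index=trial_index,
        fs=config.fs,
        seed=seed,
    )


@dataclass
class BehaviourSession:
    """A full simulated session: trials plus the condition log."""

    trials: list[DyadTrial]
    log: pd.DataFrame  # trial_index, condition, k, psi, seed
    config: DyadConfig

    def __len__(self) -> int:
        return len(self.trials)


def simulate_session(config: DyadConfig) -> BehaviourSession:
    """Simulate a session of ``n_trials`` trials, one third per condition.

    Neutral trials alternate k = -0.01 / +0.01. Trial order is shuffled by the
    session seed; per-trial seeds are spawned from it so identical configs give
    bit-identical sessions.
    """
    n = config.n_trials
    if n % 3 != 0:
        raise ValueError(f"n_trials={n} not divisible by the 3 conditions of the thirds schedule")
    per = n // 3
    shifted = config.shifted_target
    conditions: list[Condition] = []
    conditions += [Condition.from_k(K_SYNC, shifted)] * per
    conditions += [
        Condition.from_k(K_NEUTRAL if i % 2 == 0 else -K_NEUTRAL, shifted) for i in range(per)
    ]
    conditions += [Condition.from_k(K_SHIFTED, shifted)] * per

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    trial_seeds = np.random.SeedSequence(config.seed).generate_state(n) % (2**31)

    trials = []
    rows = []
    for idx in range(n):
        cond = conditions[order[idx]]
        t = simulate_trial(config, cond, trial_index=idx, seed=int(trial_seeds[idx]))
        trials.append(t)
        rows.append(
            {
                "trial_index": idx,
                "condition": cond.name,
                "k": cond.k,
                "psi": cond.psi,
                "seed": int(trial_seeds[idx]),
            }
        )
    return BehaviourSession(trials=trials, log=pd.DataFrame(rows), config=config)


def count_syllable_onsets(session: BehaviourSession, speaker: str = "vp") -> int:
    """Count syllable onsets (envelope peaks) across a session.

    One raised-cosine envelope peak corresponds to one syllable; at ~3 Hz over
    24 x 14 s this yields ~1000 syllables per session.
    """
    from scipy.signal import find_peaks

    total = 0
    for trial in session.trials:
        env = trial.vp_envelope if speaker == "vp" else trial.participant_envelope
        min_dist = int(0.5 * trial.fs / 3.0)  # half a syllable period
        peaks, _ = find_peaks(env, height=0.3, distance=min_dist)
        total += len(peaks)
    return total


def tiny_config(seed: int = 0) -> DyadConfig:
    """A reduced session (6 trials) for fast tests and fixtures."""
    return replace(DyadConfig(seed=seed), n_trials=6)
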