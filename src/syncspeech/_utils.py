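"""Shared small utilities: phase wrapping, circular statistics, seed derivation."""

from __future__ import annotations

import zlib

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_phase(x):
    """Wrap angles (radians) to the half-open interval (-pi, pi].

    Accepts scalars or arrays. The convention maps -pi -> pi so the interval
    is open at -pi and closed at pi, and wrapping an already-wrapped value is
    the identity.
    """
    return np.pi - np.mod(np.pi - np.asarray(x, dtype=float), TWO_PI)


def circular_mean(angles) -> float:
    """Circular mean angle of a set of radians, in (-pi, pi]."""
    z = np.mean(np.exp(1j * np.asarray(angles, dtype=float)))
    return float(wrap_phase(np.angle(z)))


def circular_distance(a, b):
    """Smallest absolute angular distance between two angles (radians)."""
    return np.abs(wrap_phase(np.asarray(a, dtype=float) - b))


def plv(delta_phase) -> float:
    """Phase-locking value: modulus of the time-averaged unit phasor."""
    d = np.asarray(delta_phase, dtype=float)
    return float(np.abs(np.mean(np.exp(1j * d))))


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from a master seed and a stage name.

    Uses a CRC32 hash of the stage name folded into a SeedSequence so stages can
    be re-run independently while remaining fully determined by the master seed.
    """
    tag = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def check_finite(name: str, *values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} contains non-finite values")
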