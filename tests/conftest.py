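"""Shared fixtures: small simulated sessions and synthetic recordings.

Everything is generated at test time from seeds; nothing is read from disk.
Session-scoped fixtures are shared across test modules to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from syncspeech.dyad import DyadConfig, simulate_session
from syncspeech import coordination as coord
from syncspeech.synth_seeg import generate_rest, generate_task, tiny_layout


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A 12-trial session with the default study parameters."""
    return simulate_session(DyadConfig(n_trials=12, seed=7))


@pytest.fixture(scope="session")
def small_session_vci(small_session):
    results = coord.analyse_session(small_session, n_surrogates=100, seed=11)
    return np.array([r.vci for r in results])


@pytest.fixture(scope="session")
def tiny_specs():
    return tiny_layout()


@pytest.fixture(scope="session")
def tiny_task(tiny_specs, small_session, small_session_vci):
    return generate_task(tiny_specs, small_session.trials, small_session_vci, seed=21)


@pytest.fixture(scope="session")
def tiny_rest(tiny_specs):
    return generate_rest(tiny_specs, duration=140.0, seed=22)
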