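import math

import numpy as np
import pytest

from aurbt import OUParams, StateSpec, TetherSpec
from aurbt.core import Dwell


@pytest.fixture
def tether():
    return TetherSpec()


@pytest.fixture
def ou():
    return OUParams(tau_c=0.005, sigma=0.05)


@pytest.fixture
def spec3():
    """Sequential C/I/O model at the generator's default rates."""
    return StateSpec.default_cio()


@pytest.fixture
def two_state_spec():
    """Two-state model matching the twist-recovery study conditions:
    dtheta_CI = -(7/10.5) turns, dG(0) = 3 kBT, barrier fraction 0.4."""
    k_ci = 0.2
    return StateSpec(labels=("C", "I"), unwinding_bp=(0.0, 7.0),
                     base_rates={("C", "I"): k_ci,
                                 ("I", "C"): k_ci * math.exp(3.0)},
                     barrier_fraction=0.4)


def make_dwells(entries, units="bp"):
    """Build a labeled dwell list from (state, duration, level) tuples."""
    out, t = [], 0.0
    for state, dur, level in entries:
        out.append(Dwell(t_start=t, t_end=t + dur, mean_level=level,
                         n_samples=max(1, int(dur)), units=units, state=state))
        t += dur
    return out


@pytest.fixture
def dwell_factory():
    return make_dwells
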