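"""Shared fixtures: expensive simulation sessions are session-scoped so the
ordering assertions can reuse them."""

from __future__ import annotations

import numpy as np
import pytest

from hhinfo import pipeline
from hhinfo.biophysics import BiophysParams

ORDERING_SEEDS = (0, 1, 2)
N_TRIALS = 20
LOW_MEAN, HIGH_SD = 1.0, 10.0


@pytest.fixture(scope="session")
def params() -> BiophysParams:
    return BiophysParams()


@pytest.fixture(scope="session")
def spiking_low_high():
    """Fully stochastic model at the low-mean/high-SD grid corner, frozen +
    unfrozen sessions, one entry per seed."""
    return {s: pipeline.spiking_condition(LOW_MEAN, HIGH_SD, N_TRIALS,
                                          seed=s)
            for s in ORDERING_SEEDS}


@pytest.fixture(scope="session")
def graded_low_high():
    return {s: pipeline.graded_condition(LOW_MEAN, HIGH_SD, N_TRIALS, seed=s)
            for s in ORDERING_SEEDS}


@pytest.fixture(scope="session")
def graded_mid():
    """Graded frozen session at the grid midpoint (footprint baseline)."""
    return {s: pipeline.graded_condition(5.0, 5.0, N_TRIALS, seed=s)
            for s in ORDERING_SEEDS}
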