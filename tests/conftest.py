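"""Shared fixtures: calibrated detectors and reusable session schedules.

Detector calibrations are the expensive shared resources; they are built
once per test session at reduced but honest Monte-Carlo sizes.
"""

from __future__ import annotations

import numpy as np
import pytest

from seqmem.changepoint import calibrate_thresholds
from seqmem.decay import DecayParams
from seqmem.harness import calibrate_matched
from seqmem.stimuli import schedule_session


@pytest.fixture(scope="session")
def det_unconstrained():
    """Matched-null calibration for the unconstrained model (ARL0 10^4)."""
    return calibrate_matched(arl0=10_000.0, max_length=140, n_sims=30_000,
                             seed=101)


@pytest.fixture(scope="session")
def det_constrained():
    """Matched-null calibration for the memory-constrained model."""
    return calibrate_matched(arl0=10_000.0, max_length=140, n_sims=20_000,
                             seed=102, decay=DecayParams())


@pytest.fixture(scope="session")
def det_fast():
    """Small IID-Gaussian calibration (ARL0 200) for detector unit tests."""
    return calibrate_thresholds(arl0=200.0, max_length=140, n_sims=6_000,
                                rng=7)


@pytest.fixture(scope="session")
def exp1a_session():
    return schedule_session("1A", np.random.default_rng(2024))


@pytest.fixture(scope="session")
def exp2_session():
    return schedule_session("2", np.random.default_rng(2025))
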