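"""Shared fixtures: all inputs are generated programmatically, no downloads."""

from __future__ import annotations

import numpy as np
import pytest

from popneuron.population import ProtocolSuite, evaluate_candidate
from popneuron.protocols import ramp_protocol, step_protocol
from popneuron.synthetic import toy_hh_model


@pytest.fixture(scope="session")
def toy_model():
    return toy_hh_model()


@pytest.fixture(scope="session")
def fast_protocols():
    """Shortened step/ramp protocols for quick toy-model tests.

    The toy model settles within a few ms, so a 20 ms pre-stimulus delay
    and 100-200 ms stimuli exercise the same code paths as the full-length
    protocols at a fraction of the cost.
    """
    return ProtocolSuite(
        step=step_protocol(delay=20.0, duration=200.0, t_stop=300.0),
        ramp=ramp_protocol(delay=20.0, duration=100.0, t_stop=200.0),
    )


@pytest.fixture(scope="session")
def toy_baseline_biomarkers(toy_model):
    """Baseline (identity-scaled) biomarkers under the full-length protocols."""
    return evaluate_candidate(toy_model, {})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
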