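"""Shared fixtures: models and a few expensive simulations, computed once."""

import numpy as np
import pytest

import cardioinverse as ci
from cardioinverse.models import EVAL_PROTOCOL, PacingProtocol


@pytest.fixture(scope="session")
def base_model():
    return ci.build_base_model()


@pytest.fixture(scope="session")
def mature_model():
    return ci.build_mature_model()


@pytest.fixture(scope="session")
def base_p(base_model):
    return ci.ParameterVector.ones(base_model.parameter_names)


@pytest.fixture(scope="session")
def baseline_trace(base_model, base_p):
    """Unperturbed base-model beat under the canonical evaluation protocol."""
    return ci.simulate(base_model, base_p, EVAL_PROTOCOL)


@pytest.fixture(scope="session")
def baseline_features(baseline_trace):
    return ci.extract_features(baseline_trace)


@pytest.fixture(scope="session")
def kr_blocked_trace(base_model, base_p):
    """Beat with I_Kr half blocked (classic hERG-block APD prolongation)."""
    lam = ci.BlockVector({"I_Kr": -0.5}, mode="drug")
    return ci.simulate(base_model, ci.apply_block(base_p, lam), EVAL_PROTOCOL)


def synthetic_beat(rng, n_ms=1000, dt=1.0):
    """A randomized smooth one-beat pulse with known analytic structure.

    Logistic upstroke times exponential decay on a flat baseline; parameters
    randomized widely enough to cover AP-like and calcium-transient-like
    shapes.
    """
    from scipy.special import expit

    t = np.arange(0.0, n_ms + dt / 2, dt)
    onset = rng.uniform(50, 150)
    rise = rng.uniform(2, 15)
    decay = rng.uniform(80, 350)
    amp = rng.uniform(0.5, 120.0)
    base = rng.uniform(-80.0, 10.0)
    # smooth (C-infinity) pulse: the sigmoid always rises faster than the
    # exponential decays, so the pre-onset tail vanishes
    x = base + amp * expit((t - onset) / rise) * np.exp(-(t - onset) / decay)
    return t, x
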