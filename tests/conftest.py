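import numpy as np
import pytest

from seedpath.model import parse_model
from seedpath.synthetic import (
    SimConfig,
    default_true_parameters,
    simulate_landscape,
    theta_from_maps,
)


@pytest.fixture(scope="session")
def chain_model():
    """x -> m -> y chain with an extra direct x -> y path."""
    return parse_model("y ~ m + x\nm ~ x", variables=["y", "m", "x"])


@pytest.fixture(scope="session")
def chain_theta(chain_model):
    return theta_from_maps(
        chain_model,
        {("y", "m"): 0.4, ("y", "x"): 0.2, ("m", "x"): -0.5},
        {"y": 0.6, "m": 0.75, "x": 1.0},
    )


@pytest.fixture(scope="session")
def downsizing_model():
    model, _ = default_true_parameters()
    return model


@pytest.fixture(scope="session")
def downsizing_theta():
    _, theta = default_true_parameters()
    return theta


@pytest.fixture(scope="session")
def small_landscape():
    """A compact landscape bundle shared by the slower integration tests."""
    cfg = SimConfig(
        extent_km=(240.0, 330.0),
        n_plants=250,
        n_frugivores_extant=36,
        n_frugivores_extinct=12,
        n_mega_species=8,
        m_imputations=3,
        rng_seed=11,
    )
    return simulate_landscape(cfg)
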