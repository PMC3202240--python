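"""Shared fixtures: default parameters, built models, and the five
scenario runs the study reports (computed once per session)."""

import numpy as np
import pytest
from hypothesis import settings

import brainenergy as be
from brainenergy.model_core import (
    CompartmentalModel,
    Compartment,
    KineticLaw,
    Reaction,
    Species,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return be.default_parameters()


@pytest.fixture(scope="session")
def classical_model(params):
    return be.build_classical_model(params)


@pytest.fixture(scope="session")
def anlsh_model(params):
    return be.build_anlsh_model(params)


@pytest.fixture(scope="session")
def runs(params):
    """The five experiment runs reported by the study (dense, default
    tolerances).  Horizons: 250 min, extended to 500 min for the two
    lactate-shuttle oxygenation scenarios (long-run insets)."""
    grid = [
        ("classical", "normoxia", 250.0),
        ("classical", "hypoxia", 250.0),
        ("anlsh", "normoxia", 500.0),
        ("anlsh", "hypoxia", 500.0),
        ("anlsh", "starvation", 250.0),
    ]
    return {
        (v, s): be.run_experiment(v, s, params=params, t_end=te)
        for v, s, te in grid
    }


def make_two_pool_model(k1=0.3, k2=0.1, a0=2.0, b0=0.0, vx=0.2, vy=0.5):
    """Closed first-order interconversion A@x <-> B@y across two
    compartments; the analytic solution is a 2x2 linear ODE."""
    comps = {
        "x": Compartment("x", "pool x", vx),
        "y": Compartment("y", "pool y", vy),
    }
    species = {
        ("A", "x"): Species("A", "x", a0),
        ("B", "y"): Species("B", "y", b0),
    }
    reactions = [
        Reaction(
            number=1, name="A to B",
            substrates=(("A", "x", 1.0),), products=(("B", "y", 1.0),),
            law=KineticLaw("mass_action", {"k": k1}),
            source_compartment="x", target_compartment="y",
            rate_species=(("A", "x"),),
        ),
        Reaction(
            number=2, name="B to A",
            substrates=(("B", "y", 1.0),), products=(("A", "x", 1.0),),
            law=KineticLaw("mass_action", {"k": k2}),
            source_compartment="y", target_compartment="x",
            rate_species=(("B", "y"),),
        ),
    ]
    return CompartmentalModel(
        variant="classical", compartments=comps, species=species,
        reactions=reactions, genes=(),
    )


def two_pool_solution(t, k1=0.3, k2=0.1, a0=2.0, b0=0.0, vx=0.2, vy=0.5):
    """Matrix-exponential solution of the two-pool model (oracle)."""
    import scipy.linalg

    t = np.atleast_1d(np.asarray(t, dtype=float))
    # dA = -k1 A + k2 B * vy/vx ; dB = k1 A * vx/vy - k2 B
    M = np.array([[-k1, k2 * vy / vx], [k1 * vx / vy, -k2]])
    out = np.empty((len(t), 2))
    for i, ti in enumerate(t):
        out[i] = scipy.linalg.expm(M * ti) @ np.array([a0, b0])
    return out
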