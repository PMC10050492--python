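"""Shared fixtures: toy rings, a scaled-down active network, short trials."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import thetaring as tr

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_geom() -> tr.RingGeometry:
    """16 principal cells, 8 interneurons — small enough for brute force."""
    return tr.RingGeometry(n_e=16, n_i=8)


@pytest.fixture(scope="session")
def default_geom() -> tr.RingGeometry:
    return tr.RingGeometry()


@pytest.fixture(scope="session")
def default_mats(default_geom) -> tr.ConnectivityMatrices:
    return tr.build_connectivity(default_geom, tr.ConnectivityParams())


def mini_model(n_e: int = 64, n_i: int = 16) -> tr.ModelParameters:
    """Scaled-down network with conductances rescaled to keep the total
    synaptic drive comparable to the full-size network (weights are
    mean-normalized, so the summed drive scales with the presynaptic
    count)."""
    model = tr.ModelParameters(n_e=n_e, n_i=n_i)
    scale_e = 1024 / n_e
    scale_i = 256 / n_i
    model.syn = dataclasses.replace(
        model.syn,
        g_nmda_ei=model.syn.g_nmda_ei * scale_e,
        g_gaba_ie=model.syn.g_gaba_ie * scale_i,
        g_gaba_ii=model.syn.g_gaba_ii * scale_i,
    )
    return model


@pytest.fixture(scope="session")
def short_default_trial() -> tr.SimulationResult:
    """One 1.5-s default-protocol trial at full size (reused by several
    invariant tests)."""
    model, protocol = tr.default_protocol(duration=1.5)
    return tr.run_trial(model, protocol, seed=12345)


def safe_v0(rng: np.random.Generator, n_e: int, n_i: int):
    """Initial potentials bounded away from threshold, for path-equivalence
    tests where a razor-edge crossing would amplify round-off ordering."""
    return rng.uniform(-60.0, -55.0, n_e), rng.uniform(-60.0, -55.0, n_i)
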