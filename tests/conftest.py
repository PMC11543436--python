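"""Shared expensive fixtures: one affinity scan, one surrogate set, one
conditioned posterior per session."""
import numpy as np
import pytest

from tcrmeta import (
    ContactProtocol,
    Observation,
    build_training_grid,
    condition,
    couple,
    decay_length_grid,
    fit_surrogate,
    reduced_contact_config,
    run_affinity_scan,
    sample_prior,
)

SEED = 20240917


@pytest.fixture(scope="session")
def lck_sweep():
    """5x5 log-grid decay lengths (1000 walkers, 1000 steps per cell)."""
    diffs = np.logspace(-2, 0, 5)
    p_offs = np.logspace(-1, 2, 5)
    dls = decay_length_grid(diffs, p_offs, seed=SEED)
    return diffs, p_offs, dls


@pytest.fixture(scope="session")
def training_grids():
    g_ks = build_training_grid("KS", n_replicates=3, seed=SEED)
    g_lck = build_training_grid("LckA", n_replicates=3, seed=SEED)
    g_pt = build_training_grid("pTCR", n_replicates=3, seed=SEED)
    return {"KS": g_ks, "LckA": g_lck, "pTCR": g_pt}


@pytest.fixture(scope="session")
def surrogates(training_grids):
    return {
        "KS": fit_surrogate(training_grids["KS"]),
        "LckA": fit_surrogate(training_grids["LckA"]),
        "pTCR": fit_surrogate(training_grids["pTCR"], degree=3),
    }


@pytest.fixture(scope="session")
def metamodel_fixture(surrogates):
    return couple(surrogates["KS"], surrogates["LckA"], surrogates["pTCR"])


@pytest.fixture(scope="session")
def posterior(metamodel_fixture):
    return condition(metamodel_fixture, Observation(), seed=SEED)


@pytest.fixture(scope="session")
def prior_samples(metamodel_fixture):
    # the unconditioned joint is a DAG: ancestral sampling is exact
    return sample_prior(metamodel_fixture, n=40000, seed=SEED + 1)


@pytest.fixture(scope="session")
def affinity_scan():
    proto = ContactProtocol(n_replicates=3)
    return run_affinity_scan(reduced_contact_config(), proto, seed=SEED)
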