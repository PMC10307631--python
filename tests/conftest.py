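import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fibrokine as fk

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_bulk():
    """Bulk counts with one planted program (20 up / 20 down, |lfc|=2)."""
    prog = fk.CytokineProgram(
        "TNF", up_genes=list(range(20)), down_genes=list(range(20, 40)),
        log2fc_up=2.0, log2fc_down=2.0,
    )
    bulk, truth = fk.simulate.generate_bulk([prog], n_genes=400, seed=101)
    return bulk, truth


@pytest.fixture(scope="session")
def two_state_cells():
    """Two cell states differing by one 50-gene 4x program."""
    prog = fk.CytokineProgram("P", up_genes=list(range(50, 100)), down_genes=[], log2fc_up=2.0)
    states = [
        fk.StateSpec("resting", [], n_cells=200),
        fk.StateSpec("activated", [(prog, 1.0)], n_cells=200),
    ]
    em, truth = fk.simulate.generate_single_cell(states, n_genes=600, seed=202)
    return em, truth


@pytest.fixture(scope="session")
def two_state_norm(two_state_cells):
    em, truth = two_state_cells
    return fk.scoring.normalize_log(em), truth


@pytest.fixture(scope="session")
def small_spatial():
    """3-topic spatial spots with a topic-independent shared gene block."""
    theta = fk.simulate.make_topics(
        3, 500, seed=33, n_shared=40, shared_mass=0.1, shared_background=True
    )
    em, truth = fk.simulate.generate_spatial(theta, n_spots=600, depth=600, alpha=0.5, seed=33)
    return em, truth


@pytest.fixture(scope="session")
def small_atac():
    """ATAC with motif_0 strongly active in state 1 of two states."""
    mm = fk.simulate.make_motif_match(5, 200, peaks_per_motif=40, seed=44)
    activity = np.zeros((5, 2))
    activity[0, 1] = 2.0
    pm, truth = fk.simulate.generate_atac(200, 100, mm, activity, seed=44)
    return pm, mm, truth
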