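"""Shared fixtures: one small phantom, influence matrix, plan and Pareto
dataset, all session-scoped so the heavier objects are built once."""

import numpy as np
import pytest

import paretoplan as pp
from paretoplan.pareto import NavigationDimension, generate_dataset

SMALL_GRID = (32, 32, 32)


@pytest.fixture(scope="session")
def small_geo():
    return pp.build_ptvs(pp.generate_patient(1, grid_shape=SMALL_GRID))


@pytest.fixture(scope="session")
def proto_a():
    return pp.load_builtin_protocol("instA")


@pytest.fixture(scope="session")
def proto_b():
    return pp.load_builtin_protocol("instB")


@pytest.fixture(scope="session")
def small_beams():
    return pp.BeamConfig(n_beams=8)


@pytest.fixture(scope="session")
def small_influence(small_geo, small_beams):
    return pp.build_influence_matrix(small_geo, small_beams)


@pytest.fixture(scope="session")
def fast_cfg():
    return pp.PBAIOConfig(inner_iterations=15, outer_loops=2)


@pytest.fixture(scope="session")
def small_plan(small_geo, proto_a, small_beams, fast_cfg, small_influence):
    return pp.autoplan(small_geo, proto_a, small_beams, fast_cfg,
                       influence=small_influence)


@pytest.fixture(scope="session")
def tiny_dataset(small_geo, proto_a, small_beams, small_influence):
    """A (3, 3) Pareto dataset over rectum-Dmean WF × external fall-off WF."""
    dims = [
        NavigationDimension("rectum", "mean_dose", "weighting_factor",
                            (0.584, 5.84, 58.4)),
        NavigationDimension("external", "dose_falloff_external", "weighting_factor",
                            (102.0, 204.0, 408.0)),
    ]
    cfg = pp.PBAIOConfig(inner_iterations=10, outer_loops=1)
    return generate_dataset(small_geo, proto_a, dims, pp.BeamConfig(n_beams=8),
                            cfg, influence=small_influence)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
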