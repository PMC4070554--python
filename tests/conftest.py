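"""Shared fixtures: small deterministic populations and the study-scale
emulation (four DH families, 131/120/200/196 lines, 21-group map)."""

import pytest

import mlcqtl as m
from mlcqtl.genoprob import expected_counts, make_grid
from mlcqtl.scan import ScanEngine


@pytest.fixture(scope="session")
def study_map():
    return m.study_map()


@pytest.fixture(scope="session")
def study_arch():
    return m.study_architecture()


@pytest.fixture(scope="session")
def study_pop(study_map, study_arch):
    return m.simulate_population(study_map, m.study_families(), seed=1, arch=study_arch)


@pytest.fixture(scope="session")
def study_engine(study_pop):
    """Scan engine on a 5 cM grid over the study population."""
    grid = make_grid(study_pop.gmap, 5.0)
    return ScanEngine(study_pop, expected_counts(study_pop, grid))


@pytest.fixture(scope="session")
def small_pop():
    """4 families x 40 lines on a 3-group map: fast unit-test material."""
    gmap = m.make_map(3, 100.0, 10.0)
    fams = tuple(m.FamilySpec(f"F{i + 1}", 40, f"P{i}a", f"P{i}b") for i in range(4))
    return m.simulate_population(gmap, fams, seed=7)


@pytest.fixture(scope="session")
def small_engine(small_pop):
    grid = make_grid(small_pop.gmap, 5.0)
    return ScanEngine(small_pop, expected_counts(small_pop, grid))
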