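"""Two-locus interaction scan: region-pair threshold arithmetic, null
calibration of the F test, power on planted interactions, and landscapes."""

import numpy as np
import pytest
from scipy import stats

import mlcqtl as m
from mlcqtl.core import ParameterError
from mlcqtl.epistasis import (
    epistasis_scan,
    landscape,
    pair_test,
    region_threshold,
    _pair_block,
)
from mlcqtl.genoprob import expected_counts, make_grid
from mlcqtl.scan import ScanEngine


class TestRegionThreshold:
    def test_single_group(self):
        assert region_threshold(1) == pytest.approx(0.05)

    def test_21_groups(self):
        # 42 regions -> C(42,2) = 861 pairs
        assert region_threshold(21) == pytest.approx(0.05 / 861)

    def test_22_groups_matches_printed_level(self):
        # 44 regions -> C(44,2) = 946 pairs -> 5.29e-5, i.e. "P < 5.3e-5"
        thr = region_threshold(22)
        assert thr == pytest.approx(0.05 / 946)
        assert thr < 5.3e-5

    def test_invalid(self):
        with pytest.raises(ParameterError):
            region_threshold(0)


@pytest.fixture(scope="module")
def epi_pop():
    """Two-locus interaction planted at marker positions, ~5% of Vg."""
    gmap = m.make_map(4, 100.0, 10.0)
    fams = m.study_families()
    arch = m.QTLArchitecture(
        additive=(
            m.AdditiveQTL("LG1", 40.0, (0.5,) * 4),
            m.AdditiveQTL("LG2", 60.0, (0.5,) * 4),
        ),
        epistatic=(m.EpistaticQTL(("LG1", 40.0), ("LG2", 60.0), (0.162,) * 4),),
    )
    pop = m.simulate_population(gmap, fams, seed=44, arch=arch)
    grid = make_grid(gmap, 5.0)
    engine = ScanEngine(pop, expected_counts(pop, grid))
    return pop, arch, engine


class TestPairTest:
    def test_exact_symmetry(self, epi_pop):
        pop, arch, engine = epi_pop
        y = np.random.default_rng(1).normal(size=pop.n_lines)
        i = engine.grid.locate("LG1", 40.0)
        j = engine.grid.locate("LG3", 20.0)
        p1, e1 = pair_test(engine, y, i, j)
        p2, e2 = pair_test(engine, y, j, i)
        assert p1 == p2
        np.testing.assert_array_equal(e1, e2)

    def test_identical_loci_rejected(self, epi_pop):
        _, _, engine = epi_pop
        with pytest.raises(ParameterError):
            pair_test(engine, np.zeros(engine.n), 3, 3)

    def test_constant_phenotype_gives_p_one(self, epi_pop):
        _, _, engine = epi_pop
        p, _ = pair_test(engine, np.full(engine.n, 2.0), 0, 40)
        assert p == 1.0

    def test_null_p_uniform(self, small_engine):
        """Purely additive signal: interaction P uniform (KS over 200 sims)."""
        rng = np.random.default_rng(5)
        i = small_engine.grid.locate("LG1", 50.0)
        j = np.array([small_engine.grid.locate("LG2", 50.0)])
        x = small_engine.counts[:, i] + small_engine.counts[:, j[0]]
        ps = []
        for _ in range(200):
            y = 0.4 * x + rng.normal(size=small_engine.n)  # additive two-locus signal
            ps.append(float(_pair_block(small_engine, y, i, j)[0]))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_on_planted_interaction(self, epi_pop):
        """Planted ~5%-of-Vg interaction at n=647: P below the 21-group
        region threshold in >=80% of 50 sims (h2 = 0.9)."""
        gmap = m.make_map(4, 100.0, 10.0)
        thr = region_threshold(21)
        arch = epi_pop[1]
        hits = 0
        for seed in range(50):
            pop = m.simulate_population(gmap, m.study_families(), seed=600 + seed, arch=arch)
            g = m.genetic_values(pop, arch, "s")
            noise_sd = np.sqrt(np.var(g, ddof=1) * (1 / 0.9 - 1))
            y = g + np.random.default_rng(seed).normal(0, noise_sd, pop.n_lines)
            engine = ScanEngine(pop, expected_counts(pop, make_grid(gmap, 5.0)))
            i = engine.grid.locate("LG1", 40.0)
            j = engine.grid.locate("LG2", 60.0)
            p, _ = pair_test(engine, y, i, j)
            hits += p < thr
        assert hits >= 40


class TestEpistasisScan:
    def test_planted_interaction_recovered(self, epi_pop):
        pop, arch, engine = epi_pop
        g = m.genetic_values(pop, arch, "s")
        y = g + np.random.default_rng(2).normal(0, g.std() * 0.3, pop.n_lines)
        thr = region_threshold(len(pop.gmap.groups))
        recs = epistasis_scan(engine, y, thr, h2=0.9)
        groups = {(r.locus1[0], r.locus2[0]) for r in recs}
        assert ("LG1", "LG2") in groups
        hit = [r for r in recs if (r.locus1[0], r.locus2[0]) == ("LG1", "LG2")][0]
        assert abs(hit.locus1[1] - 40.0) <= 10.0 and abs(hit.locus2[1] - 60.0) <= 10.0
        assert hit.pG_epi > 0.0

    def test_same_group_guard(self, epi_pop):
        _, _, engine = epi_pop
        from mlcqtl.epistasis import _candidates

        i = engine.grid.locate("LG1", 50.0)
        J = _candidates(engine, i, 20.0)
        same = J[engine.grid.group_idx[J] == engine.grid.group_idx[i]]
        assert np.all(np.abs(engine.grid.pos[same] - 50.0) >= 20.0)

    def test_coarse_grid_runs(self, epi_pop):
        """Step larger than the group length still completes (marker-sparse grid)."""
        pop, arch, _ = epi_pop
        grid = make_grid(pop.gmap, 500.0)
        engine = ScanEngine(pop, expected_counts(pop, grid))
        y = np.random.default_rng(3).normal(size=pop.n_lines)
        epistasis_scan(engine, y, region_threshold(4))


class TestLandscape:
    def test_dimensions_and_consistency(self, epi_pop):
        pop, arch, engine = epi_pop
        g = m.genetic_values(pop, arch, "s")
        y = g + np.random.default_rng(4).normal(0, g.std() * 0.3, pop.n_lines)
        thr = region_threshold(4)
        land = landscape(engine, y, "LG1", "LG2", thr)
        assert land.neglog10p.shape == (land.pos_a.size, land.pos_b.size)
        assert np.all(land.neglog10p >= 0.0)
        # maximum of the surface equals the best pair-test P for this pair
        ia = int(np.argmax(land.neglog10p.max(axis=1)))
        ib = int(np.argmax(land.neglog10p[ia]))
        gi = engine.grid.group_slices["LG1"].start + ia
        gj = engine.grid.group_slices["LG2"].start + ib
        p, _ = pair_test(engine, y, gi, gj)
        assert -np.log10(p) == pytest.approx(land.neglog10p[ia, ib], rel=1e-9)

    def test_planted_cell_significant(self, epi_pop):
        pop, arch, engine = epi_pop
        g = m.genetic_values(pop, arch, "s")
        y = g + np.random.default_rng(6).normal(0, g.std() * 0.3, pop.n_lines)
        land = landscape(engine, y, "LG1", "LG2", region_threshold(4))
        ia = np.flatnonzero(np.abs(land.pos_a - 40.0) <= 10.0)
        ib = np.flatnonzero(np.abs(land.pos_b - 60.0) <= 10.0)
        assert land.significant[np.ix_(ia, ib)].any()
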