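"""Coalescent simulator calibration and the sweep injector.

msprime acts as the independent simulation oracle: our ARG-walk
implementation must agree with it (and with coalescent theory) in
distribution on matched configurations.
"""

import numpy as np
import pytest
from scipy.stats import kstest

import sweepscan.diversity as dv
from sweepscan.datamodel import GeneticMap
from sweepscan.ehh import CoreHaplotype, ehh_at
from sweepscan.simulate import (SimConfig, SizeChange, Split, SweepSpec,
                                demographic_preset, growth_staircase,
                                inject_sweep, simulate_background,
                                simulate_neutral)


class TestFixedS:
    def test_exactly_s_sites_every_run(self):
        cfg = SimConfig(samples=40, fixed_s=16, rho=1.0, length_bp=4007)
        rng = np.random.default_rng(11)
        for _ in range(25):
            sites, mat = simulate_neutral(cfg, rng=rng)
            assert mat.n_sites == 16
            counts = mat.derived_counts()
            assert np.all((counts > 0) & (counts < 40))

    def test_s_zero_returns_empty_matrix(self):
        cfg = SimConfig(samples=8, fixed_s=0, seed=3)
        sites, mat = simulate_neutral(cfg)
        assert mat.alleles.shape == (8, 0)

    def test_positions_strictly_increasing_and_uniform(self):
        cfg = SimConfig(samples=10, fixed_s=12, length_bp=100_000, rho=0.5)
        rng = np.random.default_rng(5)
        pooled = []
        for _ in range(120):
            sites, _ = simulate_neutral(cfg, rng=rng)
            assert np.all(np.diff(sites.pos) > 0)
            pooled.extend(sites.pos / 100_000)
        assert kstest(pooled, "uniform").pvalue > 0.01


def test_same_seed_is_reproducible():
    cfg = SimConfig(samples=20, theta=8.0, rho=2.0, seed=42)
    s1, m1 = simulate_neutral(cfg)
    s2, m2 = simulate_neutral(cfg)
    assert np.array_equal(s1.pos, s2.pos)
    assert np.array_equal(m1.alleles, m2.alleles)


def test_config_validation():
    with pytest.raises(ValueError, match="exactly one"):
        SimConfig(samples=10).validate()
    with pytest.raises(ValueError, match="exactly one"):
        SimConfig(samples=10, theta=1.0, fixed_s=5).validate()
    with pytest.raises(ValueError, match="2 sampled"):
        SimConfig(samples=1, theta=1.0).validate()


def test_disconnected_demography_raises():
    cfg = SimConfig(samples={"A": 4, "B": 4}, theta=2.0, migration=0.0)
    with pytest.raises(ValueError, match="disconnected"):
        simulate_neutral(cfg, rng=np.random.default_rng(0))


def test_split_connects_populations():
    cfg = SimConfig(samples={"A": 6, "B": 6}, theta=4.0,
                    events=[Split(0.5, "B", "A")], seed=9)
    sites, mat = simulate_neutral(cfg)
    assert mat.n_chromosomes == 12


def test_migration_connects_populations():
    cfg = SimConfig(samples={"A": 5, "B": 5}, theta=4.0, migration=2.0, seed=9)
    _, mat = simulate_neutral(cfg)
    assert mat.n_chromosomes == 10


class TestCalibration:
    def test_n2_mean_pairwise_equals_theta(self):
        theta = 5.0
        cfg = SimConfig(samples=2, theta=theta, length_bp=10_000)
        rng = np.random.default_rng(17)
        diffs = []
        for _ in range(800):
            _, m = simulate_neutral(cfg, rng=rng)
            diffs.append(int((m.alleles[0] != m.alleles[1]).sum()))
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - theta) < 3 * se

    def test_null_tajimas_d_agrees_with_msprime(self):
        """Constant-size n=40: mean Tajima's D must agree between our
        simulator and msprime at matched θ within Monte Carlo error."""
        import msprime

        a1 = sum(1.0 / i for i in range(1, 40))
        theta = 16.0 / a1
        rng = np.random.default_rng(23)
        cfg = SimConfig(samples=40, theta=theta, length_bp=4007)
        ours = []
        for _ in range(600):
            _, m = simulate_neutral(cfg, rng=rng)
            if m.n_sites:
                ours.append(dv.tajimas_D(dv.SFSCounts.from_matrix(m, 4007)))
        reference = []
        reps = msprime.sim_ancestry(samples=20, ploidy=2, sequence_length=4007,
                                    population_size=0.5, num_replicates=600,
                                    random_seed=97)
        for ts in reps:
            mts = msprime.sim_mutations(
                ts, rate=theta / 2 / 4007,
                model=msprime.BinaryMutationModel(), random_seed=None)
            c = np.array([v.genotypes.sum() for v in mts.variants()])
            c = c[(c > 0) & (c < 40)]
            if len(c):
                reference.append(dv.tajimas_D(dv.SFSCounts.from_counts(c, 40, 4007)))
        se = np.sqrt(np.var(ours, ddof=1) / len(ours)
                     + np.var(reference, ddof=1) / len(reference))
        assert abs(np.mean(ours) - np.mean(reference)) < 3 * se


class TestDemography:
    def test_growth_staircase_monotone(self):
        evs = growth_staircase("A", 0.0, 0.1, present_size=2.0, rate=10.0)
        sizes = [e.size for e in evs]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert all(isinstance(e, SizeChange) for e in evs)

    def test_presets_are_valid_configs(self):
        for name in ("african", "european", "asian"):
            cfg = SimConfig(samples=10, fixed_s=5, seed=1,
                            **demographic_preset(name))
            _, m = simulate_neutral(cfg)
            assert m.n_sites == 5

    def test_bottleneck_reduces_mean_s(self):
        rng = np.random.default_rng(31)
        base = SimConfig(samples=20, theta=5.0)
        bott = SimConfig(samples=20, theta=5.0,
                         events=[SizeChange(0.01, "pop0", 0.05),
                                 SizeChange(0.5, "pop0", 1.0)])
        s_base = np.mean([simulate_neutral(base, rng=rng)[1].n_sites
                          for _ in range(300)])
        s_bott = np.mean([simulate_neutral(bott, rng=rng)[1].n_sites
                          for _ in range(300)])
        assert s_bott < s_base


class TestSweepInjection:
    @pytest.fixture
    def region(self):
        cfg = SimConfig(samples=30, theta=20.0, rho=10.0, length_bp=1_000_000,
                        seed=77)
        return simulate_neutral(cfg)

    def test_focal_daf_matches_spec(self, region):
        sites, mat = region
        gmap = GeneticMap.uniform(0, 1_000_000)
        spec = SweepSpec(500_000, 0.6, 0.2)
        swept, focal = inject_sweep(mat, spec, gmap, seed=1)
        assert swept.derived_counts()[focal] == round(0.6 * 30)

    def test_extent_to_zero_only_touches_focal_column(self, region):
        sites, mat = region
        gmap = GeneticMap.uniform(0, 1_000_000)
        spec = SweepSpec(500_000, 0.5, 1e-12)
        swept, focal = inject_sweep(mat, spec, gmap, seed=2)
        other = np.delete(np.arange(mat.n_sites), focal)
        assert np.array_equal(swept.alleles[:, other], mat.alleles[:, other])

    def test_carrier_ehh_exceeds_neutral(self, region):
        """Paired check: injection lengthens carrier haplotypes."""
        sites, mat = region
        gmap = GeneticMap.uniform(0, 1_000_000)
        spec = SweepSpec(500_000, 0.6, 0.3)
        rng = np.random.default_rng(8)
        gains = []
        for _ in range(30):
            swept, focal = inject_sweep(mat, spec, gmap, rng=rng)
            to = min(focal + 8, mat.n_sites - 1)
            carriers = np.flatnonzero(swept.alleles[:, focal] == 1)
            core_s = CoreHaplotype(focal, focal + 1, "1", carriers, 30)
            pre = CoreHaplotype(focal, focal + 1, "1",
                                np.sort(carriers), 30)
            e_swept = ehh_at(swept, core_s, to)
            e_neutral = ehh_at(mat, pre, to)
            gains.append(e_swept - e_neutral)
        assert np.mean(gains) > 0

    def test_too_few_carriers_rejected(self, region):
        sites, mat = region
        gmap = GeneticMap.uniform(0, 1_000_000)
        with pytest.raises(ValueError, match="carriers"):
            inject_sweep(mat, SweepSpec(500_000, 0.01, 0.2), gmap, seed=1)


class TestBackground:
    def test_count_and_determinism(self):
        cfg = SimConfig(samples=10, theta=4.0, rho=1.0, length_bp=50_000)
        pools1 = simulate_background(cfg, 4, seed=5)
        pools2 = simulate_background(cfg, 4, seed=5)
        assert len(pools1) == 4
        for (s1, m1), (s2, m2) in zip(pools1, pools2):
            assert np.array_equal(s1.pos, s2.pos)
            assert np.array_equal(m1.alleles, m2.alleles)

    def test_regions_are_independent(self):
        cfg = SimConfig(samples=10, theta=4.0, length_bp=50_000)
        pools = simulate_background(cfg, 3, seed=6)
        positions = [tuple(s.pos) for s, _ in pools]
        assert len(set(positions)) == 3
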