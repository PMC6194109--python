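"""AMOVA variance components, pairwise R_ST, Nei distance, SAMOVA search."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import kstest

from _oracles import amova_oneway_oracle
from conftest import make_cohort, make_panel, make_sample
from ystrkit.cohort import Cohort, qc_filter_biallelic, reduce_for_rst
from ystrkit.structure import (
    amova,
    clamp_negative,
    nei_distance,
    pairwise_rst,
    rst_distance_pair,
    samova_search,
)
from ystrkit.simulate import SimConfig, simulate_cohort, simulate_two_pop_divergence


def _random_cohort(rng, max_samples=12, n_pops=3, n_loci=2):
    """Small random cohort with >= 2 samples per population."""
    sizes = [int(rng.integers(2, max(3, max_samples // n_pops + 1))) for _ in range(n_pops)]
    rows, pops = [], []
    for p, size in enumerate(sizes):
        for _ in range(size):
            rows.append([int(a) for a in rng.integers(8, 14, size=n_loci)])
            pops.append(f"P{p}")
    return make_cohort(rows, populations=pops), rows, pops


class TestDistance:
    def test_identical_haplotypes_zero(self):
        panel = make_panel(3)
        a = make_sample("a", [14, 10, 20], panel=panel)
        assert rst_distance_pair(a, a, panel) == 0.0

    def test_squared_differences(self):
        panel = make_panel(2)
        a = make_sample("a", [14, 10], panel=panel)
        b = make_sample("b", [16, 10], panel=panel)
        c = make_sample("c", [15, 11], panel=panel)
        assert rst_distance_pair(a, b, panel) == 4.0
        assert rst_distance_pair(a, c, panel) == 2.0


class TestAmova:
    def test_internally_monomorphic_pops_phi_one(self):
        cohort = make_cohort(
            [[10], [10], [12], [12]], populations=["A", "A", "B", "B"]
        )
        res = amova(cohort)
        assert res.phi_st == pytest.approx(1.0, abs=1e-12)
        assert res.sigma2_within == 0.0

    def test_identical_population_multisets_no_structure(self):
        """Same haplotype multiset in both populations: no among-group signal.

        The unbiased estimator is slightly negative at finite n (SS_among is
        exactly zero, so sigma_among = -sigma_within/n'); the reported value
        is therefore <= 0 and clamps to 0 for display, and the bias shrinks
        as 1/n."""
        rows = [[10], [11], [12], [10], [11], [12]]
        res = amova(make_cohort(rows, populations=["A"] * 3 + ["B"] * 3))
        assert res.ss["among_pops"] == pytest.approx(0.0, abs=1e-12)
        assert res.phi_st <= 0.0 and max(res.phi_st, 0.0) == 0.0
        big = [[10], [11], [12]] * 20
        res_big = amova(make_cohort(big, populations=["A"] * 30 + ["B"] * 30))
        assert res_big.phi_st <= 0.0 and abs(res_big.phi_st) < 0.05

    def test_matches_brute_force_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            cohort, rows, pops = _random_cohort(rng)
            res = amova(cohort)
            sw, sa, phi = amova_oneway_oracle([tuple(r) for r in rows], pops)
            assert res.sigma2_within == pytest.approx(sw, abs=1e-9)
            assert res.sigma2_among == pytest.approx(sa, abs=1e-9)
            assert res.phi_st == pytest.approx(phi, abs=1e-9)

    def test_singleton_population_rejected_by_name(self):
        cohort = make_cohort([[10], [11], [12]], populations=["A", "A", "B"])
        with pytest.raises(ValueError, match="'B'"):
            amova(cohort)

    def test_null_phi_small_at_n50_per_pop(self):
        phis = []
        for rep in range(20):
            cfg = SimConfig(
                seed=rep, n_samples=100, biallelic_artifact_count=0,
                microvariant_rate=0.0, genealogy_depth_mean=100,
                divergence_generations=0,
            )
            cohort, _ = simulate_two_pop_divergence(cfg)
            reduced = reduce_for_rst(qc_filter_biallelic(cohort)[0])
            phis.append(amova(reduced).phi_st)
        assert abs(float(np.median(phis))) < 0.01

    def test_diverged_pair_phi_above_02(self):
        phis = []
        for rep in range(10):
            cfg = SimConfig(
                seed=100 + rep, n_samples=50, biallelic_artifact_count=0,
                microvariant_rate=0.0, genealogy_depth_mean=100,
                divergence_generations=800,
            )
            cohort, _ = simulate_two_pop_divergence(cfg)
            reduced = reduce_for_rst(qc_filter_biallelic(cohort)[0])
            phis.append(amova(reduced).phi_st)
        assert float(np.median(phis)) > 0.2

    def test_permutation_p_uniform_under_null(self):
        """Permutation p-values should be ~Uniform(0,1) when no structure exists."""
        rng = np.random.default_rng(5)
        pvals = []
        for rep in range(100):
            rows = [[int(a) for a in rng.integers(8, 14, size=2)] for _ in range(20)]
            cohort = make_cohort(rows, populations=["A"] * 10 + ["B"] * 10)
            res = amova(cohort, permutations=99, seed=rep)
            pvals.append(res.p_values["phi_st"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_hierarchical_components_sum_and_phi_consistency(self):
        rng = np.random.default_rng(1)
        cohort, rows, pops = _random_cohort(rng, max_samples=16, n_pops=4)
        grouping = {"P0": "g1", "P1": "g1", "P2": "g2", "P3": "g2"}
        res = amova(cohort, grouping=grouping, permutations=49, seed=2)
        total = res.sigma2_within + res.sigma2_among + res.sigma2_among_groups
        assert res.phi_ct == pytest.approx(res.sigma2_among_groups / total)
        assert res.phi_st == pytest.approx(
            (res.sigma2_among_groups + res.sigma2_among) / total
        )
        for p in res.p_values.values():
            assert 0.0 < p <= 1.0


class TestPairwiseRst:
    def test_equals_two_population_amova_exactly(self, sim_cohort_small):
        cohort, _ = sim_cohort_small
        reduced = reduce_for_rst(qc_filter_biallelic(cohort)[0])
        # restrict to 3 populations for speed
        pops = reduced.populations[:3]
        ids = [s.sample_id for s in reduced.samples if s.population in pops]
        sub = reduced.subset(ids)
        dm, pvals = pairwise_rst(sub)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        by_pop = sub.by_population()
        for a, b in itertools.combinations(sub.populations, 2):
            pair = Cohort(sub.panel, tuple(by_pop[a] + by_pop[b]))
            assert dm[a, b] == amova(pair).phi_st

    def test_clamp_negative_is_display_only(self):
        dm, _ = pairwise_rst(
            make_cohort(
                [[10], [11], [10], [11], [10], [11]],
                populations=["A", "A", "B", "B", "C", "C"],
            )
        )
        clamped = clamp_negative(dm)
        assert clamped.values.min() >= 0.0
        assert dm.values.min() <= clamped.values.min()


class TestNeiDistance:
    def test_identical_profiles_zero(self):
        cohort = make_cohort(
            [[10], [11], [10], [11]], populations=["A", "A", "B", "B"]
        )
        dm = nei_distance(cohort)
        assert dm["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_two_population_toy_matches_hand_arithmetic(self):
        # A: alleles 10,10,11,11 -> p = (.5, .5); B: 10,10,10,11 -> p = (.75, .25)
        cohort = make_cohort(
            [[10], [10], [11], [11], [10], [10], [10], [11]],
            populations=["A"] * 4 + ["B"] * 4,
        )
        jx, jy = 0.5, 0.75**2 + 0.25**2
        jxy = 0.5 * 0.75 + 0.5 * 0.25
        expected = -math.log(jxy / math.sqrt(jx * jy))
        assert nei_distance(cohort)["A", "B"] == pytest.approx(expected, rel=1e-12)

    def test_disjoint_allele_sets_capped_with_warning(self):
        cohort = make_cohort(
            [[10], [10], [20], [20]], populations=["A", "A", "B", "B"]
        )
        with pytest.warns(UserWarning, match="capping"):
            dm = nei_distance(cohort)
        assert dm["A", "B"] == pytest.approx(math.log(1e3))


class TestSamova:
    def test_exhaustive_over_three_populations(self):
        """k=2 over 3 populations: the best of the 3 possible splits, checked by hand."""
        cohort = make_cohort(
            [[10], [10], [10], [11], [20], [20], [21], [21]],
            populations=["A", "A", "B", "B", "C", "C", "C", "C"],
        )
        grouping, res = samova_search(cohort, k=2, seed=0)
        # A and B are similar, C far away: best split isolates C
        assert grouping["A"] == grouping["B"] != grouping["C"]
        # exhaustive check over all 3 bipartitions
        best = max(
            amova(cohort, grouping=g).phi_ct
            for g in (
                {"A": "x", "B": "x", "C": "y"},
                {"A": "x", "B": "y", "C": "x"},
                {"A": "x", "B": "y", "C": "y"},
            )
        )
        assert res.phi_ct == pytest.approx(best, abs=1e-12)

    def test_recovers_two_simulated_clusters(self):
        cfg = SimConfig(
            seed=21, n_samples=80, biallelic_artifact_count=0, microvariant_rate=0.0,
            genealogy_depth_mean=60, divergence_generations=600,
        )
        cohort, _ = simulate_two_pop_divergence(cfg)
        reduced = reduce_for_rst(qc_filter_biallelic(cohort)[0])
        # split each true population into two labels -> 4 pops, true partition 2+2
        relabeled = []
        for i, s in enumerate(reduced.samples):
            from dataclasses import replace

            relabeled.append(replace(s, population=f"{s.population}{'ab'[i % 2]}"))
        cohort4 = Cohort(reduced.panel, tuple(relabeled))
        grouping, res = samova_search(cohort4, k=2, seed=1)
        names = sorted(grouping)
        assert grouping[names[0]] == grouping[names[1]] != grouping[names[2]]
        assert grouping[names[2]] == grouping[names[3]]
        assert res.phi_ct > 0.2

    def test_infeasible_k_rejected(self):
        cohort = make_cohort(
            [[10], [10], [11], [11]], populations=["A", "A", "B", "B"]
        )
        with pytest.raises(ValueError):
            samova_search(cohort, k=2)  # k must be < number of populations
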