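"""Locus weights, minimum spanning networks and median-joining networks."""

import itertools

import networkx as nx
import numpy as np
import pytest

from _oracles import steiner_star_oracle
from conftest import make_cohort, make_panel, make_sample
from ystrkit.cohort import Cohort
from ystrkit.network import (
    LocusWeights,
    collapse_and_msn,
    locus_weights_from_variance,
    mj_network,
    variance_to_weight,
)
from ystrkit.simulate import SimConfig, simulate_cohort


def _uniform_weights(n_loci, weight=10):
    return LocusWeights(
        {f"L{i}": weight for i in range(n_loci)}, {f"L{i}": 0.0 for i in range(n_loci)}
    )


class TestWeights:
    @pytest.mark.parametrize(
        "variance,weight",
        [
            (0.0, 10), (0.1, 10), (0.19999, 10),
            (0.2, 8), (0.3, 8),
            (0.4, 6), (0.5, 6),
            (0.6, 4), (0.7, 4),
            (0.8, 2), (0.9, 2), (5.0, 2),
        ],
    )
    def test_variance_bins_with_half_open_boundaries(self, variance, weight):
        assert variance_to_weight(variance) == weight

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_to_weight(-0.1)

    def test_weights_from_cohort_match_sample_variance(self):
        # L0 monomorphic (var 0 -> 10); L1 alternating 10/12 (var ~1.07 -> 2)
        cohort = make_cohort([[10, 10], [10, 12], [10, 10], [10, 12]])
        lw = locus_weights_from_variance(cohort)
        x = np.array([10, 12, 10, 12])
        assert lw.variances["L1"] == pytest.approx(x.var(ddof=1))
        assert lw.weights == {"L0": 10, "L1": 2}

    def test_inconsistent_weight_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            LocusWeights({"L0": 4}, {"L0": 0.1})

    def test_subset_argument_changes_variance_scope(self):
        cohort = make_cohort([[10], [10], [10], [14]])
        global_w = locus_weights_from_variance(cohort)
        subset_w = locus_weights_from_variance(cohort, sample_ids=["s000", "s001"])
        assert subset_w.variances["L0"] == 0.0
        assert global_w.variances["L0"] > 0.8

    def test_empty_subset_rejected(self):
        cohort = make_cohort([[10]])
        with pytest.raises(KeyError):
            locus_weights_from_variance(cohort, sample_ids=["nope"])


class TestMsn:
    def test_duplicates_collapse_with_multiplicities(self):
        cohort = make_cohort([[10, 11], [10, 11], [10, 12], [11, 11], [12, 12]])
        net = collapse_and_msn(cohort)
        assert net.n_observed == 4
        mults = sorted(d["multiplicity"] for _, d in net.graph.nodes(data=True))
        assert mults == [1, 1, 1, 2]

    def test_simulated_multiplicity_structure_preserved(self, sim_cohort_small):
        cohort, _ = sim_cohort_small
        net = collapse_and_msn(cohort)
        total = sum(d["multiplicity"] for _, d in net.graph.nodes(data=True))
        assert total == len(cohort)
        assert nx.is_connected(net.graph)

    def test_equidistant_triangle_keeps_all_tied_edges(self):
        cohort = make_cohort([[11, 10, 10], [10, 11, 10], [10, 10, 11]])
        net = collapse_and_msn(cohort)
        assert net.graph.number_of_edges() == 3  # full triangle, not 2 tree edges

    def test_every_msn_edge_belongs_to_some_mst(self):
        """On small random instances the MSN equals the union of all MSTs."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            rows = [[int(a) for a in rng.integers(9, 13, size=3)] for _ in range(n)]
            # de-duplicate rows (collapse handles duplicates; this test wants distinct nodes)
            rows = [list(r) for r in {tuple(r) for r in rows}]
            if len(rows) < 3:
                continue
            cohort = make_cohort(rows)
            net = collapse_and_msn(cohort)
            g = nx.Graph()
            nodes = list(net.graph.nodes)
            for u, v in itertools.combinations(nodes, 2):
                du = [int(x.split(",")[0]) for x in u.split("|")]
                dv = [int(x.split(",")[0]) for x in v.split("|")]
                g.add_edge(u, v, weight=sum(abs(a - b) for a, b in zip(du, dv)))
            union = set()
            mst_weight = None
            for tree in nx.SpanningTreeIterator(g):
                w = sum(d["weight"] for _, _, d in tree.edges(data=True))
                if mst_weight is None:
                    mst_weight = w
                if w > mst_weight + 1e-9:
                    break
                union.update(frozenset(e) for e in tree.edges())
            assert {frozenset(e) for e in net.graph.edges()} == union
            assert net.minimum_spanning_length() == pytest.approx(mst_weight)

    def test_dys385_pair_distance_minimizes_over_pairings(self):
        from ystrkit.panel import PPY23, MULTI_COPY_LOCUS

        def hap(pair):
            return [pair if l.name == MULTI_COPY_LOCUS else 12 for l in PPY23]

        cohort = Cohort(
            PPY23,
            (
                make_sample("a", hap((11, 14)), panel=PPY23),
                make_sample("b", hap((14, 11)), panel=PPY23),
                make_sample("c", hap((12, 14)), panel=PPY23),
            ),
        )
        net = collapse_and_msn(cohort)
        assert net.n_observed == 2  # a and b are the same unordered pair
        (u, v, w), = net.graph.edges(data="weight")
        assert w == 1.0  # {11,14} vs {12,14}: best pairing differs by 1


class TestMedianJoining:
    def test_two_haplotypes_single_edge_no_medians(self):
        cohort = make_cohort([[10, 10], [10, 13]])
        net = mj_network(cohort, weights=_uniform_weights(2))
        assert net.n_medians == 0
        assert list(net.graph.edges(data="weight")) == [((10, 10), (10, 13), 30)]

    def test_star_triple_adds_single_median_matching_steiner_oracle(self):
        haps = [(11, 10, 10), (10, 11, 10), (10, 10, 11)]
        cohort = make_cohort([list(h) for h in haps])
        w = _uniform_weights(3)
        net = mj_network(cohort, weights=w)
        base, best, point = steiner_star_oracle(haps, [10, 10, 10])
        assert point == (10, 10, 10)
        assert net.n_medians == 1
        median = next(n for n, d in net.graph.nodes(data=True) if d["is_median"])
        assert median == point
        assert net.minimum_spanning_length() == best

    def test_weighted_star_matches_oracle(self):
        haps = [(12, 10, 10), (10, 12, 10), (10, 10, 12)]
        weights = LocusWeights(
            {"L0": 10, "L1": 8, "L2": 6}, {"L0": 0.1, "L1": 0.25, "L2": 0.45}
        )
        cohort = make_cohort([list(h) for h in haps])
        net = mj_network(cohort, weights=weights)
        base, best, point = steiner_star_oracle(haps, [10, 8, 6])
        assert net.minimum_spanning_length() == best

    def test_duplicate_only_cohort_single_node(self):
        cohort = make_cohort([[10, 10], [10, 10], [10, 10]])
        net = mj_network(cohort, weights=_uniform_weights(2))
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0
        assert net.n_observed == 1

    def test_observed_nodes_never_removed_and_mst_never_lengthens(self):
        cfg = SimConfig(seed=23, n_samples=40, biallelic_artifact_count=0, microvariant_rate=0.0)
        cohort, _ = simulate_cohort(cfg)
        from ystrkit.cohort import reduce_for_rst

        reduced = reduce_for_rst(cohort)
        net = mj_network(reduced)
        observed = {n for n, d in net.graph.nodes(data=True) if not d["is_median"]}
        from ystrkit.structure import repeat_matrix

        expected = {tuple(int(v) for v in row) for row in repeat_matrix(reduced)}
        assert observed == expected
        total_mult = sum(d["multiplicity"] for _, d in net.graph.nodes(data=True))
        assert total_mult == len(reduced)
        # median addition must not lengthen the minimum spanning length
        plain = mj_network(reduced, max_medians=0)
        assert net.minimum_spanning_length() <= plain.minimum_spanning_length()
        assert nx.is_connected(net.graph)

    def test_guard_on_haplotype_count(self):
        rows = [[10 + i] for i in range(6)]
        cohort = make_cohort(rows)
        with pytest.raises(ValueError, match="exceeds the guard"):
            mj_network(cohort, weights=_uniform_weights(1), max_haplotypes=5)

    def test_graphml_and_dot_export(self, tmp_path):
        cohort = make_cohort([[10, 10], [10, 13], [13, 10]])
        net = mj_network(cohort, weights=_uniform_weights(2))
        gml = tmp_path / "net.graphml"
        dot = tmp_path / "net.dot"
        net.write_graphml(gml)
        net.write_dot(dot)
        back = nx.read_graphml(gml)
        assert back.number_of_nodes() == net.graph.number_of_nodes()
        assert "--" in dot.read_text()
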