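"""Minimum-spanning and median-joining haplotype networks.

The minimum spanning network (MSN) collapses identical haplotypes into
multiplicity-sized nodes and keeps *every* edge that belongs to some
minimum spanning tree (tied alternatives are all retained): an edge (u,v)
of length w is in the MSN iff u and v are not connected by strictly
shorter links.

Median-joining (MJ) networks additionally infer unobserved intermediate
("median") haplotypes: candidate consensus vectors of connected node
triples are added when they shorten the network's minimum spanning
length, and medians that stop paying for themselves are pruned, until a
fixpoint. Distances are locus-weighted absolute repeat differences; the
weights are integers assigned from the per-locus repeat variance by the
binning rule (half-open on the left):

    [0, 0.2) -> 10   [0.2, 0.4) -> 8   [0.4, 0.6) -> 6
    [0.6, 0.8) -> 4   >= 0.8 -> 2

so low-variance (slowly mutating) loci count more. MJ operates on the
reduced panel (integer repeats only); the MSN accepts the full panel,
scoring the DYS385a/b pair as the minimum over pairings of summed
absolute differences.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .cohort import Cohort
from .diversity import haplotype_key
from .panel import MULTI_COPY_LOCUS
from .structure import repeat_matrix


# ---------------------------------------------------------------------------
# variance-binned locus weights

_BINS = ((0.2, 10), (0.4, 8), (0.6, 6), (0.8, 4))


def variance_to_weight(variance: float) -> int:
    """Map a per-locus repeat variance to its integer network weight."""
    if variance < 0:
        raise ValueError("variance must be non-negative")
    for upper, weight in _BINS:
        if variance < upper:
            return weight
    return 2


@dataclass(frozen=True)
class LocusWeights:
    weights: dict[str, int]
    variances: dict[str, float]

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if w != variance_to_weight(self.variances[name]):
                raise ValueError(f"weight for {name} inconsistent with its variance bin")


def locus_weights_from_variance(cohort: Cohort, sample_ids=None) -> LocusWeights:
    """Per-locus weights from repeat variance (sample variance, ddof=1).

    ``sample_ids`` restricts the variance computation (e.g. to one
    haplogroup's carriers); the default is the whole cohort, matching the
    convention of computing variances globally even when networks are
    drawn per haplogroup.
    """
    if sample_ids is not None:
        cohort = cohort.subset(sample_ids)
    if not cohort.samples:
        raise ValueError("empty sample subset")
    x = repeat_matrix(cohort).astype(float)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    names = cohort.locus_names
    variances = {n: float(v) for n, v in zip(names, var)}
    return LocusWeights({n: variance_to_weight(v) for n, v in variances.items()}, variances)


# ---------------------------------------------------------------------------
# network container


@dataclass
class HaplotypeNetwork:
    """Graph of observed (and, for MJ, inferred median) haplotypes.

    Node attributes: ``multiplicity`` (0 for medians), ``is_median``,
    ``populations`` (count per population label). Edge attribute:
    ``weight`` (the haplotype distance).
    """

    graph: nx.Graph
    epsilon: int = 0

    @property
    def n_observed(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if not d["is_median"])

    @property
    def n_medians(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if d["is_median"])

    def total_weight(self) -> float:
        return sum(w for _, _, w in self.graph.edges(data="weight"))

    def minimum_spanning_length(self) -> float:
        return sum(
            w for _, _, w in nx.minimum_spanning_edges(self.graph, data=True, keys=False)
            for w in [w["weight"]]
        )

    def write_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for node, d in self.graph.nodes(data=True):
            g.add_node(
                str(node),
                multiplicity=int(d["multiplicity"]),
                is_median=bool(d["is_median"]),
                populations=json.dumps(d["populations"], sort_keys=True),
            )
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(str(u), str(v), weight=float(d["weight"]))
        nx.write_graphml(g, path)

    def write_dot(self, path: str | Path) -> None:
        lines = ["graph haplotypes {"]
        for node, d in self.graph.nodes(data=True):
            shape = "point" if d["is_median"] else "circle"
            lines.append(
                f'  "{node}" [shape={shape}, width={0.2 + 0.1 * d["multiplicity"]:.2f}];'
            )
        for u, v, d in self.graph.edges(data=True):
            lines.append(f'  "{u}" -- "{v}" [label="{d["weight"]:g}"];')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# minimum spanning network on the full panel


def _full_panel_distance(s1, s2, locus_names) -> float:
    total = 0.0
    for name in locus_names:
        a, b = s1.calls[name], s2.calls[name]
        if name == MULTI_COPY_LOCUS and len(a) == 2 and len(b) == 2:
            d1 = abs(a[0].value - b[0].value) + abs(a[1].value - b[1].value)
            d2 = abs(a[0].value - b[1].value) + abs(a[1].value - b[0].value)
            total += min(d1, d2)
        else:
            total += abs(a[0].value - b[0].value)
    return round(total, 9)


def _msn_edges(nodes: list, dist) -> list[tuple]:
    """Edges of the union of all MSTs: (u,v,w) kept iff u,v not joined by shorter links."""
    weighted = sorted(
        ((dist(u, v), i, j) for (i, u), (j, v) in itertools.combinations(enumerate(nodes), 2)),
    )
    parent = list(range(len(nodes)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges = []
    for _, group in itertools.groupby(weighted, key=lambda t: t[0]):
        batch = list(group)
        kept = [(w, i, j) for w, i, j in batch if find(i) != find(j)]
        for w, i, j in kept:
            edges.append((nodes[i], nodes[j], w))
        for _, i, j in kept:
            parent[find(i)] = find(j)
    return edges


def collapse_and_msn(cohort: Cohort) -> HaplotypeNetwork:
    """Collapse identical full-panel haplotypes and build their MSN."""
    if not cohort.samples:
        raise ValueError("empty cohort")
    names = cohort.locus_names
    groups: dict[str, list] = {}
    for s in cohort.samples:
        groups.setdefault(haplotype_key(s, names), []).append(s)
    keys = sorted(groups)
    reps = {k: groups[k][0] for k in keys}

    g = nx.Graph()
    for k in keys:
        pops: dict[str, int] = {}
        for s in groups[k]:
            pops[s.population] = pops.get(s.population, 0) + 1
        g.add_node(k, multiplicity=len(groups[k]), is_median=False, populations=pops)
    if len(keys) > 1:
        for u, v, w in _msn_edges(keys, lambda a, b: _full_panel_distance(reps[a], reps[b], names)):
            g.add_edge(u, v, weight=w)
    return HaplotypeNetwork(g, epsilon=0)


# ---------------------------------------------------------------------------
# median-joining network on the reduced panel


def _weighted_dist(u: tuple, v: tuple, w: tuple) -> int:
    return sum(wi * abs(a - b) for wi, a, b in zip(w, u, v))


def _dist_matrix(nodes: list[tuple], wvec: tuple) -> np.ndarray:
    """Integer matrix of weighted Manhattan distances between haplotype vectors."""
    from scipy.spatial.distance import cdist

    arr = np.asarray(nodes, dtype=float) * np.asarray(wvec, dtype=float)
    return np.rint(cdist(arr, arr, metric="cityblock")).astype(np.int64)


def _epsilon_msn(nodes: list[tuple], wvec: tuple, epsilon: int) -> list[tuple]:
    """Edges whose endpoints are not connected via pairs shorter than w - epsilon."""
    d = _dist_matrix(nodes, wvec)
    n = len(nodes)
    iu, ju = np.triu_indices(n, 1)
    order = np.argsort(d[iu, ju], kind="stable")
    pairs = [(int(d[iu[k], ju[k]]), int(iu[k]), int(ju[k])) for k in order]
    edges = []
    if epsilon == 0:
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for _, group in itertools.groupby(pairs, key=lambda t: t[0]):
            batch = list(group)
            kept = [(w, i, j) for w, i, j in batch if find(i) != find(j)]
            edges.extend((nodes[i], nodes[j], w) for w, i, j in kept)
            for _, i, j in kept:
                parent[find(i)] = find(j)
        return edges
    for w, i, j in pairs:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((a, b) for ww, a, b in pairs if ww < w - epsilon)
        if not nx.has_path(g, i, j):
            edges.append((nodes[i], nodes[j], w))
    return edges


def _mst_weight_matrix(d: np.ndarray) -> int:
    from scipy.sparse.csgraph import minimum_spanning_tree

    if d.shape[0] < 2:
        return 0
    return int(round(minimum_spanning_tree(d).sum()))


def _mst_weight(nodes: list[tuple], wvec: tuple) -> int:
    if len(nodes) < 2:
        return 0
    return _mst_weight_matrix(_dist_matrix(nodes, wvec))


def _consensus(u: tuple, v: tuple, x: tuple) -> tuple:
    """Per-locus consensus of three haplotypes: majority value, else the median."""
    out = []
    for a, b, c in zip(u, v, x):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(sorted((a, b, c))[1])
    return tuple(out)


def mj_network(
    cohort: Cohort,
    weights: LocusWeights | None = None,
    epsilon: int = 0,
    max_medians: int = 500,
    max_haplotypes: int = 200,
) -> HaplotypeNetwork:
    """Median-joining network of a reduced cohort (or subset of it).

    Iterates: build the epsilon-relaxed MSN over current nodes; propose
    consensus medians from connected triples (deterministic lexicographic
    order); accept each candidate that strictly shortens the minimum
    spanning length; prune medians whose removal no longer lengthens it;
    stop at a fixpoint or at ``max_medians``.
    """
    x = repeat_matrix(cohort)
    names = cohort.locus_names
    if weights is None:
        weights = locus_weights_from_variance(cohort)
    wvec = tuple(weights.weights[n] for n in names)

    observed: dict[tuple, dict] = {}
    for row, s in zip(x, cohort.samples):
        key = tuple(int(v) for v in row)
        info = observed.setdefault(key, {"multiplicity": 0, "populations": {}})
        info["multiplicity"] += 1
        info["populations"][s.population] = info["populations"].get(s.population, 0) + 1
    if len(observed) > max_haplotypes:
        raise ValueError(
            f"{len(observed)} distinct haplotypes exceeds the guard ({max_haplotypes}); "
            "analyse a subset or raise max_haplotypes"
        )

    nodes = sorted(observed)
    medians: list[tuple] = []

    for _ in range(1000):  # fixpoint loop; bounded defensively
        all_nodes = nodes + sorted(medians)
        edges = _epsilon_msn(all_nodes, wvec, epsilon)
        adj: dict[tuple, set] = {n: set() for n in all_nodes}
        for u, v, _ in edges:
            adj[u].add(v)
            adj[v].add(u)

        changed = False
        # prune obsolete medians (removal does not lengthen the spanning length)
        base = _mst_weight(all_nodes, wvec)
        for m in sorted(medians):
            rest = [n for n in all_nodes if n != m]
            if _mst_weight(rest, wvec) <= base:
                medians.remove(m)
                all_nodes = rest
                base = _mst_weight(all_nodes, wvec)
                changed = True
        if changed:
            continue

        # propose consensus medians from connected triples centred at v
        candidates = set()
        for v in all_nodes:
            for u, y in itertools.combinations(sorted(adj[v]), 2):
                cand = _consensus(u, v, y)
                if cand not in observed and cand not in medians:
                    candidates.add(cand)
        added = False
        for cand in sorted(candidates):
            if len(medians) >= max_medians:
                break
            trial = all_nodes + [cand]
            if _mst_weight(trial, wvec) < _mst_weight(all_nodes, wvec):
                medians.append(cand)
                all_nodes = trial
                added = True
        if not added:
            break

    all_nodes = nodes + sorted(medians)
    g = nx.Graph()
    for n in all_nodes:
        if n in observed:
            g.add_node(
                n,
                multiplicity=observed[n]["multiplicity"],
                is_median=False,
                populations=observed[n]["populations"],
            )
        else:
            g.add_node(n, multiplicity=0, is_median=True, populations={})
    if len(all_nodes) > 1:
        for u, v, w in _epsilon_msn(all_nodes, wvec, epsilon):
            g.add_edge(u, v, weight=w)
    return HaplotypeNetwork(g, epsilon=epsilon)
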