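"""R_ST-style AMOVA, pairwise population distances, Nei distance, SAMOVA.

The molecular distance between two haplotypes is the Slatkin-style sum
over loci of squared repeat-count differences, which makes the AMOVA
fixation indices R_ST analogues (Phi statistics on repeat variance).
Variance components follow the standard haplotypic analysis-of-molecular-
variance decomposition: sums of squares are obtained from pairwise
squared distances (SS of a group = sum of its pairwise distances divided
by group size), mean squares are equated to their expectations, and
negative component estimates are kept raw — clamping to zero is a
presentation choice, not a statistical one.

Permutation tests: Phi_ST permutes individuals among populations;
Phi_CT permutes whole populations among groups; Phi_SC permutes
individuals among populations within their group. p = (1 + #{perm >=
observed}) / (1 + B).

All operations here require a cohort reduced via
:func:`ystrkit.cohort.reduce_for_rst` (no DYS385a/b, no microvariants);
:func:`nei_distance` is the exception — it is allele-identity based and
accepts the full panel.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cohort import Cohort, SampleRecord
from .distance import DistanceMatrix
from .panel import MULTI_COPY_LOCUS


# ---------------------------------------------------------------------------
# haplotype -> integer repeat vector


def repeat_vector(sample: SampleRecord, locus_names: list[str]) -> np.ndarray:
    """Integer repeat counts in panel order; rejects pairs and microvariants."""
    out = np.empty(len(locus_names), dtype=np.int64)
    for i, name in enumerate(locus_names):
        alleles = sample.calls[name]
        if len(alleles) != 1:
            raise ValueError(
                f"sample {sample.sample_id}: locus {name} has {len(alleles)} alleles; "
                "reduce the cohort first"
            )
        a = alleles[0]
        if a.is_microvariant:
            raise ValueError(
                f"sample {sample.sample_id}: microvariant at {name}; reduce the cohort first"
            )
        out[i] = a.repeats
    return out


def repeat_matrix(cohort: Cohort) -> np.ndarray:
    if MULTI_COPY_LOCUS in cohort.locus_names:
        raise ValueError("cohort still contains DYS385a/b; apply reduce_for_rst first")
    names = cohort.locus_names
    return np.vstack([repeat_vector(s, names) for s in cohort.samples])


def rst_distance_pair(h1: SampleRecord, h2: SampleRecord, panel) -> float:
    """Sum over loci of squared repeat-count differences."""
    names = [l.name for l in panel if l.copy_number == 1]
    v1 = repeat_vector(h1, names)
    v2 = repeat_vector(h2, names)
    if v1.shape != v2.shape:
        raise ValueError("locus mismatch")
    return float(np.sum((v1 - v2) ** 2))


def squared_distance_matrix(cohort: Cohort) -> np.ndarray:
    """n x n matrix of summed squared repeat differences."""
    x = repeat_matrix(cohort).astype(float)
    return squareform(pdist(x, metric="sqeuclidean"))


# ---------------------------------------------------------------------------
# AMOVA


@dataclass(frozen=True)
class AmovaResult:
    """Variance components and Phi statistics of a (possibly hierarchical) AMOVA."""

    sigma2_within: float
    sigma2_among: float
    phi_st: float
    sigma2_among_groups: float | None = None
    phi_ct: float | None = None
    phi_sc: float | None = None
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None
    ss: dict[str, float] = field(default_factory=dict)
    df: dict[str, int] = field(default_factory=dict)

    @property
    def percent_within(self) -> float:
        """Within-population share of total variance, in percent (clamped at 0)."""
        comps = [self.sigma2_within, self.sigma2_among]
        if self.sigma2_among_groups is not None:
            comps.append(self.sigma2_among_groups)
        comps = [max(c, 0.0) for c in comps]
        total = sum(comps)
        return 100.0 * comps[0] / total if total > 0 else float("nan")

    def to_dict(self) -> dict:
        d = {
            "sigma2_within": self.sigma2_within,
            "sigma2_among": self.sigma2_among,
            "phi_st": self.phi_st,
            "p_values": self.p_values,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "ss": self.ss,
            "df": self.df,
        }
        if self.sigma2_among_groups is not None:
            d.update(
                sigma2_among_groups=self.sigma2_among_groups,
                phi_ct=self.phi_ct,
                phi_sc=self.phi_sc,
            )
        return d


def _group_ss(d: np.ndarray, idx: np.ndarray) -> float:
    """SS of one group from pairwise squared distances: sum_{i<j} d_ij / n."""
    sub = d[np.ix_(idx, idx)]
    return float(sub.sum()) / (2.0 * len(idx))


def _phi(num: float, den: float) -> float:
    return num / den if den != 0.0 else 0.0


def _one_level_components(d: np.ndarray, pops: list[np.ndarray]):
    n = d.shape[0]
    p = len(pops)
    ss_total = float(d.sum()) / (2.0 * n)
    ss_wp = sum(_group_ss(d, idx) for idx in pops)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = p - 1, n - p
    sigma_w = ss_wp / df_wp
    sizes = np.array([len(idx) for idx in pops], dtype=float)
    n_prime = (n - float(np.sum(sizes**2)) / n) / df_ap
    sigma_a = (ss_ap / df_ap - sigma_w) / n_prime
    phi_st = _phi(sigma_a, sigma_a + sigma_w)
    return sigma_w, sigma_a, phi_st, {"total": ss_total, "among_pops": ss_ap, "within_pops": ss_wp}, {
        "among_pops": df_ap,
        "within_pops": df_wp,
    }


def _hierarchical_components(d: np.ndarray, pops: list[np.ndarray], group_of: np.ndarray):
    """Three-level decomposition: groups / populations-in-groups / individuals."""
    n = d.shape[0]
    p = len(pops)
    g = int(group_of.max()) + 1
    sizes = np.array([len(idx) for idx in pops], dtype=float)
    group_members = [
        np.concatenate([pops[i] for i in range(p) if group_of[i] == gi]) for gi in range(g)
    ]
    group_sizes = np.array([len(m) for m in group_members], dtype=float)

    ss_total = float(d.sum()) / (2.0 * n)
    ss_wp = sum(_group_ss(d, idx) for idx in pops)
    ss_wg = sum(_group_ss(d, m) for m in group_members)
    ss_ap = ss_wg - ss_wp  # among populations within groups
    ss_ag = ss_total - ss_wg  # among groups

    df_ag, df_ap, df_wp = g - 1, p - g, n - p
    sigma_c = ss_wp / df_wp

    # expected-mean-square coefficients
    per_group_sq = np.array(
        [np.sum(sizes[group_of == gi] ** 2) / group_sizes[gi] for gi in range(g)]
    )
    n1 = (n - per_group_sq.sum()) / df_ap
    n2 = (per_group_sq.sum() - np.sum(sizes**2) / n) / df_ag
    n3 = (n - np.sum(group_sizes**2) / n) / df_ag

    sigma_b = (ss_ap / df_ap - sigma_c) / n1
    sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3

    total = sigma_a + sigma_b + sigma_c
    phi_st = _phi(sigma_a + sigma_b, total)
    phi_ct = _phi(sigma_a, total)
    phi_sc = _phi(sigma_b, sigma_b + sigma_c)
    ss = {
        "total": ss_total,
        "among_groups": ss_ag,
        "among_pops_within_groups": ss_ap,
        "within_pops": ss_wp,
    }
    df = {"among_groups": df_ag, "among_pops_within_groups": df_ap, "within_pops": df_wp}
    return sigma_c, sigma_b, sigma_a, phi_st, phi_ct, phi_sc, ss, df


def _population_indices(cohort: Cohort) -> tuple[list[str], list[np.ndarray]]:
    pops = cohort.populations
    labels = np.array([s.population for s in cohort.samples])
    idx = [np.flatnonzero(labels == p) for p in pops]
    for p, i in zip(pops, idx):
        if len(i) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 samples")
    return pops, idx


def amova(
    cohort: Cohort,
    grouping: dict[str, str] | None = None,
    permutations: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA on squared repeat differences.

    With ``grouping=None`` (or a single group) this is the one-level
    populations-within-total analysis yielding Phi_ST; a grouping with two
    or more groups yields the hierarchical Phi_CT / Phi_SC / Phi_ST.
    """
    pops, idx = _population_indices(cohort)
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    d = squared_distance_matrix(cohort)
    rng = np.random.default_rng(seed)

    if grouping is not None:
        missing = [p for p in pops if p not in grouping]
        if missing:
            raise ValueError(f"grouping missing populations: {missing}")
        group_names = sorted({grouping[p] for p in pops})
        if len(group_names) >= 2:
            return _amova_hierarchical(d, pops, idx, grouping, group_names, permutations, rng, seed)

    sigma_w, sigma_a, phi_st, ss, df = _one_level_components(d, idx)
    p_values: dict[str, float] = {}
    if permutations > 0:
        sizes = [len(i) for i in idx]
        count = 0
        order = np.arange(d.shape[0])
        for _ in range(permutations):
            rng.shuffle(order)
            perm_pops = _split_by_sizes(order, sizes)
            _, _, phi_perm, _, _ = _one_level_components(d, perm_pops)
            if phi_perm >= phi_st:
                count += 1
        p_values["phi_st"] = (1 + count) / (1 + permutations)
    return AmovaResult(
        sigma2_within=sigma_w,
        sigma2_among=sigma_a,
        phi_st=phi_st,
        p_values=p_values,
        n_permutations=permutations,
        seed=seed,
        ss=ss,
        df=df,
    )


def _split_by_sizes(order: np.ndarray, sizes: list[int]) -> list[np.ndarray]:
    out, start = [], 0
    for s in sizes:
        out.append(order[start : start + s])
        start += s
    return out


def _amova_hierarchical(d, pops, idx, grouping, group_names, permutations, rng, seed):
    group_of = np.array([group_names.index(grouping[p]) for p in pops])
    if np.bincount(group_of, minlength=len(group_names)).min() < 1:
        raise ValueError("every group must contain at least one population")
    sigma_c, sigma_b, sigma_a, phi_st, phi_ct, phi_sc, ss, df = _hierarchical_components(
        d, idx, group_of
    )
    p_values: dict[str, float] = {}
    if permutations > 0:
        n = d.shape[0]
        sizes = [len(i) for i in idx]
        c_st = c_ct = c_sc = 0
        order = np.arange(n)
        for _ in range(permutations):
            # Phi_ST: individuals among populations
            rng.shuffle(order)
            perm_pops = _split_by_sizes(order, sizes)
            _, _, _, st, _, _, _, _ = _hierarchical_components(d, perm_pops, group_of)
            c_st += st >= phi_st
            # Phi_CT: populations among groups
            perm_group = rng.permutation(group_of)
            _, _, _, _, ct, _, _, _ = _hierarchical_components(d, idx, perm_group)
            c_ct += ct >= phi_ct
            # Phi_SC: individuals among populations within groups
            perm_pops_sc = [i.copy() for i in idx]
            for gi in range(len(group_names)):
                members = [k for k in range(len(pops)) if group_of[k] == gi]
                pool = np.concatenate([idx[k] for k in members])
                pool = rng.permutation(pool)
                start = 0
                for k in members:
                    perm_pops_sc[k] = pool[start : start + len(idx[k])]
                    start += len(idx[k])
            _, _, _, _, _, sc, _, _ = _hierarchical_components(d, perm_pops_sc, group_of)
            c_sc += sc >= phi_sc
        p_values = {
            "phi_st": (1 + c_st) / (1 + permutations),
            "phi_ct": (1 + c_ct) / (1 + permutations),
            "phi_sc": (1 + c_sc) / (1 + permutations),
        }
    return AmovaResult(
        sigma2_within=sigma_c,
        sigma2_among=sigma_b,
        sigma2_among_groups=sigma_a,
        phi_st=phi_st,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        p_values=p_values,
        n_permutations=permutations,
        seed=seed,
        ss=ss,
        df=df,
    )


def pairwise_rst(
    cohort: Cohort, permutations: int = 0, seed: int | None = None
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Phi_ST for every population pair (raw estimates; may be negative).

    Each pair is analysed with :func:`amova` restricted to those two
    populations, so the pairwise value agrees exactly with the
    two-population AMOVA. The companion DataFrame holds permutation
    p-values (NaN on the diagonal, and everywhere when permutations=0).
    """
    pops = cohort.populations
    k = len(pops)
    values = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    by_pop = cohort.by_population()
    for i, j in itertools.combinations(range(k), 2):
        sub = Cohort(cohort.panel, tuple(by_pop[pops[i]] + by_pop[pops[j]]))
        res = amova(sub, permutations=permutations, seed=seed)
        values[i, j] = values[j, i] = res.phi_st
        if permutations > 0:
            pvals[i, j] = pvals[j, i] = res.p_values["phi_st"]
    return DistanceMatrix(tuple(pops), values), pd.DataFrame(pvals, index=pops, columns=pops)


def clamp_negative(dm: DistanceMatrix) -> DistanceMatrix:
    """Display helper: negative estimates set to zero."""
    return DistanceMatrix(dm.labels, np.maximum(dm.values, 0.0))


# ---------------------------------------------------------------------------
# Nei (1972) standard genetic distance


def nei_distance(
    cohort: Cohort, zero_identity_cap: float = math.log(1e3)
) -> DistanceMatrix:
    """Nei's standard distance D = -ln I between population pairs.

    I = J_XY / sqrt(J_X * J_Y) with the J terms (expected homozygosity and
    shared-allele probability) averaged over loci; allele-identity based,
    so the full panel including DYS385a/b is usable (the pair contributes
    both alleles). A pair with zero shared identity (I = 0, impossible
    distance) is capped at ``zero_identity_cap`` with a warning.
    """
    pops = cohort.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    names = cohort.locus_names
    by_pop = cohort.by_population()
    # per population, per locus allele frequency dict
    freqs: dict[str, list[dict]] = {}
    for p in pops:
        rows = []
        for name in names:
            counts: dict = {}
            total = 0
            for s in by_pop[p]:
                for a in s.calls[name]:
                    counts[a] = counts.get(a, 0) + 1
                    total += 1
            if total == 0:
                raise ValueError(f"population {p!r} has no data at locus {name}")
            rows.append({a: c / total for a, c in counts.items()})
        freqs[p] = rows

    k = len(pops)
    values = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        fx, fy = freqs[pops[i]], freqs[pops[j]]
        jx = np.mean([sum(v * v for v in row.values()) for row in fx])
        jy = np.mean([sum(v * v for v in row.values()) for row in fy])
        jxy = np.mean(
            [
                sum(rx[a] * ry.get(a, 0.0) for a in rx)
                for rx, ry in zip(fx, fy)
            ]
        )
        identity = jxy / math.sqrt(jx * jy)
        if identity <= math.exp(-zero_identity_cap):
            warnings.warn(
                f"Nei identity ~0 between {pops[i]} and {pops[j]}; capping distance"
            )
            d = zero_identity_cap
        else:
            d = -math.log(identity)
        values[i, j] = values[j, i] = max(d, 0.0)
    return DistanceMatrix(tuple(pops), values)


# ---------------------------------------------------------------------------
# SAMOVA-style group search


def _stirling2(n: int, k: int) -> int:
    s = [[0] * (k + 1) for _ in range(n + 1)]
    s[0][0] = 1
    for i in range(1, n + 1):
        for j in range(1, min(i, k) + 1):
            s[i][j] = j * s[i - 1][j] + s[i - 1][j - 1]
    return s[n][k]


def _partitions_into_k(items: list[str], k: int):
    """All set partitions of items into exactly k non-empty blocks."""

    def rec(i, blocks):
        if i == len(items):
            if len(blocks) == k:
                yield [list(b) for b in blocks]
            return
        if len(blocks) + (len(items) - i) < k:
            return
        for b in blocks:
            b.append(items[i])
            yield from rec(i + 1, blocks)
            b.pop()
        if len(blocks) < k:
            blocks.append([items[i]])
            yield from rec(i + 1, blocks)
            blocks.pop()

    yield from rec(0, [])


def samova_search(
    cohort: Cohort,
    k: int,
    restarts: int = 10,
    seed: int | None = None,
    permutations: int = 0,
    exhaustive_limit: int = 10_000,
) -> tuple[dict[str, str], AmovaResult]:
    """Find the grouping of populations into k groups maximizing Phi_CT.

    Exhaustive enumeration when the number of k-block partitions is at most
    ``exhaustive_limit``; otherwise simulated annealing (geometric cooling,
    rate 0.95, 100 moves per temperature, best of ``restarts`` starts),
    deterministic given the seed.
    """
    pops, idx = _population_indices(cohort)
    if not (2 <= k < len(pops)):
        raise ValueError(f"k must satisfy 2 <= k < {len(pops)}, got {k}")
    d = squared_distance_matrix(cohort)

    def objective(group_of: np.ndarray) -> float:
        if np.bincount(group_of, minlength=k).min() == 0:
            return -np.inf
        return _hierarchical_components(d, idx, group_of)[4]

    rng = np.random.default_rng(seed)
    if _stirling2(len(pops), k) <= exhaustive_limit:
        best, best_phi = None, -np.inf
        for blocks in _partitions_into_k(list(range(len(pops))), k):
            group_of = np.empty(len(pops), dtype=int)
            for gi, block in enumerate(blocks):
                group_of[block] = gi
            phi = objective(group_of)
            if phi > best_phi:
                best, best_phi = group_of.copy(), phi
    else:
        best, best_phi = None, -np.inf
        for _ in range(restarts):
            state = _anneal(objective, len(pops), k, rng)
            phi = objective(state)
            if phi > best_phi:
                best, best_phi = state, phi

    grouping = {pops[i]: f"group{best[i] + 1}" for i in range(len(pops))}
    result = amova(cohort, grouping=grouping, permutations=permutations, seed=seed)
    return grouping, result


def _anneal(objective, n_pops: int, k: int, rng) -> np.ndarray:
    # random feasible start: each group seeded once, remainder uniform
    state = np.concatenate([np.arange(k), rng.integers(0, k, n_pops - k)])
    rng.shuffle(state)
    current = objective(state)
    best, best_val = state.copy(), current
    temp = 0.1
    while temp > 1e-4:
        for _ in range(100):
            i = int(rng.integers(n_pops))
            old = state[i]
            new = int(rng.integers(k))
            if new == old:
                continue
            state[i] = new
            cand = objective(state)
            if cand >= current or rng.random() < math.exp((cand - current) / temp):
                current = cand
                if current > best_val:
                    best, best_val = state.copy(), current
            else:
                state[i] = old
        temp *= 0.95
    return best
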