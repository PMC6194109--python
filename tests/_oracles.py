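"""Independent brute-force oracles used only by the tests.

Each oracle is written as explicit enumeration/loops from first
principles, deliberately avoiding the package's vectorized code paths.
"""

from __future__ import annotations

import itertools
import math


def pairwise_identity_probability(observations) -> float:
    """P(two draws with replacement identical) = sum p_i^2, by double loop."""
    n = len(observations)
    matches = 0
    for a in observations:
        for b in observations:
            matches += a == b
    return matches / (n * n)


def amova_oneway_oracle(vectors, labels):
    """One-level AMOVA variance components from explicit sums of squares.

    ``vectors``: list of integer tuples; ``labels``: population label per
    sample. Returns (sigma_within, sigma_among, phi_st).
    """

    def dist(u, v):
        return sum((a - b) ** 2 for a, b in zip(u, v))

    n = len(vectors)
    pops = sorted(set(labels))
    members = {p: [i for i, l in enumerate(labels) if l == p] for p in pops}

    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += dist(vectors[i], vectors[j])
    ss_total /= n

    ss_within = 0.0
    for p in pops:
        idx = members[p]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += dist(vectors[idx[a]], vectors[idx[b]])
        ss_within += acc / len(idx)

    ss_among = ss_total - ss_within
    df_among = len(pops) - 1
    df_within = n - len(pops)
    sigma_w = ss_within / df_within
    n_prime = (n - sum(len(members[p]) ** 2 for p in pops) / n) / df_among
    sigma_a = (ss_among / df_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom != 0 else 0.0
    return sigma_w, sigma_a, phi


def mantel_exhaustive_oracle(m1, m2) -> tuple[float, float]:
    """(r, p) over all n! relabelings of m2, computed with plain loops."""
    n = len(m1)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    def corr(mat):
        xs = [m1[i][j] for i, j in pairs]
        ys = [mat[i][j] for i, j in pairs]
        mx = sum(xs) / len(xs)
        my = sum(ys) / len(ys)
        sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        sxx = sum((x - mx) ** 2 for x in xs)
        syy = sum((y - my) ** 2 for y in ys)
        if sxx == 0 or syy == 0:
            return 0.0
        return sxy / math.sqrt(sxx * syy)

    r_obs = corr(m2)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        permuted = [[m2[perm[i]][perm[j]] for j in range(n)] for i in range(n)]
        count += corr(permuted) >= r_obs - 1e-12
        total += 1
    return r_obs, count / total


def steiner_star_oracle(haplotypes, weights, state_pad: int = 1):
    """Minimum total weighted length of a spanning structure allowed one
    extra (Steiner) point, by exhaustive enumeration over the state box."""

    def dist(u, v):
        return sum(w * abs(a - b) for w, a, b in zip(weights, u, v))

    def mst_len(points):
        n = len(points)
        if n < 2:
            return 0
        chosen, best = {0}, 0
        while len(chosen) < n:
            w, nxt = min(
                (dist(points[i], points[j]), j)
                for i in chosen
                for j in range(n)
                if j not in chosen
            )
            best += w
            chosen.add(nxt)
        return best

    base = mst_len(list(haplotypes))
    ranges = [
        range(min(h[k] for h in haplotypes) - state_pad, max(h[k] for h in haplotypes) + state_pad + 1)
        for k in range(len(haplotypes[0]))
    ]
    best = base
    best_point = None
    for cand in itertools.product(*ranges):
        if cand in haplotypes:
            continue
        total = mst_len(list(haplotypes) + [cand])
        if total < best:
            best, best_point = total, cand
    return base, best, best_point
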