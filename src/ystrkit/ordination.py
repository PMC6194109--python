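"""Ordination and geography-vs-genetics association.

* :func:`pcoa` — classical (metric) scaling of a distance matrix via the
  double-centered Gram matrix eigendecomposition; explained percentages
  are shares of the positive eigenvalues only.
* :func:`sammon_mds` — Sammon's nonlinear mapping, minimizing the
  distance-weighted stress by gradient descent with a step-halving line
  search from a PCoA initialization, so the stress sequence is monotone
  non-increasing and the result deterministic.
* :func:`haversine_km` — great-circle distance (Earth radius 6371 km).
* :func:`mantel_test` — Pearson correlation of two distance matrices over
  the off-diagonal upper triangle, with a permutation p-value (exact
  enumeration of all n! label permutations when feasible). The squared
  correlation doubles as the R^2 of the distance-on-distance regression
  framing; both share the same correlation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class OrdinationResult:
    labels: tuple[str, ...]
    coordinates: np.ndarray  # (n, k)
    explained: tuple[float, ...] = ()  # percentages, PCoA only
    stress: float | None = None  # MDS only
    iterations: int = 0
    stress_history: tuple[float, ...] = ()  # per-iteration stress, MDS only

    def embedded_distances(self) -> np.ndarray:
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(self.coordinates))


@dataclass(frozen=True)
class GeoGeneticTest:
    r_squared: float
    correlation: float
    p_value: float
    permutations: int
    seed: int | None = None
    exhaustive: bool = False


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical scaling. ``k`` may not exceed the number of positive eigenvalues."""
    if k < 1:
        raise ValueError("k must be >= 1")
    d2 = dm.values**2
    n = len(dm)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(abs(eigval[0]), 1.0) * 1e-10
    positive = eigval > tol
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise ValueError("no positive eigenvalues; degenerate distance matrix")
    if k > n_pos:
        raise ValueError(f"k={k} exceeds number of positive eigenvalues ({n_pos})")
    most_negative = eigval.min()
    if most_negative < 0 and abs(most_negative) > 0.05 * eigval[0]:
        warnings.warn(
            "distance matrix is strongly non-Euclidean: "
            f"|lambda_min|/lambda_max = {abs(most_negative) / eigval[0]:.3f}"
        )
    pos_val = eigval[:n_pos]
    coords = eigvec[:, :k] * np.sqrt(pos_val[:k])
    explained = tuple(100.0 * pos_val / pos_val.sum())
    return OrdinationResult(dm.labels, coords, explained=explained)


def _sammon_stress_grad(delta: np.ndarray, y: np.ndarray, need_grad: bool = True):
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(y))
    np.fill_diagonal(d, 1.0)  # excluded from sums anyway
    c = delta[np.triu_indices_from(delta, 1)].sum()
    mask = ~np.eye(len(y), dtype=bool)
    diff = delta - d
    stress = float(np.sum((diff[mask] ** 2) / delta[mask]) / (2.0 * c))
    if not need_grad:
        return stress, None
    d_safe = np.maximum(d, 1e-12)
    w = np.where(mask, diff / (delta * d_safe + np.where(mask, 0.0, 1.0)), 0.0)
    # grad_i = (-2/c) * sum_j w_ij (y_i - y_j)
    grad = (-2.0 / c) * (y * w.sum(axis=1)[:, None] - w @ y)
    return stress, grad


def sammon_mds(
    dm: DistanceMatrix,
    k: int = 2,
    max_iter: int = 500,
    tol: float = 1e-12,
    seed: int | None = None,
    n_restarts: int = 0,
) -> OrdinationResult:
    """Sammon mapping with PCoA initialization and step-halving descent.

    Off-diagonal distances must all be positive (the stress weights divide
    by them); collapse duplicate rows before calling. ``seed`` matters only
    when random restarts are requested.
    """
    delta = dm.values
    n = len(dm)
    iu = np.triu_indices(n, 1)
    if np.any(delta[iu] <= 0):
        raise ValueError(
            "zero off-diagonal distance: collapse duplicate entries before Sammon mapping"
        )

    inits = [_pcoa_init(dm, k)]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        inits.append(rng.standard_normal((n, k)) * np.mean(delta[iu]))

    best = None
    for y0 in inits:
        stress, y, iters, history = _sammon_descend(delta, y0, max_iter, tol)
        if best is None or stress < best[0]:
            best = (stress, y, iters, history)
    stress, y, iters, history = best
    return OrdinationResult(
        dm.labels, y, stress=stress, iterations=iters, stress_history=history
    )


def _pcoa_init(dm: DistanceMatrix, k: int) -> np.ndarray:
    d2 = dm.values**2
    n = len(dm)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:k]
    coords = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))
    # break exact ties/degeneracy deterministically
    if np.allclose(coords, 0.0):
        coords = coords + 1e-6 * np.arange(n * k).reshape(n, k)
    return coords


def _sammon_descend(delta, y0, max_iter, tol):
    y = y0.copy()
    stress, grad = _sammon_stress_grad(delta, y)
    history = [stress]
    step = 0.3  # Sammon's "magic factor" as the initial step scale
    iters = 0
    for iters in range(1, max_iter + 1):
        gnorm = np.linalg.norm(grad)
        if gnorm == 0.0 or stress <= tol:
            break
        direction = -grad / gnorm
        lam = step * max(np.abs(y).max(), 1.0)
        improved = False
        for _ in range(40):  # step halving: guarantees monotone stress
            cand = y + lam * direction
            cand_stress, _ = _sammon_stress_grad(delta, cand, need_grad=False)
            if cand_stress < stress:
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
        y = cand
        new_stress, grad = _sammon_stress_grad(delta, y)
        history.append(new_stress)
        if stress - new_stress < tol * max(stress, 1.0):
            stress = new_stress
            break
        stress = new_stress
    return stress, y, iters, tuple(history)


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance between (lat, lon) points in degrees."""
    for lat, lon in (a, b):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    s = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def geographic_distance_matrix(locations: dict[str, tuple[float, float]]) -> DistanceMatrix:
    """Pairwise great-circle distances between labeled (lat, lon) points."""
    labels = list(locations)
    n = len(labels)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        values[i, j] = values[j, i] = haversine_km(locations[labels[i]], locations[labels[j]])
    return DistanceMatrix(tuple(labels), values)


def mantel_test(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    permutations: int = 999,
    seed: int | None = None,
) -> GeoGeneticTest:
    """Mantel correlation between two distance matrices with matching labels.

    One-sided (greater) permutation p-value from relabeling ``dm2``. When
    n! <= permutations the enumeration is exhaustive and the p-value exact:
    p = #{permutations with r >= observed r} / n! (identity included);
    otherwise p = (1 + #{r_perm >= r}) / (1 + permutations) over seeded
    random permutations.
    """
    if dm1.labels != dm2.labels:
        raise ValueError("distance matrices must share labels in the same order")
    n = len(dm1)
    if n < 3:
        raise ValueError("Mantel test needs at least 3 labels")
    iu = np.triu_indices(n, 1)
    x = dm1.values[iu]

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(dm2.values)
    if math.factorial(n) <= permutations:
        total = count = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            r = corr(dm2.values[np.ix_(p, p)])
            count += r >= r_obs - 1e-12
            total += 1
        p_value = count / total
        return GeoGeneticTest(r_obs**2, r_obs, p_value, total, seed, exhaustive=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        p = rng.permutation(n)
        count += corr(dm2.values[np.ix_(p, p)]) >= r_obs - 1e-12
    p_value = (1 + count) / (1 + permutations)
    return GeoGeneticTest(r_obs**2, r_obs, p_value, permutations, seed)
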