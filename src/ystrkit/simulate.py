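"""Forward stepwise-mutation-model (SMM) cohort simulator.

Generates synthetic Y-STR cohorts with the statistical structure the
analysis pipeline assumes, so every stage runs at desk scale without
real genotypes. The model:

* each sample draws a haplogroup from the configured mix (defaults mirror
  a North-Indian-subcontinent composition: R1a 51.5%, H 16.2%, L 15.8%,
  remainder over minor lineages);
* each haplogroup has a fixed modal founder haplotype (generated once
  from an internal seed, so founders are stable across runs);
* lineages are star-like: each sample sits at the end of an independent
  branch of exponential(mean) length in generations, and each locus
  mutates Poisson(depth x rate) times, each mutation a symmetric +-1
  repeat step (single-step SMM);
* populations/regions/coordinates are assigned by weight, independent of
  haplogroup;
* rare microvariant alleles and an exactly controllable number of
  biallelic (two-peak) artifact samples are injected afterwards.

Everything is reproducible from ``SimConfig.seed``; a truth table records
per-sample haplogroup, branch depth and artifact flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import AlleleCall, Cohort, SampleRecord
from .panel import MULTI_COPY_LOCUS, PPY23, PPY23_MODAL_ALLELES, LocusDef

_FOUNDER_SEED = 20180923  # founders are a fixture, independent of cohort seed

DEFAULT_HAPLOGROUP_MIX: dict[str, float] = {
    "R1a": 0.515,
    "H": 0.162,
    "L": 0.158,
    "Q": 0.050,
    "J2b": 0.040,
    "J2a1": 0.030,
    "J1": 0.020,
    "G2a": 0.015,
    "R1b": 0.010,
}

#: 12 sampling locations in 4 geographic regions (name, region, lat, lon, weight).
DEFAULT_POPULATIONS: tuple[tuple[str, str, float, float, float], ...] = (
    ("UP", "North", 26.85, 80.95, 1.0),
    ("RJ", "North", 26.91, 75.79, 1.0),
    ("DL", "North", 28.61, 77.21, 1.0),
    ("MH", "West", 19.08, 72.88, 1.0),
    ("GJ", "West", 23.22, 72.65, 1.0),
    ("WB", "East", 22.57, 88.36, 1.0),
    ("JH", "East", 23.34, 85.31, 1.0),
    ("OR", "East", 20.27, 85.84, 1.0),
    ("KA", "South", 12.97, 77.59, 1.0),
    ("TN", "South", 13.08, 80.27, 1.0),
    ("KL", "South", 8.52, 76.94, 1.0),
    ("AP", "South", 17.38, 78.48, 1.0),
)

_MICROVARIANT_PRONE = ("DYS458", MULTI_COPY_LOCUS)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the package's study conditions."""

    seed: int = 0
    n_samples: int = 407
    haplogroup_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAPLOGROUP_MIX)
    )
    genealogy_depth_mean: float = 300.0  # generations to the haplogroup founder
    populations: tuple[tuple[str, str, float, float, float], ...] = DEFAULT_POPULATIONS
    divergence_generations: int = 0  # two-population mode only
    microvariant_rate: float = 0.02  # per-sample probability of one partial-repeat allele
    biallelic_artifact_count: int = 4
    panel: tuple[LocusDef, ...] = PPY23
    mutation_rates: dict[str, float] | None = None  # override per-locus panel rates

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        total = sum(self.haplogroup_mix.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"haplogroup_mix must sum to 1, got {total}")
        if self.genealogy_depth_mean <= 0:
            raise ValueError("genealogy_depth_mean must be positive")
        if not (0.0 <= self.microvariant_rate < 1.0):
            raise ValueError("microvariant_rate must be in [0, 1)")
        if not (0 <= self.biallelic_artifact_count <= self.n_samples):
            raise ValueError("biallelic_artifact_count must be in [0, n_samples]")
        if self.divergence_generations < 0:
            raise ValueError("divergence_generations must be non-negative")
        if not self.populations:
            raise ValueError("populations must be non-empty")
        for rate in (self.mutation_rates or {}).values():
            if not (0.0 <= rate < 0.05):
                raise ValueError(f"mutation rate out of range: {rate}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "populations" in d:
            d["populations"] = tuple(tuple(p) for p in d["populations"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _locus_rate(config: SimConfig, locus: LocusDef) -> float:
    if config.mutation_rates and locus.name in config.mutation_rates:
        return config.mutation_rates[locus.name]
    return locus.mutation_rate


def _allele_slots(panel) -> list[tuple[str, int]]:
    """(locus name, copy index) per allele column; DYS385a/b contributes two."""
    return [(l.name, c) for l in panel for c in range(l.copy_number)]


def founder_haplotypes(
    haplogroups, panel=PPY23, spread: int = 3, seed: int = _FOUNDER_SEED
) -> dict[str, np.ndarray]:
    """Fixed modal haplotypes per haplogroup (allele-slot vectors).

    Generated once from an internal seed: each founder offsets the panel's
    typical modal alleles by per-slot integers in [-spread, spread], redrawn
    until all founders are pairwise distinct. Stable fixture across runs.
    """
    slots = _allele_slots(panel)
    base = np.array([PPY23_MODAL_ALLELES.get(name, 12) for name, _ in slots])
    rng = np.random.default_rng(seed)
    founders: dict[str, np.ndarray] = {}
    for hg in sorted(haplogroups):
        for _ in range(100):
            vec = base + rng.integers(-spread, spread + 1, size=len(slots))
            vec = np.maximum(vec, 5)
            if not any(np.array_equal(vec, f) for f in founders.values()):
                founders[hg] = vec
                break
        else:  # pragma: no cover - unreachable at sane spreads
            raise RuntimeError("could not generate distinct founders")
    return founders


def _mutate(rng, start: np.ndarray, depths: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """SMM: net displacement of Poisson(depth*rate) symmetric +-1 steps."""
    counts = rng.poisson(np.outer(depths, rates))
    disp = 2 * rng.binomial(counts, 0.5) - counts
    return np.maximum(start + disp, 1)


def _build_samples(config, rng, alleles, hg_names, pop_idx, depths, prefix="S"):
    slots = _allele_slots(config.panel)
    n = alleles.shape[0]

    micro_mask = rng.random(n) < config.microvariant_rate
    micro_locus = [
        _MICROVARIANT_PRONE[int(rng.integers(len(_MICROVARIANT_PRONE)))] for _ in range(n)
    ]
    artifact_ids = rng.choice(n, size=config.biallelic_artifact_count, replace=False)
    single = [l.name for l in config.panel if l.copy_number == 1]
    artifact_locus = {
        int(i): single[int(rng.integers(len(single)))] for i in artifact_ids
    }

    samples, truth_rows = [], []
    for i in range(n):
        name, region, lat, lon, _ = config.populations[pop_idx[i]]
        calls: dict[str, list[AlleleCall]] = {}
        for (locus, _copy), value in zip(slots, alleles[i]):
            partial = 2 if (micro_mask[i] and locus == micro_locus[i] and not calls.get(locus)) else 0
            calls.setdefault(locus, []).append(AlleleCall(int(value), partial))
        if i in artifact_locus:
            loc = artifact_locus[i]
            extra = calls[loc][0]
            calls[loc].append(AlleleCall(extra.repeats + 1, extra.partial))
        sid = f"{prefix}{i + 1:04d}"
        samples.append(
            SampleRecord(
                sample_id=sid,
                population=name,
                region=region,
                lat=lat,
                lon=lon,
                calls={loc: tuple(sorted(a)) for loc, a in calls.items()},
            ).canonicalized()
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "haplogroup": hg_names[i],
                "depth": float(depths[i]),
                "population": name,
                "region": region,
                "is_microvariant": bool(micro_mask[i]),
                "is_biallelic_artifact": i in artifact_locus,
            }
        )
    return Cohort(config.panel, tuple(samples)), pd.DataFrame(truth_rows)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a cohort under the star-genealogy SMM; returns (cohort, truth)."""
    rng = np.random.default_rng(config.seed)
    slots = _allele_slots(config.panel)
    rates = np.array([_locus_rate(config, config.panel[_slot_locus_index(config.panel, s)]) for s in range(len(slots))])

    hgs = sorted(config.haplogroup_mix)
    probs = np.array([config.haplogroup_mix[h] for h in hgs])
    founders = founder_haplotypes(hgs, config.panel)

    n = config.n_samples
    hg_idx = rng.choice(len(hgs), size=n, p=probs)
    hg_names = [hgs[i] for i in hg_idx]
    depths = rng.exponential(config.genealogy_depth_mean, size=n)
    start = np.vstack([founders[h] for h in hg_names])
    alleles = _mutate(rng, start, depths, rates)

    weights = np.array([p[4] for p in config.populations], dtype=float)
    pop_idx = rng.choice(len(config.populations), size=n, p=weights / weights.sum())
    return _build_samples(config, rng, alleles, hg_names, pop_idx, depths)


def _slot_locus_index(panel, slot: int) -> int:
    i = 0
    for li, l in enumerate(panel):
        for _ in range(l.copy_number):
            if i == slot:
                return li
            i += 1
    raise IndexError(slot)


def simulate_two_pop_divergence(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Two populations from one founder, diverged for ``divergence_generations``.

    Each population first drifts independently from the common founder for
    the divergence time (a shared population branch), then individuals
    branch off with exponential(mean) private depths. Expected Phi_ST grows
    with divergence time; at 0 the populations are exchangeable.
    """
    if len(config.populations) < 2:
        raise ValueError("two-population mode needs at least 2 configured populations")
    config2 = replace(config, populations=config.populations[:2])
    rng = np.random.default_rng(config.seed)
    slots = _allele_slots(config.panel)
    rates = np.array(
        [_locus_rate(config, config.panel[_slot_locus_index(config.panel, s)]) for s in range(len(slots))]
    )
    hg = sorted(config.haplogroup_mix)[0]
    founder = founder_haplotypes([hg], config.panel)[hg]

    n = config.n_samples
    half = n // 2
    pop_idx = np.array([0] * half + [1] * (n - half))
    # shared population branches
    pop_founders = _mutate(
        rng, np.vstack([founder, founder]), np.full(2, float(config.divergence_generations)), rates
    )
    depths = rng.exponential(config.genealogy_depth_mean, size=n)
    start = pop_founders[pop_idx]
    alleles = _mutate(rng, start, depths, rates)
    return _build_samples(config2, rng, alleles, [hg] * n, pop_idx, depths)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def truth_labels(truth: pd.DataFrame) -> dict[str, str]:
    """sample_id -> haplogroup map from a truth table."""
    return dict(zip(truth["sample_id"], truth["haplogroup"]))
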