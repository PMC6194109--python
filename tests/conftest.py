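"""Shared fixtures: tiny hand-built cohorts and simulated ones."""

from __future__ import annotations

import pytest

from ystrkit.cohort import AlleleCall, Cohort, SampleRecord
from ystrkit.panel import PPY23, LocusDef
from ystrkit.simulate import SimConfig, simulate_cohort


def make_panel(n_loci: int = 3, prefix: str = "L") -> tuple[LocusDef, ...]:
    return tuple(LocusDef(f"{prefix}{i}") for i in range(n_loci))


def make_sample(
    sample_id: str,
    alleles,
    population: str = "P1",
    region: str = "North",
    lat: float = 20.0,
    lon: float = 78.0,
    panel=None,
) -> SampleRecord:
    """Sample from a list of per-locus allele specs (int, float-string, or tuple)."""
    panel = panel if panel is not None else make_panel(len(alleles))
    calls = {}
    for locus, spec in zip(panel, alleles):
        if isinstance(spec, (list, tuple)):
            parsed = tuple(sorted(_coerce(a) for a in spec))
        else:
            parsed = (_coerce(spec),)
        calls[locus.name] = parsed
    return SampleRecord(sample_id, population, region, lat, lon, calls)


def _coerce(a) -> AlleleCall:
    if isinstance(a, AlleleCall):
        return a
    if isinstance(a, int):
        return AlleleCall(a)
    return AlleleCall.parse(str(a))


def make_cohort(rows, panel=None, populations=None) -> Cohort:
    """Cohort from a list of allele-spec lists; optional per-row populations."""
    n_loci = len(rows[0])
    panel = panel if panel is not None else make_panel(n_loci)
    pops = populations if populations is not None else ["P1"] * len(rows)
    samples = tuple(
        make_sample(f"s{i:03d}", row, population=pop, panel=panel)
        for i, (row, pop) in enumerate(zip(rows, pops))
    )
    return Cohort(panel, samples)


@pytest.fixture(scope="session")
def sim_cohort_small():
    """80-sample simulated cohort with 2 engineered biallelic artifacts."""
    cfg = SimConfig(seed=11, n_samples=80, biallelic_artifact_count=2)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def ppy23_panel():
    return PPY23
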