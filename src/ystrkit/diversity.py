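"""Allele/haplotype frequency spectra and forensic summary statistics.

Four statistics, all computed from counting-method frequency spectra:

* genetic diversity (per locus)  GD = n/(n-1) * (1 - sum_i p_i^2)
* haplotype diversity            HD = n/(n-1) * (1 - sum_i h_i^2)
* discrimination capacity        DC = n_distinct / n
* combined match probability     CMP = sum_i h_i^2

with p_i the allele and h_i the haplotype frequency. GD/HD are the
unbiased heterozygosity analogue for haploid data; HD and CMP satisfy
HD = n/(n-1) * (1 - CMP) identically when computed on the same spectrum.

Forensic statistics use the full-panel haplotype (DYS385a/b canonical
pair included, microvariants included); only repeat-difference distance
analyses use the reduced panel. Values are kept at full precision;
rounding belongs to the presentation layer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable

import numpy as np
import pandas as pd

from .cohort import Cohort, SampleRecord
from .panel import MULTI_COPY_LOCUS


@dataclass(frozen=True)
class FrequencySpectrum:
    """Counts of distinct alleles or haplotypes; ``n`` is the total."""

    labels: tuple[Hashable, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValueError("labels and counts differ in length")
        if any(c <= 0 for c in self.counts):
            raise ValueError("counts must be positive")

    @classmethod
    def from_observations(cls, observations) -> "FrequencySpectrum":
        counter = Counter(observations)
        if not counter:
            raise ValueError("empty observation list")
        labels, counts = zip(*sorted(counter.items(), key=lambda kv: str(kv[0])))
        return cls(labels, counts)

    @classmethod
    def from_multiplicities(cls, multiplicity_counts: dict[int, int]) -> "FrequencySpectrum":
        """Build a spectrum from a multiplicity structure.

        ``{1: 392, 2: 4, 3: 1}`` means 392 singletons, 4 doubletons and one
        tripleton; anonymous labels are generated.
        """
        labels: list[str] = []
        counts: list[int] = []
        i = 0
        for mult, how_many in sorted(multiplicity_counts.items()):
            for _ in range(how_many):
                labels.append(f"h{i:05d}")
                counts.append(mult)
                i += 1
        return cls(tuple(labels), tuple(counts))

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n

    def sum_squared_frequencies(self) -> float:
        # exact rational arithmetic via integer counts, divided once
        return sum(c * c for c in self.counts) / (self.n * self.n)


@dataclass(frozen=True)
class ForensicSummary:
    """HD, DC and CMP of a haplotype spectrum, with the counts behind them."""

    hd: float
    dc: float
    cmp: float
    n: int
    n_distinct: int

    def to_dict(self) -> dict:
        return {
            "haplotype_diversity": self.hd,
            "discrimination_capacity": self.dc,
            "combined_match_probability": self.cmp,
            "n_samples": self.n,
            "n_distinct_haplotypes": self.n_distinct,
        }


def haplotype_key(sample: SampleRecord, locus_names: list[str]) -> str:
    """Canonical haplotype string over the given loci (alleles sorted within a locus)."""
    parts = []
    for name in locus_names:
        alleles = sorted(sample.calls[name])
        parts.append(",".join(str(a) for a in alleles))
    return "|".join(parts)


def allele_spectrum(cohort: Cohort, locus: str) -> FrequencySpectrum:
    """Spectrum of allele counts at one locus; DYS385a/b contributes both pair members."""
    cohort.locus(locus)  # raises KeyError on unknown locus
    if not cohort.samples:
        raise ValueError("empty cohort")
    obs = [a for s in cohort.samples for a in s.calls[locus]]
    return FrequencySpectrum.from_observations(obs)


def haplotype_spectrum(cohort: Cohort) -> FrequencySpectrum:
    """Spectrum of full-panel haplotype multiplicities."""
    if not cohort.samples:
        raise ValueError("empty cohort")
    names = cohort.locus_names
    return FrequencySpectrum.from_observations(haplotype_key(s, names) for s in cohort.samples)


def locus_gd(spectrum: FrequencySpectrum) -> float:
    """Unbiased genetic diversity n/(n-1)*(1 - sum p_i^2). Requires n >= 2."""
    n = spectrum.n
    if n < 2:
        raise ValueError("genetic diversity needs n >= 2")
    return n / (n - 1) * (1.0 - spectrum.sum_squared_frequencies())


def haplotype_diversity(spectrum: FrequencySpectrum) -> float:
    """Same estimator as :func:`locus_gd`, applied to haplotype frequencies."""
    return locus_gd(spectrum)


def discrimination_capacity(spectrum: FrequencySpectrum) -> float:
    """Distinct haplotypes divided by total samples."""
    return spectrum.n_distinct / spectrum.n


def combined_match_probability(spectrum: FrequencySpectrum) -> float:
    """Sum of squared haplotype frequencies; bounded below by 1/n."""
    return spectrum.sum_squared_frequencies()


def forensic_summary(cohort: Cohort) -> ForensicSummary:
    spec = haplotype_spectrum(cohort)
    return ForensicSummary(
        hd=haplotype_diversity(spec),
        dc=discrimination_capacity(spec),
        cmp=combined_match_probability(spec),
        n=spec.n,
        n_distinct=spec.n_distinct,
    )


def locus_gd_table(cohort: Cohort) -> pd.Series:
    """Per-locus GD over the whole cohort."""
    return pd.Series(
        {name: locus_gd(allele_spectrum(cohort, name)) for name in cohort.locus_names},
        name="GD",
    )


def per_population_gd_table(cohort: Cohort) -> tuple[pd.DataFrame, list[str]]:
    """Population x locus GD table.

    Populations with fewer than 2 samples cannot support the unbiased
    estimator; their row is NaN and the population name is returned in the
    flagged list rather than silently dropped.
    """
    names = cohort.locus_names
    rows: dict[str, dict[str, float]] = {}
    flagged: list[str] = []
    for pop, members in cohort.by_population().items():
        sub = Cohort(cohort.panel, tuple(members))
        if len(members) < 2:
            flagged.append(pop)
            rows[pop] = {n: float("nan") for n in names}
            continue
        rows[pop] = {n: locus_gd(allele_spectrum(sub, n)) for n in names}
    return pd.DataFrame.from_dict(rows, orient="index")[names], flagged
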