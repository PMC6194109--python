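"""Haplotype data model and QC/reduction filters.

A :class:`Cohort` is the central container: a panel of loci plus one
:class:`SampleRecord` per genotyped male. Alleles are exact
integer-plus-partial repeat counts (:class:`AlleleCall`) — never floats —
so that haplotype identity, collapsing and round-trip serialization are
exact.

Two filters mirror the standard analysis workflow:

* :func:`qc_filter_biallelic` drops samples showing more than one allele
  at any single-copy locus (multi-peak artifacts, e.g. from trace
  contamination or somatic duplication);
* :func:`reduce_for_rst` prepares a cohort for repeat-difference
  distances (R_ST, networks) by dropping the duplicated DYS385a/b locus
  and removing samples that carry microvariant (partial-repeat) alleles
  at the retained loci.
"""

from __future__ import annotations

import functools
import re
import warnings
from dataclasses import dataclass, field, replace

from .panel import MULTI_COPY_LOCUS, LocusDef, validate_panel

_ALLELE_RE = re.compile(r"^(\d+)(?:\.(\d))?$")


@functools.total_ordering
@dataclass(frozen=True)
class AlleleCall:
    """A repeat-count allele, possibly a microvariant.

    ``"13.2"`` parses to ``AlleleCall(repeats=13, partial=2)`` — 13 full
    repeat units plus a 2-base partial repeat. ``partial`` is 0 for full
    repeats and must be smaller than a repeat-unit length (5 bases).
    """

    repeats: int
    partial: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 0:
            raise ValueError("repeats must be non-negative")
        if not (0 <= self.partial <= 4):
            raise ValueError("partial repeat must be in 0..4")

    @classmethod
    def parse(cls, text: str) -> "AlleleCall":
        m = _ALLELE_RE.match(text.strip())
        if not m:
            raise ValueError(f"unparseable allele {text!r}")
        return cls(int(m.group(1)), int(m.group(2)) if m.group(2) else 0)

    def __str__(self) -> str:
        return f"{self.repeats}.{self.partial}" if self.partial else str(self.repeats)

    def __lt__(self, other: "AlleleCall") -> bool:
        return (self.repeats, self.partial) < (other.repeats, other.partial)

    @property
    def is_microvariant(self) -> bool:
        return self.partial != 0

    @property
    def value(self) -> float:
        """Numeric value (repeats + partial/10) for presentation/distance use."""
        return self.repeats + self.partial / 10.0


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped male: haplotype plus population/region labels and coordinates.

    ``calls`` maps locus name to a tuple of alleles: length 1 for a clean
    single-copy locus (>1 marks a biallelic artifact), and a canonically
    ascending pair for DYS385a/b.
    """

    sample_id: str
    population: str
    region: str
    lat: float
    lon: float
    calls: dict[str, tuple[AlleleCall, ...]]

    def canonicalized(self) -> "SampleRecord":
        """Return a copy with every locus's alleles sorted ascending."""
        return replace(
            self, calls={loc: tuple(sorted(a)) for loc, a in self.calls.items()}
        )

    def has_microvariant(self, loci: list[str] | None = None) -> bool:
        loci = loci if loci is not None else list(self.calls)
        return any(a.is_microvariant for loc in loci for a in self.calls.get(loc, ()))


@dataclass(frozen=True)
class Cohort:
    """A panel plus a list of samples, each typed on that panel."""

    panel: tuple[LocusDef, ...]
    samples: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "panel", validate_panel(self.panel))
        object.__setattr__(self, "samples", tuple(self.samples))
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in cohort")
        names = {l.name for l in self.panel}
        for s in self.samples:
            extra = set(s.calls) - names
            if extra:
                raise ValueError(f"sample {s.sample_id} has loci outside panel: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.panel]

    def locus(self, name: str) -> LocusDef:
        for l in self.panel:
            if l.name == name:
                return l
        raise KeyError(f"unknown locus {name!r}")

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    def subset(self, sample_ids) -> "Cohort":
        wanted = set(sample_ids)
        missing = wanted - {s.sample_id for s in self.samples}
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return Cohort(self.panel, tuple(s for s in self.samples if s.sample_id in wanted))

    def by_population(self) -> dict[str, list[SampleRecord]]:
        out: dict[str, list[SampleRecord]] = {}
        for s in self.samples:
            out.setdefault(s.population, []).append(s)
        return out


def qc_filter_biallelic(cohort: Cohort) -> tuple[Cohort, list[str]]:
    """Remove samples with more than one allele at any single-copy locus.

    DYS385a/b (copy number 2) never triggers removal. Returns the filtered
    cohort and the discarded sample ids, so ``len(kept) + len(discarded)``
    always equals the input size. Idempotent.
    """
    single = {l.name for l in cohort.panel if l.copy_number == 1}
    kept, discarded = [], []
    for s in cohort.samples:
        if any(len(a) > 1 for loc, a in s.calls.items() if loc in single):
            discarded.append(s.sample_id)
        else:
            kept.append(s)
    return Cohort(cohort.panel, tuple(kept)), discarded


def reduce_for_rst(cohort: Cohort) -> Cohort:
    """Reduce a QC-filtered cohort for repeat-difference distance analyses.

    Drops the DYS385a/b column, then removes every sample carrying a
    microvariant allele at any retained locus (partial repeats have no
    well-defined integer repeat difference). Warns if nothing survives.
    """
    panel = tuple(l for l in cohort.panel if l.name != MULTI_COPY_LOCUS)
    names = [l.name for l in panel]
    kept = []
    for s in cohort.samples:
        if s.has_microvariant(names):
            continue
        calls = {loc: a for loc, a in s.calls.items() if loc != MULTI_COPY_LOCUS}
        kept.append(replace(s, calls=calls))
    if cohort.samples and not kept:
        warnings.warn("reduce_for_rst: all samples carried microvariants; cohort is empty")
    return Cohort(panel, tuple(kept))
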