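"""Locus definitions for Y-STR panels.

The default panel is the 23-marker PowerPlex Y23 set: 21 single-copy loci
plus the duplicated DYS385a/b locus, which is genotyped as an unordered
pair of alleles. Mutation rates are per-locus, per-generation values used
only by the forward simulator; two loci (DYS570, DYS576) are the panel's
rapidly mutating markers and carry a ~5x higher default rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LocusDef:
    """One STR locus in a panel.

    Parameters
    ----------
    name:
        Locus name, unique within a panel (e.g. ``"DYS19"``).
    copy_number:
        1 for ordinary loci, 2 for the duplicated DYS385a/b.
    mutation_rate:
        Per-generation single-step mutation probability; consumed only by
        the simulator.
    """

    name: str
    copy_number: int = 1
    mutation_rate: float = 2e-3

    def __post_init__(self) -> None:
        if self.copy_number not in (1, 2):
            raise ValueError(f"copy_number must be 1 or 2, got {self.copy_number}")
        if not (0.0 <= self.mutation_rate < 0.05):
            raise ValueError(f"mutation_rate out of range for {self.name}: {self.mutation_rate}")


# Typical modal repeat counts, used by the simulator to seed founders.
_PPY23_SPEC: list[tuple[str, int, float, int]] = [
    # (name, copy_number, mutation_rate, typical modal allele)
    ("DYS19", 1, 2e-3, 15),
    ("DYS385a/b", 2, 2e-3, 13),
    ("DYS389I", 1, 2e-3, 13),
    ("DYS389II", 1, 2e-3, 30),
    ("DYS390", 1, 2e-3, 23),
    ("DYS391", 1, 2e-3, 10),
    ("DYS392", 1, 2e-3, 11),
    ("DYS393", 1, 2e-3, 12),
    ("DYS437", 1, 2e-3, 15),
    ("DYS438", 1, 2e-3, 10),
    ("DYS439", 1, 2e-3, 11),
    ("DYS448", 1, 2e-3, 19),
    ("DYS456", 1, 2e-3, 15),
    ("DYS458", 1, 2e-3, 16),
    ("DYS481", 1, 2e-3, 24),
    ("DYS533", 1, 2e-3, 11),
    ("DYS549", 1, 2e-3, 12),
    ("DYS570", 1, 1e-2, 18),
    ("DYS576", 1, 1e-2, 18),
    ("DYS635", 1, 2e-3, 22),
    ("DYS643", 1, 2e-3, 10),
    ("YGATAH4", 1, 2e-3, 12),
]

#: The 23-marker PowerPlex Y23 panel (22 loci; DYS385a/b counts as two markers).
PPY23: tuple[LocusDef, ...] = tuple(
    LocusDef(name, copy_number, rate) for name, copy_number, rate, _ in _PPY23_SPEC
)

#: Modal repeat counts used as the base haplotype when generating founders.
PPY23_MODAL_ALLELES: dict[str, int] = {name: modal for name, _, _, modal in _PPY23_SPEC}

MULTI_COPY_LOCUS = "DYS385a/b"


def validate_panel(panel: tuple[LocusDef, ...] | list[LocusDef]) -> tuple[LocusDef, ...]:
    """Check name uniqueness and return the panel as a tuple."""
    panel = tuple(panel)
    names = [l.name for l in panel]
    if len(set(names)) != len(names):
        raise ValueError("duplicate locus names in panel")
    return panel


def single_copy_loci(panel: tuple[LocusDef, ...]) -> list[LocusDef]:
    return [l for l in panel if l.copy_number == 1]
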