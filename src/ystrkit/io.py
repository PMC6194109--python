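"""CSV reading and writing of Y-STR haplotype tables.

One unambiguous dialect: comma-separated, UTF-8, header required. Fixed
leading columns ``SampleID, Population, Region, Lat, Lon`` followed by one
column per locus. Multi-allele cells (the DYS385a/b pair, or a biallelic
artifact at a single-copy locus) are comma-joined inside the cell and
therefore quoted by the csv layer, e.g. ``"11,14"``. Microvariants use
dotted notation (``13.2``). Blank cells are parse errors — complete
profiles are assumed.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

from .cohort import AlleleCall, Cohort, SampleRecord
from .panel import LocusDef, validate_panel

_META_COLS = ["SampleID", "Population", "Region", "Lat", "Lon"]


class CohortFormatError(ValueError):
    """Structural problem with a haplotype table (header, columns, emptiness)."""


class AlleleParseError(ValueError):
    """A cell failed to parse; message names the sample, locus and line."""


def _parse_cell(text: str, sample_id: str, locus: str, line_no: int) -> tuple[AlleleCall, ...]:
    text = text.strip()
    if not text:
        raise AlleleParseError(
            f"line {line_no}: blank call for sample {sample_id!r} at locus {locus!r}"
        )
    try:
        alleles = tuple(AlleleCall.parse(part) for part in text.split(","))
    except ValueError as exc:
        raise AlleleParseError(
            f"line {line_no}: sample {sample_id!r}, locus {locus!r}: {exc}"
        ) from None
    return tuple(sorted(alleles))


def read_cohort(path: str | Path, panel: tuple[LocusDef, ...] | list[LocusDef]) -> Cohort:
    """Read a haplotype CSV against a panel spec.

    Every panel locus must appear as a column; allele strings are parsed to
    exact :class:`AlleleCall` values and multi-allele cells are stored
    canonically sorted. Errors carry 1-based line numbers.
    """
    panel = validate_panel(panel)
    with open(path, newline="", encoding="utf-8") as fh:
        return _read(fh, panel, str(path))


def read_cohort_string(text: str, panel) -> Cohort:
    """Like :func:`read_cohort` but from an in-memory string."""
    return _read(_io.StringIO(text), validate_panel(panel), "<string>")


def _read(fh, panel: tuple[LocusDef, ...], source: str) -> Cohort:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise CohortFormatError(f"{source}: empty file") from None
    missing = [c for c in _META_COLS if c not in header]
    if missing:
        raise CohortFormatError(f"{source}: missing metadata columns {missing}")
    locus_names = [l.name for l in panel]
    absent = [n for n in locus_names if n not in header]
    if absent:
        raise CohortFormatError(f"{source}: missing locus columns {absent}")
    idx = {name: header.index(name) for name in _META_COLS + locus_names}

    samples = []
    for line_no, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise CohortFormatError(
                f"{source}: line {line_no}: expected {len(header)} fields, got {len(row)}"
            )
        sid = row[idx["SampleID"]].strip()
        try:
            lat = float(row[idx["Lat"]])
            lon = float(row[idx["Lon"]])
        except ValueError:
            raise CohortFormatError(f"{source}: line {line_no}: bad coordinates") from None
        calls = {
            name: _parse_cell(row[idx[name]], sid, name, line_no) for name in locus_names
        }
        samples.append(
            SampleRecord(
                sample_id=sid,
                population=row[idx["Population"]].strip(),
                region=row[idx["Region"]].strip(),
                lat=lat,
                lon=lon,
                calls=calls,
            )
        )
    if not samples:
        raise CohortFormatError(f"{source}: no sample rows")
    return Cohort(panel, tuple(samples))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the dialect :func:`read_cohort` reads (round-trip exact)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        _write(cohort, fh)


def write_cohort_string(cohort: Cohort) -> str:
    buf = _io.StringIO()
    _write(cohort, buf)
    return buf.getvalue()


def _write(cohort: Cohort, fh) -> None:
    names = cohort.locus_names
    writer = csv.writer(fh)
    writer.writerow(_META_COLS + names)
    for s in cohort.samples:
        s = s.canonicalized()
        row = [s.sample_id, s.population, s.region, repr(s.lat), repr(s.lon)]
        row += [",".join(str(a) for a in s.calls[n]) for n in names]
        writer.writerow(row)
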