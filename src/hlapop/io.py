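"""Delimited-text I/O for genotype cohorts, frequency tables and metadata.

Formats
-------
Genotype table
    Header ``subject_id[,family_id,role]`` followed by two columns per locus
    named ``<locus>_1`` and ``<locus>_2`` (the composite locus appears as
    ``DRB3/4/5_1`` / ``DRB3/4/5_2``).  The allele pair within a subject is
    unordered and is canonicalized on read.
Frequency table
    Columns ``haplotype`` (allele names joined by ``~``), ``frequency`` and
    optionally ``count``.  Frequencies are written with four decimals.

Files are UTF-8; comma- or tab-delimited, autodetected from the header line.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

from .nomenclature import (
    Allele,
    Haplotype,
    format_allele,
    format_haplotype,
    parse_allele,
    parse_haplotype,
)
from .tables import HaplotypeTable


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass
class GenotypeRecord:
    """Unordered diploid allele calls per locus for one subject."""

    subject_id: str
    genotypes: dict[str, tuple[Allele, Allele]]
    family_id: str | None = None
    role: str = "unrelated"  # parent | child | unrelated
    missing_loci: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        # pair order is non-semantic: canonicalize by formatted name
        self.genotypes = {
            locus: tuple(sorted(pair, key=format_allele))
            for locus, pair in self.genotypes.items()
        }

    def pair(self, locus: str) -> tuple[Allele, Allele]:
        return self.genotypes[locus]

    def is_heterozygous(self, locus: str, resolution: int | None = 2) -> bool:
        from .nomenclature import allele_key

        a, b = self.genotypes[locus]
        return allele_key(a, resolution) != allele_key(b, resolution)


@dataclass
class Cohort:
    """A collection of genotype records sharing a locus list."""

    loci: tuple[str, ...]
    records: list[GenotypeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def unrelated(self) -> "Cohort":
        return Cohort(self.loci, [r for r in self.records if r.role == "unrelated"])

    def families(self) -> dict[str, list[GenotypeRecord]]:
        fams: dict[str, list[GenotypeRecord]] = {}
        for r in self.records:
            if r.family_id:
                fams.setdefault(r.family_id, []).append(r)
        return fams

    def complete(self, loci=None) -> "Cohort":
        """Subjects typed at every requested locus."""
        loci = tuple(loci) if loci is not None else self.loci
        keep = [r for r in self.records if not any(l in r.missing_loci for l in loci)]
        return Cohort(self.loci, keep)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _open_rows(path) -> tuple[list[str], list[dict[str, str]]]:
    text = Path(path).read_text(encoding="utf-8")
    first = text.splitlines()[0] if text else ""
    delim = _sniff_delimiter(first)
    reader = csv.DictReader(_io.StringIO(text), delimiter=delim)
    if reader.fieldnames is None:
        raise FormatError(f"{path}: empty file")
    return list(reader.fieldnames), list(reader)


def read_cohort(path, loci) -> Cohort:
    """Read a genotype table; see module docstring for the layout.

    Subjects with a blank call at some locus are kept and flagged via
    ``missing_loci`` rather than silently dropped.
    """
    loci = tuple(loci)
    header, rows = _open_rows(path)
    if "subject_id" not in header:
        raise FormatError(f"{path}: missing required column 'subject_id'")
    for locus in loci:
        for col in (f"{locus}_1", f"{locus}_2"):
            if col not in header:
                raise FormatError(f"{path}: missing genotype column for locus {locus} ({col})")
    records: list[GenotypeRecord] = []
    seen: set[str] = set()
    for row in rows:
        sid = (row.get("subject_id") or "").strip()
        if not sid:
            raise FormatError(f"{path}: row with empty subject_id")
        if sid in seen:
            raise FormatError(f"{path}: duplicate subject_id {sid!r}")
        seen.add(sid)
        genotypes: dict[str, tuple[Allele, Allele]] = {}
        missing: list[str] = []
        for locus in loci:
            raw1 = (row.get(f"{locus}_1") or "").strip()
            raw2 = (row.get(f"{locus}_2") or "").strip()
            if not raw1 or not raw2:
                missing.append(locus)
                continue
            genotypes[locus] = (
                parse_allele(raw1, locus=locus),
                parse_allele(raw2, locus=locus),
            )
        records.append(
            GenotypeRecord(
                subject_id=sid,
                genotypes=genotypes,
                family_id=(row.get("family_id") or "").strip() or None,
                role=(row.get("role") or "").strip() or "unrelated",
                missing_loci=tuple(missing),
            )
        )
    return Cohort(loci, records)


def write_cohort(path, cohort: Cohort, delimiter: str = ",") -> None:
    loci = cohort.loci
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        header = ["subject_id", "family_id", "role"]
        for locus in loci:
            header += [f"{locus}_1", f"{locus}_2"]
        writer.writerow(header)
        for r in cohort.records:
            row = [r.subject_id, r.family_id or "", r.role]
            for locus in loci:
                if locus in r.genotypes:
                    a, b = r.genotypes[locus]
                    row += [format_allele(a), format_allele(b)]
                else:
                    row += ["", ""]
            writer.writerow(row)


def read_frequency_table(path, loci) -> HaplotypeTable:
    """Read a ``haplotype,frequency[,count]`` table."""
    loci = tuple(loci)
    header, rows = _open_rows(path)
    for col in ("haplotype", "frequency"):
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    freqs: dict[Haplotype, float] = {}
    counts: dict[Haplotype, int] = {}
    have_counts = "count" in header
    total = None
    for row in rows:
        h = parse_haplotype(row["haplotype"], loci)
        freqs[h] = freqs.get(h, 0.0) + float(row["frequency"])
        if have_counts and (row.get("count") or "").strip():
            counts[h] = counts.get(h, 0) + int(row["count"])
    if have_counts and counts:
        total_mass = sum(freqs.values())
        total_count = sum(counts.values())
        if total_mass > 0:
            total = round(total_count / total_mass)
    return HaplotypeTable(loci, freqs, counts or None, total)


def write_frequency_table(
    path, table: HaplotypeTable, delimiter: str = ",", header_comment: str | None = None
) -> None:
    """Write ``haplotype,frequency[,count]`` with 4-decimal frequencies."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, delimiter=delimiter)
        cols = ["haplotype", "frequency"] + (["count"] if table.counts is not None else [])
        writer.writerow(cols)
        for h, f in table.sorted_entries():
            row = [format_haplotype(h), f"{f:.4f}"]
            if table.counts is not None:
                row.append(str(table.counts.get(h, "")))
            writer.writerow(row)


def read_metadata(path):
    """Read a population metadata table into a pandas DataFrame."""
    import pandas as pd

    first = Path(path).read_text(encoding="utf-8").splitlines()[0]
    return pd.read_csv(path, sep=_sniff_delimiter(first), comment="#")
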