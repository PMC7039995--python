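"""HLA allele and haplotype nomenclature.

Alleles follow the colon-delimited field convention (``A*31:01:02:01``),
optionally carrying an expression/annotation suffix (``A*24:02:01:02L``,
``DRB4*01:03:02e1``).  The DRB3, DRB4 and DRB5 genes are modeled as a single
composite locus ``DRB3/4/5`` whose alleles keep their own gene prefix; the
structural absence of all three genes on a chromosome is an allele-like state
written ``NULL``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

#: Canonical locus names, in genomic-report order.
LOCI = (
    "A",
    "B",
    "C",
    "DRB1",
    "DRB3/4/5",
    "DQA1",
    "DQB1",
    "DPA1",
    "DPB1",
)

#: Gene prefixes folded into the composite DRB3/4/5 locus.
_DRB_COMPOSITE_GENES = ("DRB3", "DRB4", "DRB5")

_GENE_TO_LOCUS = {g: "DRB3/4/5" for g in _DRB_COMPOSITE_GENES}
_GENE_TO_LOCUS.update({l: l for l in LOCI if l != "DRB3/4/5"})

_FIELD_RE = re.compile(r"^(\d+)([A-Za-z][A-Za-z0-9]*)?$")


class AlleleParseError(ValueError):
    """Raised when an allele string cannot be interpreted."""


@dataclass(frozen=True, order=True)
class Allele:
    """One HLA allele call.

    ``locus`` is the canonical analysis locus (DRB3/4/5 composite); ``gene``
    is the literal prefix as printed (e.g. ``DRB4``).  ``fields`` holds 1-4
    numeric tokens with leading zeros preserved.  ``is_absent`` marks the
    structural absence of a DRB3/4/5 gene (printed ``NULL``).
    """

    locus: str
    fields: tuple[str, ...] = ()
    suffix: str | None = None
    is_absent: bool = False
    gene: str | None = None

    def __post_init__(self) -> None:
        if not self.is_absent and not self.fields:
            raise AlleleParseError("allele requires at least one field unless absent")
        if self.gene is None:
            object.__setattr__(self, "gene", self.locus)

    def __str__(self) -> str:  # noqa: D105
        return format_allele(self)

    @property
    def name(self) -> str:
        """Formatted allele name (round-trips through :func:`parse_allele`)."""
        return format_allele(self)


def parse_allele(text: str, locus: str | None = None) -> Allele:
    """Parse an allele name such as ``A*31:01:02:01``.

    ``locus`` supplies context, required only for the bare ``NULL`` token
    (absence of a DRB3/4/5 gene).  A trailing expression suffix may be
    separated from the last field by an optional space.
    """
    if not isinstance(text, str) or not text.strip():
        raise AlleleParseError("empty allele string")
    text = text.strip()
    if text.upper() == "NULL":
        ctx = locus or "DRB3/4/5"
        if ctx != "DRB3/4/5":
            raise AlleleParseError(f"NULL is only meaningful at DRB3/4/5, not {ctx!r}")
        return Allele(locus="DRB3/4/5", is_absent=True, gene="DRB3/4/5")
    if "*" not in text:
        raise AlleleParseError(f"missing '*' separator in allele name {text!r}")
    gene, _, rest = text.partition("*")
    gene = gene.strip()
    if gene not in _GENE_TO_LOCUS:
        raise AlleleParseError(f"unknown locus prefix {gene!r} in {text!r}")
    canonical = _GENE_TO_LOCUS[gene]
    if locus is not None and canonical != locus:
        raise AlleleParseError(
            f"allele {text!r} belongs to locus {canonical}, expected {locus}"
        )
    rest = rest.strip()
    if not rest:
        raise AlleleParseError(f"no fields in allele name {text!r}")
    # a space may separate an expression suffix from the fields: "A*24:02:01:02 L"
    suffix = None
    if " " in rest:
        rest, _, tail = rest.partition(" ")
        suffix = tail.strip() or None
    tokens = rest.split(":")
    fields: list[str] = []
    for i, tok in enumerate(tokens):
        m = _FIELD_RE.match(tok)
        if m is None:
            raise AlleleParseError(f"malformed field {tok!r} in allele name {text!r}")
        fields.append(m.group(1))
        if m.group(2) is not None:
            if i != len(tokens) - 1:
                raise AlleleParseError(
                    f"suffix {m.group(2)!r} not on last field of {text!r}"
                )
            if suffix is not None:
                raise AlleleParseError(f"duplicate suffix in {text!r}")
            suffix = m.group(2)
    if not 1 <= len(fields) <= 4:
        raise AlleleParseError(f"expected 1-4 fields, got {len(fields)} in {text!r}")
    return Allele(
        locus=canonical, fields=tuple(fields), suffix=suffix, gene=gene
    )


def format_allele(a: Allele) -> str:
    """Format an allele; inverse of :func:`parse_allele`."""
    if a.is_absent:
        return "NULL"
    body = f"{a.gene}*{':'.join(a.fields)}"
    return body + (a.suffix or "")


def truncate(a: Allele, n_fields: int) -> Allele:
    """Truncate an allele to at most ``n_fields`` fields.

    The expression suffix is dropped whenever truncation removes the field it
    annotates; the absent state passes through unchanged.
    """
    if n_fields < 1:
        raise ValueError(f"field count must be >= 1, got {n_fields}")
    if a.is_absent or len(a.fields) <= n_fields:
        return a
    return replace(a, fields=a.fields[:n_fields], suffix=None)


def allele_key(a: Allele, resolution: int | None = 2) -> str:
    """Identity string at a given resolution.

    At the default two-field resolution, expression-variant suffixes are
    ignored so sub-alleles aggregate onto their two-field parent.  Pass
    ``resolution=None`` for full-resolution identity including the suffix.
    """
    if a.is_absent:
        return "NULL"
    if resolution is None:
        return format_allele(a)
    t = truncate(a, resolution)
    return f"{t.gene}*{':'.join(t.fields)}"


@dataclass(frozen=True, order=True)
class Haplotype:
    """An ordered tuple of alleles, one per locus of ``loci``."""

    loci: tuple[str, ...]
    alleles: tuple[Allele, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.alleles):
            raise ValueError(
                f"{len(self.loci)} loci but {len(self.alleles)} alleles"
            )
        for locus, a in zip(self.loci, self.alleles):
            if a.locus != locus:
                raise ValueError(f"allele {a} is not at locus {locus}")

    def __str__(self) -> str:  # noqa: D105
        return format_haplotype(self)

    def key(self, resolution: int | None = 2) -> tuple[str, ...]:
        """Field-wise identity tuple at the stated resolution."""
        return tuple(allele_key(a, resolution) for a in self.alleles)

    def subset(self, loci: tuple[str, ...] | list[str]) -> "Haplotype":
        """Project onto a subset of loci (order as given)."""
        index = {l: i for i, l in enumerate(self.loci)}
        missing = [l for l in loci if l not in index]
        if missing:
            raise ValueError(f"loci not in haplotype: {missing}")
        return Haplotype(
            loci=tuple(loci), alleles=tuple(self.alleles[index[l]] for l in loci)
        )

    def truncated(self, resolution: int | None = 2) -> "Haplotype":
        """Haplotype with every allele truncated to ``resolution`` fields."""
        if resolution is None:
            return self
        return Haplotype(
            loci=self.loci,
            alleles=tuple(truncate(a, resolution) for a in self.alleles),
        )


#: Separator used when printing multi-locus haplotypes.
HAPLOTYPE_SEP = "~"


def parse_haplotype(text: str, loci: tuple[str, ...] | list[str]) -> Haplotype:
    """Parse a ``~``-joined haplotype string against an explicit locus list."""
    parts = text.strip().split(HAPLOTYPE_SEP)
    if len(parts) != len(loci):
        raise AlleleParseError(
            f"haplotype {text!r} has {len(parts)} alleles, expected {len(loci)}"
        )
    alleles = tuple(parse_allele(p, locus=l) for p, l in zip(parts, loci))
    return Haplotype(loci=tuple(loci), alleles=alleles)


def format_haplotype(h: Haplotype) -> str:
    """Join allele names with ``~`` exactly as printed in frequency tables."""
    return HAPLOTYPE_SEP.join(format_allele(a) for a in h.alleles)
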