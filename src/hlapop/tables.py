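"""Haplotype frequency tables.

A :class:`HaplotypeTable` maps multi-locus haplotypes to frequencies over a
stated number of chromosomes (2N), optionally with integer counts.  All
downstream statistics (LD, conserved extended haplotypes, ancestry
aggregation) marginalize and merge these tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .nomenclature import Haplotype

_FREQ_TOL = 1e-6


@dataclass
class HaplotypeTable:
    """Haplotype -> frequency over ``total_chromosomes`` chromosomes."""

    loci: tuple[str, ...]
    frequencies: dict[Haplotype, float] = field(default_factory=dict)
    counts: dict[Haplotype, int] | None = None
    total_chromosomes: int | None = None

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        for h in self.frequencies:
            if tuple(h.loci) != self.loci:
                raise ValueError(f"haplotype {h} loci {h.loci} != table loci {self.loci}")
        if self.counts is not None and self.total_chromosomes:
            for h, c in self.counts.items():
                f = self.frequencies.get(h, 0.0)
                if abs(c / self.total_chromosomes - f) > 0.5 / self.total_chromosomes + _FREQ_TOL:
                    raise ValueError(
                        f"count {c}/{self.total_chromosomes} disagrees with frequency {f} for {h}"
                    )

    @classmethod
    def from_counts(
        cls, loci, counts: dict[Haplotype, int], total_chromosomes: int | None = None
    ) -> "HaplotypeTable":
        total = total_chromosomes if total_chromosomes is not None else sum(counts.values())
        freqs = {h: c / total for h, c in counts.items()} if total else {}
        return cls(tuple(loci), freqs, dict(counts), total)

    def total_frequency(self) -> float:
        return float(sum(self.frequencies.values()))

    def is_complete(self) -> bool:
        return abs(self.total_frequency() - 1.0) <= _FREQ_TOL

    def count_of(self, h: Haplotype) -> int | None:
        if self.counts is not None and h in self.counts:
            return self.counts[h]
        if self.total_chromosomes is not None and h in self.frequencies:
            return round(self.frequencies[h] * self.total_chromosomes)
        return None

    def normalized(self) -> "HaplotypeTable":
        """Same table with frequencies rescaled to sum to one."""
        tot = self.total_frequency()
        if tot <= 0:
            raise ValueError("cannot normalize an empty table")
        freqs = {h: f / tot for h, f in self.frequencies.items()}
        return HaplotypeTable(self.loci, freqs, self.counts, self.total_chromosomes)

    def marginal(self, loci, resolution: int | None = 2) -> "HaplotypeTable":
        """Marginalize onto a subset of loci, truncating to ``resolution``.

        Frequencies of haplotypes sharing the projected identity are summed;
        counts, where present, are summed the same way.
        """
        loci = tuple(loci)
        missing = [l for l in loci if l not in self.loci]
        if missing:
            raise ValueError(f"loci not in table: {missing}")
        freqs: dict[Haplotype, float] = {}
        counts: dict[Haplotype, int] | None = {} if self.counts is not None else None
        for h, f in self.frequencies.items():
            sub = h.subset(loci).truncated(resolution)
            freqs[sub] = freqs.get(sub, 0.0) + f
            if counts is not None:
                counts[sub] = counts.get(sub, 0) + self.counts.get(h, 0)
        return HaplotypeTable(loci, freqs, counts, self.total_chromosomes)

    def allele_frequencies(self, locus: str, resolution: int | None = 2) -> dict[str, float]:
        """Marginal allele-frequency vector at one locus (keys are names)."""
        marg = self.marginal((locus,), resolution)
        return {h.key(resolution)[0]: f for h, f in marg.frequencies.items()}

    def sorted_entries(self, resolution: int | None = 2):
        """(haplotype, frequency) pairs by descending frequency, then name."""
        return sorted(
            self.frequencies.items(),
            key=lambda kv: (-kv[1], "~".join(kv[0].key(resolution))),
        )
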