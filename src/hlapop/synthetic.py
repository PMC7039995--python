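"""Synthetic cohorts, reference panels and geography/richness covariates.

The generator emulates the statistical structure the analyses assume: a
diploid cohort drawn from a small pool of multi-locus haplotypes in strong
linkage disequilibrium, with configurable whole-haplotype inbreeding, a
minority of phase-known family trios, ancestry-labeled pool haplotypes, and a
scramble (recombination) rate that can break conserved blocks.  A fixed seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Cohort, GenotypeRecord
from .nomenclature import Haplotype, parse_haplotype, LOCI
from .tables import HaplotypeTable

_POOL_TOL = 1e-9


@dataclass(frozen=True)
class PoolEntry:
    """One pool haplotype with its true frequency and ancestry label."""

    haplotype: Haplotype
    frequency: float
    ancestry: str


@dataclass
class SyntheticConfig:
    """Study conditions for :func:`simulate_cohort`.

    Defaults mirror a small, inbred Native American community typed at nine
    HLA loci: 218 unrelated subjects plus 12 phase-known trios, inbreeding
    coefficient F = 0.05, and a 2% chance that a sampled chromosome is a
    recombinant of two pool haplotypes.
    """

    pool: list[PoolEntry]
    n_subjects: int = 218
    inbreeding_f: float = 0.05
    n_trios: int = 12
    scramble_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pool:
            raise ValueError("haplotype pool must be non-empty")
        total = sum(e.frequency for e in self.pool)
        if abs(total - 1.0) > _POOL_TOL:
            raise ValueError(f"pool frequencies sum to {total}, not 1")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding coefficient must lie in [0, 1]")
        if not 0.0 <= self.scramble_rate <= 1.0:
            raise ValueError("scramble rate must lie in [0, 1]")

    @property
    def loci(self) -> tuple[str, ...]:
        return self.pool[0].haplotype.loci


# A compact nine-locus pool with the block structure typical of an isolated
# Mesoamerican population: rigid B~C and DRB1~DQ coupling, one European and
# one African admixture haplotype, and an Asian-traceable class I block.
_DEMO_POOL_SPEC: list[tuple[str, float, str]] = [
    ("A*31:01~B*40:02~C*03:04~DRB1*04:11~DRB4*01:03~DQA1*03:01~DQB1*03:02~DPA1*01:03~DPB1*04:02", 0.0667, "NativeAmerican"),
    ("A*31:01~B*40:02~C*03:04~DRB1*04:11~DRB4*01:01~DQA1*03:01~DQB1*03:02~DPA1*01:03~DPB1*04:02", 0.0529, "NativeAmerican"),
    ("A*68:03~B*35:01~C*07:02~DRB1*16:02~DRB5*02:02~DQA1*05:05~DQB1*03:01~DPA1*01:03~DPB1*04:02", 0.0414, "NativeAmerican"),
    ("A*24:02~B*35:12~C*04:01~DRB1*04:11~DRB4*01:03~DQA1*03:01~DQB1*03:02~DPA1*01:03~DPB1*04:02", 0.0368, "NativeAmerican"),
    ("A*68:01~B*39:05~C*07:02~DRB1*04:11~DRB4*01:03~DQA1*03:01~DQB1*03:02~DPA1*01:03~DPB1*04:02", 0.0345, "NativeAmerican"),
    ("A*02:06~B*35:01~C*07:02~DRB1*04:11~DRB4*01:03~DQA1*03:01~DQB1*03:02~DPA1*01:03~DPB1*04:02", 0.0299, "NativeAmerican"),
    ("A*68:03~B*39:05~C*07:02~DRB1*04:07~DRB4*01:01~DQA1*03:01~DQB1*03:02~DPA1*01:03~DPB1*04:02", 0.0299, "NativeAmerican"),
    ("A*24:02~B*40:02~C*15:02~DRB1*14:06~DRB3*01:01~DQA1*05:03~DQB1*03:01~DPA1*01:03~DPB1*04:01", 0.0253, "NativeAmerican"),
    ("A*24:02~B*39:05~C*07:02~DRB1*08:02~NULL~DQA1*04:01~DQB1*04:02~DPA1*01:03~DPB1*04:02", 0.0240, "NativeAmerican"),
    ("A*68:01~B*40:08~C*03:04~DRB1*04:07~DRB4*01:03~DQA1*03:01~DQB1*03:02~DPA1*01:03~DPB1*04:02", 0.0230, "MixedAncestry"),
    ("A*31:01~B*40:02~C*03:04~DRB1*14:02~DRB3*01:01~DQA1*05:03~DQB1*03:01~DPA1*01:03~DPB1*04:02", 0.0200, "Asian"),
    ("A*02:01~B*18:01~C*07:01~DRB1*11:04~DRB3*02:02~DQA1*05:05~DQB1*03:01~DPA1*01:03~DPB1*04:02", 0.0161, "European"),
    ("A*24:14~B*35:01~C*04:01~DRB1*04:04~DRB4*01:01~DQA1*03:01~DQB1*03:02~DPA1*02:02~DPB1*05:01", 0.0115, "NativeAmerican"),
    ("A*68:02~B*53:01~C*04:01~DRB1*13:03~DRB3*02:02~DQA1*02:01~DQB1*02:02~DPA1*02:02~DPB1*11:01", 0.0046, "African"),
]


def demo_pool(loci: tuple[str, ...] = LOCI) -> list[PoolEntry]:
    """Default nine-locus haplotype pool, frequencies normalized to one."""
    total = sum(w for _, w, _ in _DEMO_POOL_SPEC)
    return [
        PoolEntry(parse_haplotype(text, loci), w / total, label)
        for text, w, label in _DEMO_POOL_SPEC
    ]


def pool_table(pool: list[PoolEntry]) -> HaplotypeTable:
    """True haplotype frequencies of a pool as a table (recovery oracle)."""
    loci = pool[0].haplotype.loci
    freqs: dict[Haplotype, float] = {}
    for e in pool:
        freqs[e.haplotype] = freqs.get(e.haplotype, 0.0) + e.frequency
    return HaplotypeTable(loci, freqs)


def _draw_chromosome(cfg: SyntheticConfig, rng: np.random.Generator, p: np.ndarray) -> Haplotype:
    i = int(rng.choice(len(cfg.pool), p=p))
    h = cfg.pool[i].haplotype
    if cfg.scramble_rate > 0 and rng.random() < cfg.scramble_rate:
        j = int(rng.choice(len(cfg.pool), p=p))
        k = int(rng.integers(1, len(h.loci)))  # crossover point
        other = cfg.pool[j].haplotype
        h = Haplotype(h.loci, h.alleles[:k] + other.alleles[k:])
    return h


def simulate_cohort(cfg: SyntheticConfig) -> tuple[Cohort, HaplotypeTable]:
    """Draw a diploid cohort from the pool; returns (cohort, truth table).

    Each unrelated subject receives one chromosome from the pool and, with
    probability F, an identical-by-descent copy of it as the second; otherwise
    the second chromosome is an independent draw.  Trio children inherit one
    chromosome from each parent without recombination (the scramble rate acts
    on the parental draws themselves).
    """
    rng = np.random.default_rng(cfg.seed)
    p = np.array([e.frequency for e in cfg.pool])
    p = p / p.sum()
    loci = cfg.loci
    records: list[GenotypeRecord] = []

    def genotypes_of(c1: Haplotype, c2: Haplotype):
        return {
            locus: (c1.alleles[i], c2.alleles[i]) for i, locus in enumerate(loci)
        }

    def draw_pair() -> tuple[Haplotype, Haplotype]:
        c1 = _draw_chromosome(cfg, rng, p)
        if rng.random() < cfg.inbreeding_f:
            return c1, c1
        return c1, _draw_chromosome(cfg, rng, p)

    for i in range(cfg.n_subjects):
        c1, c2 = draw_pair()
        records.append(
            GenotypeRecord(subject_id=f"S{i + 1:04d}", genotypes=genotypes_of(c1, c2))
        )
    for t in range(cfg.n_trios):
        fam = f"F{t + 1:03d}"
        mother = draw_pair()
        father = draw_pair()
        child = (
            mother[int(rng.integers(2))],
            father[int(rng.integers(2))],
        )
        for suffix, pair, role in (
            ("M", mother, "parent"),
            ("P", father, "parent"),
            ("C", child, "child"),
        ):
            records.append(
                GenotypeRecord(
                    subject_id=f"{fam}{suffix}",
                    genotypes=genotypes_of(*pair),
                    family_id=fam,
                    role=role,
                )
            )
    return Cohort(loci, records), pool_table(cfg.pool)


def simulate_reference_panels(
    pool: list[PoolEntry],
    panel_n: int | dict[str, int],
    seed: int,
    panels_per_group: int = 1,
):
    """Multinomial resamples of each ancestry's sub-pool as reference panels.

    ``panel_n`` is the number of diploid individuals per panel (2n chromosomes
    are resampled), either one integer for all groups or a per-group mapping.
    Returns a list of :class:`hlapop.ancestry.ReferencePanel`.
    """
    from .ancestry import ReferencePanel

    rng = np.random.default_rng(seed)
    groups: dict[str, list[PoolEntry]] = {}
    for e in pool:
        groups.setdefault(e.ancestry, []).append(e)
    panels = []
    loci = pool[0].haplotype.loci
    for group in sorted(groups):
        entries = groups[group]
        sub = np.array([e.frequency for e in entries])
        sub = sub / sub.sum()
        n = panel_n[group] if isinstance(panel_n, dict) else panel_n
        if n <= 0:
            raise ValueError(f"panel size must be positive, got {n}")
        for k in range(panels_per_group):
            draws = rng.multinomial(2 * n, sub)
            counts = {
                e.haplotype: int(c) for e, c in zip(entries, draws) if c > 0
            }
            table = HaplotypeTable.from_counts(loci, counts, 2 * n)
            panels.append(
                ReferencePanel(
                    name=f"{group}_panel_{k + 1}", group=group, table=table, n=n
                )
            )
    return panels


@dataclass
class GeoScenario:
    """True regression structure for the diversity-vs-geography analysis.

    logit(PIC) = b0 + b1 * distance_km + b2 * pathogen_richness + N(0, sd),
    independently per locus.  Defaults follow the cross-population panel the
    regression is designed for: 122 populations, a negative distance slope of
    realistic magnitude (diversity lost with distance from Africa), and no
    true richness effect.
    """

    n_populations: int = 122
    intercept: float = 2.0
    distance_slope: float = -5e-5
    richness_slope: float = 0.0
    noise_sd: float = 0.15
    distance_range: tuple[float, float] = (500.0, 25000.0)
    richness_range: tuple[float, float] = (100.0, 250.0)
    loci: tuple[str, ...] = ("A", "B", "DRB1")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise standard deviation must be >= 0")


def simulate_geo_dataset(sc: GeoScenario) -> pd.DataFrame:
    """Per-population covariates and per-locus PIC under the scenario."""
    from scipy.special import expit

    rng = np.random.default_rng(sc.seed)
    d = rng.uniform(*sc.distance_range, sc.n_populations)
    r = rng.uniform(*sc.richness_range, sc.n_populations)
    # viral richness tracks overall richness with independent variation
    v = 0.4 * r + rng.uniform(0.0, 0.3 * sc.richness_range[1], sc.n_populations)
    out = pd.DataFrame(
        {
            "population": [f"pop{i + 1:03d}" for i in range(sc.n_populations)],
            "distance_km": d,
            "pathogen_richness": r,
            "viral_richness": v,
        }
    )
    for locus in sc.loci:
        eta = (
            sc.intercept
            + sc.distance_slope * d
            + sc.richness_slope * r
            + (rng.normal(0.0, sc.noise_sd, sc.n_populations) if sc.noise_sd > 0 else 0.0)
        )
        out[f"PIC_{locus}"] = expit(eta)
    return out
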