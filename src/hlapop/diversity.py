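"""Per-locus diversity metrics: allele frequencies, heterozygosity, a
Monte-Carlo exact Hardy-Weinberg test, polymorphism information content (PIC)
and power of discrimination (PD).

Definitions
-----------
* OH — fraction of heterozygous subjects at the locus.
* EH — expected heterozygosity 1 − Σp²; an unbiased small-sample factor
  2N/(2N−1) is available but off by default.
* PIC — Botstein's linkage-marker informativeness,
  1 − Σp² − Σ_{i<j} 2 p_i² p_j², computed through the identity
  Σ_{i<j} 2 p_i² p_j² = (Σp²)² − Σp⁴.
* PD — probability that two random individuals differ in genotype,
  1 − ΣG² over observed genotype frequencies (forensic convention; an
  HWE-expected variant is provided).
* HWE — Monte-Carlo exact test: the 2N allele copies are repeatedly shuffled
  into N random genotypes and the heterozygote count is compared two-sidedly
  with the observed value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Cohort
from .nomenclature import allele_key


@dataclass
class DiversitySummary:
    locus: str
    oh: float
    eh: float
    hwe_p: float
    pic: float
    pd: float


def allele_freqs(cohort: Cohort, locus: str, resolution: int | None = 2) -> dict[str, float]:
    """Gene-counting allele frequencies over 2N chromosomes at one locus."""
    counts: dict[str, int] = {}
    n = 0
    for r in cohort.records:
        if locus in r.missing_loci or locus not in r.genotypes:
            continue
        n += 1
        for a in r.genotypes[locus]:
            key = allele_key(a, resolution)
            counts[key] = counts.get(key, 0) + 1
    if n == 0:
        raise ValueError(f"no subject typed at locus {locus}")
    two_n = 2 * n
    return {k: c / two_n for k, c in sorted(counts.items())}


def pic(freqs) -> float:
    """Polymorphism information content of an allele-frequency vector."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("negative allele frequency")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - (s2 * s2 - s4)


def heterozygosity(
    cohort: Cohort, locus: str, resolution: int | None = 2, unbiased: bool = False
) -> tuple[float, float]:
    """(observed, expected) heterozygosity at one locus."""
    typed = [
        r
        for r in cohort.records
        if locus in r.genotypes and locus not in r.missing_loci
    ]
    if not typed:
        raise ValueError(f"no subject typed at locus {locus}")
    oh = sum(r.is_heterozygous(locus, resolution) for r in typed) / len(typed)
    p = np.array(list(allele_freqs(cohort, locus, resolution).values()))
    eh = 1.0 - float(np.sum(p**2))
    if unbiased:
        two_n = 2 * len(typed)
        eh *= two_n / (two_n - 1)
    return oh, eh


def hwe_test(
    cohort: Cohort,
    locus: str,
    n_steps: int = 10000,
    seed: int = 0,
    resolution: int | None = 2,
) -> float:
    """Monte-Carlo exact Hardy-Weinberg test at one locus.

    All 2N allele copies are shuffled into N random genotype pairs ``n_steps``
    times; the two-sided p-value doubles the smaller tail of the permutation
    distribution of the heterozygote count around the observed value, with the
    usual +1 correction.  A monomorphic locus returns p = 1 with a warning.
    """
    typed = [
        r
        for r in cohort.records
        if locus in r.genotypes and locus not in r.missing_loci
    ]
    if not typed:
        raise ValueError(f"no subject typed at locus {locus}")
    keys: list[str] = []
    observed_het = 0
    for r in typed:
        a, b = r.genotypes[locus]
        ka, kb = allele_key(a, resolution), allele_key(b, resolution)
        keys += [ka, kb]
        observed_het += ka != kb
    uniq = sorted(set(keys))
    if len(uniq) < 2:
        warnings.warn(f"locus {locus} is monomorphic; HWE p-value set to 1")
        return 1.0
    code = {k: i for i, k in enumerate(uniq)}
    alleles = np.array([code[k] for k in keys], dtype=np.int64)
    rng = np.random.default_rng(seed)
    n_le = 0
    n_ge = 0
    for _ in range(n_steps):
        perm = rng.permutation(alleles)
        het = int(np.sum(perm[0::2] != perm[1::2]))
        n_le += het <= observed_het
        n_ge += het >= observed_het
    p_low = (n_le + 1) / (n_steps + 1)
    p_high = (n_ge + 1) / (n_steps + 1)
    return min(1.0, 2.0 * min(p_low, p_high))


def genotype_freqs(cohort: Cohort, locus: str, resolution: int | None = 2) -> dict[tuple[str, str], float]:
    """Observed unordered genotype frequencies at one locus."""
    counts: dict[tuple[str, str], int] = {}
    n = 0
    for r in cohort.records:
        if locus in r.missing_loci or locus not in r.genotypes:
            continue
        n += 1
        a, b = r.genotypes[locus]
        g = tuple(sorted((allele_key(a, resolution), allele_key(b, resolution))))
        counts[g] = counts.get(g, 0) + 1
    if n == 0:
        raise ValueError(f"no subject typed at locus {locus}")
    return {g: c / n for g, c in sorted(counts.items())}


def power_of_discrimination(genotype_frequencies) -> float:
    """PD = 1 − ΣG² over genotype frequencies."""
    g = np.asarray(
        list(genotype_frequencies.values())
        if isinstance(genotype_frequencies, dict)
        else genotype_frequencies,
        dtype=float,
    )
    if (g < 0).any():
        raise ValueError("negative genotype frequency")
    if abs(g.sum() - 1.0) > 1e-6:
        raise ValueError(f"genotype frequencies sum to {g.sum()}, not 1")
    return 1.0 - float(np.sum(g**2))


def expected_pd(freqs) -> float:
    """PD computed from HWE-expected genotype frequencies (variant)."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, dtype=float)
    hom = p**2
    het = 2.0 * np.outer(p, p)[np.triu_indices(len(p), k=1)]
    g = np.concatenate([hom, het])
    return 1.0 - float(np.sum(g**2))


def diversity_table(
    cohort: Cohort,
    loci=None,
    resolution: int | None = 2,
    hwe_steps: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Locus-by-locus summary (OH, EH, HWE p, PIC, PD)."""
    loci = tuple(loci) if loci is not None else cohort.loci
    rows = []
    for i, locus in enumerate(loci):
        oh, eh = heterozygosity(cohort, locus, resolution)
        freqs = allele_freqs(cohort, locus, resolution)
        rows.append(
            DiversitySummary(
                locus=locus,
                oh=oh,
                eh=eh,
                hwe_p=hwe_test(cohort, locus, hwe_steps, seed + i, resolution),
                pic=pic(freqs),
                pd=power_of_discrimination(genotype_freqs(cohort, locus, resolution)),
            )
        )
    return pd.DataFrame(
        [
            {
                "locus": r.locus,
                "OH": r.oh,
                "EH": r.eh,
                "p_value": r.hwe_p,
                "PIC": r.pic,
                "PD": r.pd,
            }
            for r in rows
        ]
    )
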