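"""Multi-locus haplotype frequency estimation.

Two routes, mirrored on standard practice for unphased HLA genotype tables:

* **Family segregation counting** — in parent/parent/child trios the
  transmitted and untransmitted parental chromosomes are often forced by
  Mendelian transmission; every fully resolved chromosome contributes one
  count.  Ambiguous trios are left to EM rather than guessed.
* **Expectation-maximization** — genotype-likelihood EM over the haplotypes
  compatible with at least one subject, with per-iteration pruning of
  vanishing candidates and multiple seeded restarts (the likelihood surface
  is multimodal under strong LD).

The hybrid estimate enters family-resolved chromosomes as fixed counts and
spreads the EM mass over the remaining chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .io import Cohort, GenotypeRecord
from .nomenclature import Allele, Haplotype, allele_key, truncate
from .tables import HaplotypeTable


@dataclass
class EMSettings:
    tolerance: float = 1e-7  # convergence threshold on log-likelihood change
    max_iterations: int = 1000
    restarts: int = 5
    prune_threshold: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.restarts < 1:
            raise ValueError("at least one restart is required")


@dataclass(frozen=True)
class MendelianInconsistency:
    family_id: str
    child_id: str
    locus: str


def _canonical(a: Allele, resolution: int | None) -> Allele:
    if a.is_absent or resolution is None:
        return a
    t = truncate(a, resolution)
    return _dc_replace(t, suffix=None)


def _genotype_keys(
    record: GenotypeRecord, loci, resolution: int | None
) -> dict[str, tuple[Allele, Allele]]:
    out = {}
    for locus in loci:
        a, b = record.genotypes[locus]
        out[locus] = (_canonical(a, resolution), _canonical(b, resolution))
    return out


def _compatible_pairs(
    record: GenotypeRecord, loci, resolution: int | None
) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs consistent with an unphased genotype."""
    loci = tuple(loci)
    geno = _genotype_keys(record, loci, resolution)
    het = [
        locus
        for locus in loci
        if allele_key(geno[locus][0], None) != allele_key(geno[locus][1], None)
    ]
    pairs: list[tuple[Haplotype, Haplotype]] = []
    n_het = len(het)
    # fix the orientation of the first heterozygous locus: unordered pairs
    n_cfg = 1 if n_het == 0 else 2 ** (n_het - 1)
    for cfg in range(n_cfg):
        left: list[Allele] = []
        right: list[Allele] = []
        bit = 0
        for locus in loci:
            a, b = geno[locus]
            if locus in het:
                if locus == het[0]:
                    flip = 0
                else:
                    flip = (cfg >> bit) & 1
                    bit += 1
                if flip:
                    a, b = b, a
            left.append(a)
            right.append(b)
        pairs.append(
            (Haplotype(loci, tuple(left)), Haplotype(loci, tuple(right)))
        )
    return pairs


def count_phase_known(
    cohort: Cohort, loci=None, resolution: int | None = 2
) -> tuple[HaplotypeTable, list[MendelianInconsistency]]:
    """Gene counting over family trios with forced phase.

    For each family with two parents and a child, transmission is resolved
    locus by locus; when the maternal/paternal origin of the child's alleles
    is unique at every locus, the two transmitted and two untransmitted
    parental chromosomes each contribute count 1.  Trios with any ambiguous
    locus contribute nothing (they are left to EM); trios where a child
    carries an allele absent from both parents are reported as Mendelian
    inconsistencies and contribute nothing.
    """
    loci = tuple(loci) if loci is not None else cohort.loci
    counts: dict[Haplotype, int] = {}
    inconsistencies: list[MendelianInconsistency] = []
    for fam_id, members in sorted(cohort.families().items()):
        parents = [r for r in members if r.role == "parent"]
        children = [r for r in members if r.role == "child"]
        if len(parents) != 2 or not children:
            continue
        child = children[0]
        if any(l in r.missing_loci for r in (child, *parents) for l in loci):
            continue
        mother, father = parents
        geno_c = _genotype_keys(child, loci, resolution)
        geno_m = _genotype_keys(mother, loci, resolution)
        geno_f = _genotype_keys(father, loci, resolution)
        mat_t: list[Allele] = []
        mat_u: list[Allele] = []
        pat_t: list[Allele] = []
        pat_u: list[Allele] = []
        inconsistent = False
        ambiguous = False
        for locus in loci:
            c = geno_c[locus]
            m = geno_m[locus]
            f = geno_f[locus]
            mk = [allele_key(a, None) for a in m]
            fk = [allele_key(a, None) for a in f]
            assignments = []
            for cm, cf in (c, (c[1], c[0])):
                if allele_key(cm, None) in mk and allele_key(cf, None) in fk:
                    key = (allele_key(cm, None), allele_key(cf, None))
                    if key not in [a[0] for a in assignments]:
                        assignments.append((key, (cm, cf)))
            if not assignments:
                inconsistencies.append(MendelianInconsistency(fam_id, child.subject_id, locus))
                inconsistent = True
                break
            if len(assignments) > 1:
                ambiguous = True
                break
            cm, cf = assignments[0][1]
            mat_t.append(cm)
            mat_u.append(m[1] if allele_key(m[0], None) == allele_key(cm, None) else m[0])
            pat_t.append(cf)
            pat_u.append(f[1] if allele_key(f[0], None) == allele_key(cf, None) else f[0])
        if inconsistent or ambiguous:
            continue
        for chrom in (mat_t, mat_u, pat_t, pat_u):
            h = Haplotype(loci, tuple(chrom))
            counts[h] = counts.get(h, 0) + 1
    return HaplotypeTable.from_counts(loci, counts), inconsistencies


def em_frequencies(
    cohort: Cohort, loci=None, settings: EMSettings | None = None, resolution: int | None = 2
) -> HaplotypeTable:
    """EM haplotype frequencies from unphased genotypes.

    E-step distributes each subject's unit mass over its compatible haplotype
    pairs in proportion to the current frequency product (2 f_i f_j, or f_i^2
    for a homozygous configuration); the M-step renormalizes the expected
    chromosome counts.  The log-likelihood is asserted non-decreasing; the
    best of ``settings.restarts`` seeded restarts is returned.
    """
    if settings is None:
        settings = EMSettings()
    loci = tuple(loci) if loci is not None else cohort.loci
    subjects = [r for r in cohort.records if not any(l in r.missing_loci for l in loci)]
    if not subjects:
        raise ValueError("no subject typed at every requested locus")

    pair_lists = [_compatible_pairs(r, loci, resolution) for r in subjects]
    index: dict[Haplotype, int] = {}
    for pairs in pair_lists:
        for h1, h2 in pairs:
            for h in (h1, h2):
                if h not in index:
                    index[h] = len(index)
    haps = sorted(index, key=lambda h: "~".join(h.key(None)))
    index = {h: i for i, h in enumerate(haps)}
    k = len(haps)
    n = len(subjects)
    two_n = 2 * n
    subj_pairs = [
        np.array([[index[h1], index[h2]] for h1, h2 in pairs], dtype=np.int64)
        for pairs in pair_lists
    ]

    def run(f0: np.ndarray) -> tuple[float, np.ndarray]:
        f = f0.copy()
        prev_ll = -np.inf
        for _ in range(settings.max_iterations):
            counts = np.zeros(k)
            ll = 0.0
            for pairs in subj_pairs:
                i, j = pairs[:, 0], pairs[:, 1]
                w = f[i] * f[j] * np.where(i == j, 1.0, 2.0)
                tot = w.sum()
                if tot <= 0.0:
                    # pruning removed every configuration: fall back to uniform
                    w = np.ones_like(w)
                    tot = w.sum()
                ll += np.log(tot)
                w = w / tot
                np.add.at(counts, i, w)
                np.add.at(counts, j, w)
            if ll + 1e-9 < prev_ll:
                raise AssertionError("EM log-likelihood decreased")
            f_new = counts / two_n
            # prune vanishing candidates between iterations
            f_new[f_new < settings.prune_threshold] = 0.0
            s = f_new.sum()
            if s <= 0:
                raise RuntimeError("all haplotype candidates pruned")
            f_new /= s
            if abs(ll - prev_ll) < settings.tolerance and prev_ll != -np.inf:
                return ll, f_new
            prev_ll = ll
            f = f_new
        return prev_ll, f

    rng = np.random.default_rng(settings.seed)
    best_ll, best_f = run(np.full(k, 1.0 / k))
    for _ in range(settings.restarts - 1):
        ll, f = run(rng.dirichlet(np.ones(k)))
        if ll > best_ll + 1e-12:
            best_ll, best_f = ll, f
    freqs = {h: float(best_f[i]) for h, i in index.items() if best_f[i] > 0}
    # tie-break for reporting: normalize exactly
    tot = sum(freqs.values())
    freqs = {h: f / tot for h, f in freqs.items()}
    return HaplotypeTable(loci, freqs, None, two_n)


def combine_estimates(counted: HaplotypeTable, em: HaplotypeTable) -> HaplotypeTable:
    """Merge family-resolved counts with EM mass over the remaining chromosomes.

    final frequency = (fixed count + EM frequency * EM chromosomes) / total.
    """
    if tuple(counted.loci) != tuple(em.loci):
        raise ValueError(f"locus lists differ: {counted.loci} vs {em.loci}")
    n_counted = counted.total_chromosomes or sum((counted.counts or {}).values())
    n_em = em.total_chromosomes or 0
    total = n_counted + n_em
    if total == 0:
        raise ValueError("both components are empty")
    freqs: dict[Haplotype, float] = {}
    for h, c in (counted.counts or {}).items():
        freqs[h] = freqs.get(h, 0.0) + c
    for h, f in em.frequencies.items():
        freqs[h] = freqs.get(h, 0.0) + f * n_em
    return HaplotypeTable(
        counted.loci, {h: v / total for h, v in freqs.items()}, None, total
    )
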