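"""Two-locus and block-level linkage disequilibrium.

For a haplotype carrying allele (or composite block) A at one unit and B at
the other, with haplotype frequency h and marginal frequencies pA, pB over
2N chromosomes:

* Δ  = h − pA·pB
* Δ′ = Δ / Δmax  (Lewontin standardization), with
  Δmax = min(pA(1−pB), pB(1−pA)) for Δ > 0 and
  Δmax = min(pA·pB, (1−pA)(1−pB)) for Δ < 0
* p  — two-sided Fisher exact test on the 2x2 chromosome table by default
  (valid at the small counts typical of block tables); chi-square optional
* t  = Δ / SE(Δ) with Var(Δ) = [pA(1−pA)pB(1−pB) + Δ(1−2pA)(1−2pB) − Δ²]/2N,
  a documented variant; values ≥ 2.0 are conventionally treated as
  significant.

Block scans marginalize a haplotype table onto the block loci and emit one
row per haplotype seen at least ``min_count`` times, ordered by descending
frequency.  Conserved extended haplotypes treat each sub-block as a composite
allele and apply the same pair statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .nomenclature import Haplotype
from .tables import HaplotypeTable

_SLACK = 1e-9


class UndefinedLDError(ValueError):
    """LD is undefined when a marginal frequency is 0 or 1 (monomorphic)."""


@dataclass
class LDResult:
    """One row of a block table: units, H.F., n, Δ, Δ′, p, t."""

    left: str
    right: str
    h: float
    n: int | None
    p_a: float
    p_b: float
    delta: float
    delta_prime: float
    p_value: float
    t: float

    @property
    def haplotype_name(self) -> str:
        return f"{self.left}~{self.right}"


@dataclass(frozen=True)
class BlockDefinition:
    """An ordered locus list defining a block (e.g. ``("B", "C")``)."""

    loci: tuple[str, ...]
    split: int = 1  # units = loci[:split] vs loci[split:]

    def __post_init__(self) -> None:
        if len(self.loci) < 2:
            raise ValueError("a block needs at least two loci")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("block loci must be distinct")
        if not 0 < self.split < len(self.loci):
            raise ValueError("split must leave loci on both sides")


def ld_pair(
    h: float,
    p_a: float,
    p_b: float,
    two_n: int | None,
    left: str = "A",
    right: str = "B",
    p_method: str = "fisher",
) -> LDResult:
    """Pair LD statistics from unrounded frequencies over 2N chromosomes.

    With ``two_n=None`` (a truth table of frequencies without a sample) only
    Δ and Δ′ are computed; p and t require a chromosome count.
    """
    if two_n is not None and two_n < 1:
        raise ValueError("two_n must be >= 1")
    if min(p_a, p_b) <= 0.0 or max(p_a, p_b) >= 1.0:
        raise UndefinedLDError(
            f"LD undefined for marginals pA={p_a}, pB={p_b} (monomorphic unit)"
        )
    slack = (0.5 / two_n if two_n else 0.0) + _SLACK
    if h > min(p_a, p_b) + slack:
        raise ValueError(f"haplotype frequency {h} exceeds min(pA, pB)={min(p_a, p_b)}")
    delta = h - p_a * p_b
    if delta > 0:
        d_max = min(p_a * (1.0 - p_b), p_b * (1.0 - p_a))
    elif delta < 0:
        d_max = min(p_a * p_b, (1.0 - p_a) * (1.0 - p_b))
    else:
        d_max = 1.0  # Δ = 0 -> Δ′ = 0
    delta_prime = delta / d_max if d_max > 0 else 0.0
    delta_prime = max(-1.0, min(1.0, delta_prime))

    if two_n is None:
        return LDResult(
            left=left,
            right=right,
            h=h,
            n=None,
            p_a=p_a,
            p_b=p_b,
            delta=delta,
            delta_prime=delta_prime,
            p_value=float("nan"),
            t=float("nan"),
        )

    n11 = round(h * two_n)
    n_a = round(p_a * two_n)
    n_b = round(p_b * two_n)
    table = [
        [n11, n_a - n11],
        [n_b - n11, two_n - n_a - n_b + n11],
    ]
    table = [[max(0, c) for c in row] for row in table]
    if p_method == "fisher":
        p_value = float(stats.fisher_exact(table, alternative="two-sided")[1])
    elif p_method == "chi2":
        p_value = float(stats.chi2_contingency(table, correction=False)[1])
    else:
        raise ValueError(f"unknown p-value method {p_method!r}")

    var = (
        p_a * (1.0 - p_a) * p_b * (1.0 - p_b)
        + delta * (1.0 - 2.0 * p_a) * (1.0 - 2.0 * p_b)
        - delta * delta
    ) / two_n
    t = delta / math.sqrt(var) if var > 0 else math.copysign(math.inf, delta)
    return LDResult(
        left=left,
        right=right,
        h=h,
        n=n11,
        p_a=p_a,
        p_b=p_b,
        delta=delta,
        delta_prime=delta_prime,
        p_value=p_value,
        t=t,
    )


def _unit_name(h: Haplotype, resolution: int | None = 2) -> str:
    return "~".join(h.key(resolution))


def extend_block(
    joint: HaplotypeTable,
    left_loci,
    right_loci,
    min_count: int = 2,
    resolution: int | None = 2,
    p_method: str = "fisher",
) -> list[LDResult]:
    """Pair LD between two disjoint composite units of a joint table.

    Each distinct sub-haplotype over ``left_loci`` (resp. ``right_loci``) is
    treated as a composite allele; marginals come from the joint table itself.
    Used both for plain two-locus blocks and for conserved extended haplotypes
    (e.g. B~C against DRB1~DQB1) and their extension to HLA-A.
    """
    left_loci = tuple(left_loci)
    right_loci = tuple(right_loci)
    if set(left_loci) & set(right_loci):
        raise ValueError("left and right units must be disjoint")
    all_loci = left_loci + right_loci
    block = joint.marginal(all_loci, resolution)
    left_m = block.marginal(left_loci, resolution)
    right_m = block.marginal(right_loci, resolution)
    two_n = joint.total_chromosomes
    results: list[LDResult] = []
    for hap, f in block.sorted_entries(resolution):
        count = block.count_of(hap)
        if count is not None and count < min_count:
            continue
        lh = hap.subset(left_loci)
        rh = hap.subset(right_loci)
        p_a = left_m.frequencies[lh.truncated(resolution)]
        p_b = right_m.frequencies[rh.truncated(resolution)]
        try:
            res = ld_pair(
                f,
                p_a,
                p_b,
                two_n,
                left=_unit_name(lh, resolution),
                right=_unit_name(rh, resolution),
                p_method=p_method,
            )
        except UndefinedLDError:
            res = LDResult(
                left=_unit_name(lh, resolution),
                right=_unit_name(rh, resolution),
                h=f,
                n=count,
                p_a=p_a,
                p_b=p_b,
                delta=0.0,
                delta_prime=float("nan"),
                p_value=float("nan"),
                t=float("nan"),
            )
        if count is not None:
            res.n = count
        results.append(res)
    results.sort(key=lambda r: (-r.h, r.haplotype_name))
    return results


def block_scan(
    table: HaplotypeTable,
    block: BlockDefinition,
    min_count: int = 2,
    resolution: int | None = 2,
    p_method: str = "fisher",
) -> list[LDResult]:
    """Scan a haplotype table for block rows (H.F., n, Δ′, p, t).

    The table is marginalized onto the block loci; the block's ``split``
    divides the loci into the two units whose association is measured (for a
    two-locus block this is simply allele vs allele).  Haplotypes seen fewer
    than ``min_count`` times are excluded, matching the convention of
    reporting only haplotypes found more than once.
    """
    missing = [l for l in block.loci if l not in table.loci]
    if missing:
        raise ValueError(f"block loci absent from table: {missing}")
    return extend_block(
        table,
        block.loci[: block.split],
        block.loci[block.split :],
        min_count=min_count,
        resolution=resolution,
        p_method=p_method,
    )
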