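"""Non-overlapping allele associations between pairs of HLA loci.

Given the chromosome-level allele pairs (x_i, y_i) of two loci, the *best
partner mass* in one direction is the fraction of chromosomes whose partner
allele is the modal partner of their own allele:

    f(X->Y) = sum over alleles a of max_b h(a, b)

``f_star`` is the larger of the two directional masses: 1 for a perfect
one-to-one pairing of alleles (complete non-overlap) and also 1 when one
locus is monomorphic — which is why the chance-corrected

    f_star_adj = (f_star − e) / (1 − e)

is the reported score, with e the f_star expected under independence computed
exactly from the marginals (the modal partner of every allele is then the
globally modal allele of the other locus, so e = max(max_a p_a, max_b q_b));
a degenerate e = 1 yields f_star_adj = 0.

Significance is judged against a seeded permutation null that shuffles one
column (both marginal allele-frequency vectors are preserved exactly) and
reports z = (observed − null mean) / null sd.  The z-score, not the absolute
calibration of the score, is the ranking quantity.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .tables import HaplotypeTable


@dataclass
class NonOverlapResult:
    pair: tuple[str, str]
    f_star_adj: float
    null_mean: float
    null_sd: float
    z: float
    n_permutations: int


def pairs_from_table(
    table: HaplotypeTable, locus_x: str, locus_y: str, resolution: int | None = 2
) -> list[tuple[str, str]]:
    """Expand a counted haplotype table into chromosome-level allele pairs."""
    marg = table.marginal((locus_x, locus_y), resolution)
    out: list[tuple[str, str]] = []
    for h, f in marg.sorted_entries(resolution):
        c = marg.count_of(h)
        if c is None:
            raise ValueError("table lacks counts/total; cannot expand to chromosomes")
        kx, ky = h.key(resolution)
        out.extend([(kx, ky)] * c)
    return out


def _directional_best_mass(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    joint = Counter(zip(x.tolist(), y.tolist()))
    best: dict[object, int] = {}
    for (a, _), c in joint.items():
        if c > best.get(a, 0):
            best[a] = c
    return sum(best.values()) / n


def _fstar_arrays(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    f_xy = _directional_best_mass(x, y)
    f_yx = _directional_best_mass(y, x)
    f_star = max(f_xy, f_yx)
    px = np.bincount(x).max() / len(x)
    py = np.bincount(y).max() / len(y)
    e = max(px, py)
    if 1.0 - e < 1e-12:
        return f_star, 0.0
    adj = (f_star - e) / (1.0 - e)
    return f_star, max(-1.0, min(1.0, adj))


def _encode(pairs) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) < 2:
        raise ValueError("need at least two haplotype pairs")
    xs, ys = zip(*pairs)
    ux = {v: i for i, v in enumerate(sorted(set(xs)))}
    uy = {v: i for i, v in enumerate(sorted(set(ys)))}
    return (
        np.array([ux[v] for v in xs], dtype=np.int64),
        np.array([uy[v] for v in ys], dtype=np.int64),
    )


def fstar(pairs) -> tuple[float, float]:
    """(f_star, f_star_adj) for a list of chromosome-level allele pairs."""
    x, y = _encode(pairs)
    return _fstar_arrays(x, y)


def permutation_null(
    pairs, n_perm: int = 5000, seed: int = 0, pair_name: tuple[str, str] = ("X", "Y")
) -> NonOverlapResult:
    """Observed f_star_adj against a seeded column-shuffle null.

    The Y column is shuffled ``n_perm`` times (either column gives the same
    null by symmetry); both marginal allele-frequency vectors are preserved
    exactly by construction.
    """
    x, y = _encode(pairs)
    _, observed = _fstar_arrays(x, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _fstar_arrays(x, rng.permutation(y))[1]
    mean = float(null.mean()) if n_perm else float("nan")
    sd = float(null.std(ddof=1)) if n_perm > 1 else float("nan")
    if not np.isfinite(sd) or sd == 0.0:
        warnings.warn(f"degenerate permutation null for pair {pair_name}; z set to inf")
        z = float("inf") if observed > mean else 0.0
    else:
        z = (observed - mean) / sd
    return NonOverlapResult(
        pair=pair_name,
        f_star_adj=observed,
        null_mean=mean,
        null_sd=sd,
        z=z,
        n_permutations=n_perm,
    )


def scan_locus_pairs(
    table: HaplotypeTable,
    loci=None,
    n_perm: int = 5000,
    seed: int = 0,
    resolution: int | None = 2,
) -> list[NonOverlapResult]:
    """Permutation z for every locus pair of a counted haplotype table.

    Each pair receives a deterministic child seed spawned from the master
    seed, so adding a pair does not perturb the others' nulls.
    """
    loci = tuple(loci) if loci is not None else table.loci
    results = []
    ss = np.random.SeedSequence(seed)
    pair_list = [
        (loci[i], loci[j]) for i in range(len(loci)) for j in range(i + 1, len(loci))
    ]
    children = ss.spawn(len(pair_list))
    for (lx, ly), child in zip(pair_list, children):
        pairs = pairs_from_table(table, lx, ly, resolution)
        child_seed = int(child.generate_state(1)[0] % (2**31))
        results.append(
            permutation_null(pairs, n_perm=n_perm, seed=child_seed, pair_name=(lx, ly))
        )
    return rank_pairs(results)


def rank_pairs(results: list[NonOverlapResult]) -> list[NonOverlapResult]:
    """Sort by descending z; ties broken by locus-pair name."""
    if not results:
        raise ValueError("no results to rank")
    return sorted(results, key=lambda r: (-r.z, r.pair))
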