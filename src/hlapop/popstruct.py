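"""Cross-population analyses on allele-frequency tables.

* Nei's DA distance: DA = 1 − (1/L) Σ_loci Σ_alleles sqrt(x_i y_i) over a
  shared allele universe (absent allele = frequency 0).
* Neighbor joining (Saitou-Nei) with a deterministic tie-break (smallest Q,
  then lexicographic node-label pair) and negative branch lengths clamped to
  zero; Newick export with bootstrap support as internal node labels.
* Bootstrap: alleles are resampled within loci with replacement (with as few
  as three loci, resampling whole loci is degenerate), DA and NJ are
  recomputed, and support is the fraction of replicates containing each
  internal bipartition.
* PCA: column-centered SVD of the concatenated per-locus frequency vectors
  (not scaled — frequencies share units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PopulationFreqSet:
    """Per-locus allele frequencies for one population, plus covariates."""

    population: str
    freqs: dict[str, dict[str, float]]  # locus -> allele name -> frequency
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, vec in self.freqs.items():
            total = sum(vec.values())
            if total <= 0:
                raise ValueError(f"{self.population}/{locus}: empty frequency vector")
            if total < 0.995:
                warnings.warn(
                    f"{self.population}/{locus}: frequencies sum to {total:.4f}; renormalizing"
                )
            if abs(total - 1.0) > 1e-6:
                self.freqs[locus] = {a: f / total for a, f in vec.items()}


def _allele_universe(pops: list[PopulationFreqSet], loci) -> dict[str, list[str]]:
    universe: dict[str, set[str]] = {l: set() for l in loci}
    for p in pops:
        for l in loci:
            if l not in p.freqs:
                raise ValueError(f"population {p.population} lacks locus {l}")
            universe[l].update(p.freqs[l])
    return {l: sorted(v) for l, v in universe.items()}


def da_distance(x: PopulationFreqSet, y: PopulationFreqSet, loci) -> float:
    """Nei et al. DA distance over the stated loci."""
    loci = tuple(loci)
    universe = _allele_universe([x, y], loci)
    acc = 0.0
    for l in loci:
        acc += sum(
            np.sqrt(x.freqs[l].get(a, 0.0) * y.freqs[l].get(a, 0.0))
            for a in universe[l]
        )
    return 1.0 - acc / len(loci)


def distance_matrix(pops: list[PopulationFreqSet], loci) -> pd.DataFrame:
    ids = [p.population for p in pops]
    m = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            d = da_distance(pops[i], pops[j], loci)
            m[i, j] = m[j, i] = d
    return pd.DataFrame(m, index=ids, columns=ids)


@dataclass
class TreeNode:
    """A node of an (unrooted, trifurcating-at-center) NJ tree."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> frozenset:
        if not self.children:
            return frozenset([self.name])
        out: set = set()
        for c, _ in self.children:
            out |= c.leaves()
        return frozenset(out)

    def newick(self, digits: int = 6) -> str:
        return self._newick_node(digits) + ";"

    def _newick_node(self, digits: int) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(
            f"{c._newick_node(digits)}:{bl:.{digits}f}" for c, bl in self.children
        )
        label = "" if self.support is None else f"{self.support:.3f}"
        return f"({inner}){label}"

    def bipartitions(self, all_leaves: frozenset | None = None) -> set[frozenset]:
        """Canonical internal bipartitions (smaller/lexicographic side)."""
        if all_leaves is None:
            all_leaves = self.leaves()
        out: set[frozenset] = set()

        def visit(node: TreeNode) -> None:
            for child, _ in node.children:
                clade = child.leaves()
                if 2 <= len(clade) <= len(all_leaves) - 2:
                    out.add(_canonical_split(clade, all_leaves))
                visit(child)

        visit(self)
        return out


def _canonical_split(clade: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - clade
    if len(clade) != len(other):
        return clade if len(clade) < len(other) else other
    return clade if sorted(clade) < sorted(other) else other


def nj_tree(d: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Deterministic: the joined pair minimizes Q with ties broken by the
    lexicographic pair of node labels (an internal node is labeled by its
    smallest leaf), so permuting the input order leaves the topology
    unchanged.  Negative branch lengths are clamped to zero.
    """
    if not np.allclose(d.values, d.values.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    ids = list(d.index)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least three populations")
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    labels: dict[str, str] = {i: i for i in ids}
    dist: dict[tuple[str, str], float] = {}
    for i in ids:
        for j in ids:
            if i != j:
                dist[(i, j)] = float(d.loc[i, j])
    active = sorted(ids)

    def get(i: str, j: str) -> float:
        return dist[(i, j)]

    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = get(i, j)
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        bi, bj = max(0.0, bi), max(0.0, bj)
        counter += 1
        new_id = f"__internal{counter}"
        new_node = TreeNode(children=[(nodes[i], bi), (nodes[j], bj)])
        nodes[new_id] = new_node
        labels[new_id] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(new_id, k)] = dist[(k, new_id)] = max(0.0, duk)
        active = sorted(
            [k for k in active if k not in (i, j)] + [new_id],
            key=lambda k: labels[k],
        )
    a, b, c = active
    # three-point formulas for the central node
    ba = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    bb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    bc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    return TreeNode(
        children=[
            (nodes[a], max(0.0, ba)),
            (nodes[b], max(0.0, bb)),
            (nodes[c], max(0.0, bc)),
        ]
    )


def bootstrap_support(
    pops: list[PopulationFreqSet], loci, n_reps: int = 1200, seed: int = 0
) -> TreeNode:
    """NJ tree with bootstrap support on internal nodes.

    Each replicate resamples the allele columns within every locus with
    replacement (to the original number of alleles), renormalizes, and
    recomputes DA and NJ; support is the fraction of replicates containing
    each internal bipartition of the point-estimate tree.
    """
    loci = tuple(loci)
    tree = nj_tree(distance_matrix(pops, loci))
    if n_reps <= 0:
        return tree
    universe = _allele_universe(pops, loci)
    all_leaves = tree.leaves()
    target = tree.bipartitions(all_leaves)
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    mats = {
        l: np.array([[p.freqs[l].get(a, 0.0) for a in universe[l]] for p in pops])
        for l in loci
    }
    ids = [p.population for p in pops]
    for _ in range(n_reps):
        rep_pops = []
        rep = {}
        for l in loci:
            cols = rng.integers(0, mats[l].shape[1], mats[l].shape[1])
            sub = mats[l][:, cols]
            sums = sub.sum(axis=1, keepdims=True)
            sums[sums == 0] = 1.0
            rep[l] = sub / sums
        for idx, pid in enumerate(ids):
            freqs = {
                l: {
                    f"a{c}": float(rep[l][idx, c])
                    for c in range(rep[l].shape[1])
                    if rep[l][idx, c] > 0
                }
                for l in loci
            }
            rep_pops.append(PopulationFreqSet(pid, freqs))
        rep_tree = nj_tree(distance_matrix(rep_pops, loci))
        for bp in rep_tree.bipartitions(all_leaves) & set(hits):
            hits[bp] += 1

    def annotate(node: TreeNode) -> None:
        for child, _ in node.children:
            clade = child.leaves()
            if 2 <= len(clade) <= len(all_leaves) - 2:
                bp = _canonical_split(clade, all_leaves)
                if bp in hits:
                    child.support = hits[bp] / n_reps
            annotate(child)

    annotate(tree)
    return tree


def frequency_matrix(pops: list[PopulationFreqSet], loci) -> pd.DataFrame:
    """Concatenated per-locus frequency vectors as populations x alleles."""
    loci = tuple(loci)
    universe = _allele_universe(pops, loci)
    cols = [f"{l}:{a}" for l in loci for a in universe[l]]
    data = [
        [p.freqs[l].get(a, 0.0) for l in loci for a in universe[l]] for p in pops
    ]
    return pd.DataFrame(data, index=[p.population for p in pops], columns=cols)


def pca(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered SVD; returns (coordinates, explained variance fractions)."""
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least two populations")
    centered = x - x.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0.0):
        warnings.warn("constant frequency matrix: zero total variance")
        coords = np.zeros((x.shape[0], 1))
        return (
            pd.DataFrame(coords, index=matrix.index, columns=["PC1"]),
            np.array([0.0]),
        )
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords = u * s
    explained = (s**2) / np.sum(s**2)
    names = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=matrix.index, columns=names), explained
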