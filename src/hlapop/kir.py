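"""KIR-ligand class aggregation of HLA class I allele frequencies.

HLA-Bw4 (some HLA-B and some HLA-A allotypes), HLA-C1 and HLA-C2 epitopes are
the ligands of the inhibitory receptors KIR3DL1, KIR2DL2/3 and KIR2DL1.  The
classification ships as an editable lookup file (two-field allele name ->
ligand class) rather than residue-level sequence logic; alleles absent from
the lookup count as "none" with a warning.
"""

from __future__ import annotations

import csv
import warnings
from importlib import resources

LIGAND_CLASSES = ("Bw4", "C1", "C2", "none")


def load_ligand_lookup(path=None) -> dict[str, str]:
    """Read a two-column ``allele<TAB>class`` lookup (default: bundled table)."""
    if path is None:
        source = resources.files("hlapop").joinpath("data/kir_ligands.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    lookup: dict[str, str] = {}
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        allele, cls = row[0].strip(), row[1].strip()
        if cls not in LIGAND_CLASSES:
            raise ValueError(f"unknown ligand class {cls!r} for {allele}")
        lookup[allele] = cls
    return lookup


def ligand_aggregate(
    freqs: dict[str, float], lookup: dict[str, str] | None = None
) -> dict[str, float]:
    """Sum allele frequencies per KIR-ligand class.

    ``freqs`` maps two-field allele names (possibly across loci, e.g. HLA-B
    Bw4 alleles together with Bw4-positive HLA-A allotypes) to study
    frequencies.  Unlisted alleles fall into "none" with a warning.
    """
    if lookup is None:
        lookup = load_ligand_lookup()
    out = {cls: 0.0 for cls in LIGAND_CLASSES}
    for allele, f in freqs.items():
        cls = lookup.get(allele)
        if cls is None:
            warnings.warn(f"allele {allele} absent from ligand lookup; counted as 'none'")
            cls = "none"
        out[cls] += f
    return out
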