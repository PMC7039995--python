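"""Most probable ancestry (MPA) of haplotype blocks and aggregate block
frequencies (ABF).

A block receives an ancestry label when it reaches a frequency threshold
(default 1%) in at least one reference panel of that continental group; among
qualifying groups the one with the highest supporting panel frequency wins,
with a fixed precedence order breaking exact ties.  Panels of admixed
populations never confer a label by themselves — they are reported as
supporting context only, and a block found only there is *not previously
reported* for the four-group accounting.  The ABF of a label is the summed
study frequency of the blocks assigned to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .nomenclature import Haplotype
from .tables import HaplotypeTable

ANCESTRY_GROUPS = ("NativeAmerican", "European", "African", "Asian")
MIXED = "MixedAncestry"
NOT_REPORTED = "NotPreviouslyReported"

#: tie precedence when two groups reach the same supporting frequency
_PRECEDENCE = {g: i for i, g in enumerate(ANCESTRY_GROUPS)}


@dataclass
class ReferencePanel:
    """A published population frequency table with its continental group."""

    name: str
    group: str  # one of ANCESTRY_GROUPS or MIXED
    table: HaplotypeTable
    n: int | None = None

    def __post_init__(self) -> None:
        if self.group not in ANCESTRY_GROUPS + (MIXED,):
            raise ValueError(f"unknown ancestry group {self.group!r}")

    def frequency_of(self, h: Haplotype, resolution: int | None = 2) -> float:
        """Frequency of a block in this panel, matched on the block's loci."""
        loci = h.loci
        missing = [l for l in loci if l not in self.table.loci]
        if missing:
            raise ValueError(f"panel {self.name} lacks loci {missing}")
        marg = self.table.marginal(loci, resolution)
        return marg.frequencies.get(h.truncated(resolution), 0.0)


@dataclass
class MPAAssignment:
    haplotype: Haplotype
    label: str
    supporting: dict[str, float] = field(default_factory=dict)  # panel -> freq
    max_frequency: float = 0.0


def assign_mpa(
    h: Haplotype,
    panels: list[ReferencePanel],
    threshold: float = 0.01,
    resolution: int | None = 2,
) -> MPAAssignment:
    """Assign a block's most probable ancestry from reference panels."""
    if not panels:
        raise ValueError("no reference panels supplied")
    supporting: dict[str, float] = {}
    group_max: dict[str, float] = {}
    for panel in panels:
        f = panel.frequency_of(h, resolution)
        if f > 0:
            supporting[panel.name] = f
        if panel.group == MIXED:
            continue
        group_max[panel.group] = max(group_max.get(panel.group, 0.0), f)
    candidates = [(g, f) for g, f in group_max.items() if f >= threshold]
    if not candidates:
        return MPAAssignment(
            haplotype=h,
            label=NOT_REPORTED,
            supporting=supporting,
            max_frequency=max(group_max.values(), default=0.0),
        )
    candidates.sort(key=lambda gf: (-gf[1], _PRECEDENCE[gf[0]]))
    label, best = candidates[0]
    return MPAAssignment(haplotype=h, label=label, supporting=supporting, max_frequency=best)


def abf(
    assignments: list[MPAAssignment], study_frequencies: dict[Haplotype, float]
) -> dict[str, float]:
    """Aggregate block frequency per ancestry label.

    Conservation: the values sum exactly to the total frequency mass of the
    included blocks.
    """
    out: dict[str, float] = {}
    for a in assignments:
        if a.haplotype not in study_frequencies:
            raise ValueError(f"no study frequency for {a.haplotype}")
        out[a.label] = out.get(a.label, 0.0) + study_frequencies[a.haplotype]
    return out


def mpa_table(
    table: HaplotypeTable,
    panels: list[ReferencePanel],
    threshold: float = 0.01,
    resolution: int | None = 2,
):
    """Assignments and ABF for every haplotype of a study frequency table."""
    trunc = table.marginal(table.loci, resolution)
    assignments = [
        assign_mpa(h, panels, threshold, resolution) for h, _ in trunc.sorted_entries()
    ]
    return assignments, abf(assignments, trunc.frequencies)
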