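"""End-to-end analysis pipeline over a genotyped cohort.

Stages: haplotype estimation (family counting + EM) -> two-locus blocks ->
conserved extended haplotypes and their HLA-A extension -> per-locus
diversity -> ancestry assignment/ABF -> non-overlap permutation scan.  Every
output table carries the run seed and an input checksum in a header comment;
identical config and inputs yield identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import estimation, io as hio, ld
from .ancestry import mpa_table
from .diversity import diversity_table
from .nomenclature import LOCI
from .nonoverlap import scan_locus_pairs
from .synthetic import SyntheticConfig, demo_pool, simulate_cohort, simulate_reference_panels


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    cohort_path: str | None = None  # None -> simulate the bundled demo cohort
    panels_dir: str | None = None  # None -> simulated panels from the demo pool
    loci: tuple[str, ...] = LOCI
    resolution: int = 2
    min_block_count: int = 2
    mpa_threshold: float = 0.01
    t_cutoff: float = 2.0
    n_permutations: int = 5000
    bootstrap: int = 1200
    seed: int = 0
    out_dir: str = "hlapop_out"

    def __post_init__(self) -> None:
        for name in ("min_block_count", "mpa_threshold", "t_cutoff", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        data["loci"] = tuple(data["loci"])
        return cls(**data)


def _checksum(cfg: RunConfig, cohort) -> str:
    # the stamp reflects inputs and analysis settings, not the output location
    settings = {k: v for k, v in asdict(cfg).items() if k != "out_dir"}
    payload = json.dumps(settings, sort_keys=True) + "|" + "|".join(
        f"{r.subject_id}:{','.join(str(a) for l in cfg.loci if l in r.genotypes for a in r.genotypes[l])}"
        for r in cohort.records
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _ld_frame(rows: list[ld.LDResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "haplotype": r.haplotype_name,
                "HF": round(r.h, 4),
                "n": r.n,
                "delta_prime": round(r.delta_prime, 4),
                "p": r.p_value,
                "t": round(r.t, 1),
            }
            for r in rows
        ]
    )


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns {table name: written path}."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - abort with the stage name
            raise PipelineError(name, exc) from exc

    def emit(name: str, frame: pd.DataFrame, stamp: str) -> None:
        path = out / f"{name}.csv"
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# seed={cfg.seed} input={stamp}\n")
            frame.to_csv(fh, index=False)
        outputs[name] = path

    # --- input ---------------------------------------------------------
    def load():
        if cfg.cohort_path is None:
            synth = SyntheticConfig(pool=demo_pool(cfg.loci), seed=cfg.seed)
            cohort, _ = simulate_cohort(synth)
            return cohort
        return hio.read_cohort(cfg.cohort_path, cfg.loci)

    cohort = stage("load", load)
    stamp = _checksum(cfg, cohort)

    # --- haplotype estimation ------------------------------------------
    def estimate():
        counted, _ = estimation.count_phase_known(cohort, cfg.loci, cfg.resolution)
        em = estimation.em_frequencies(
            cohort.unrelated(),
            cfg.loci,
            estimation.EMSettings(seed=cfg.seed),
            cfg.resolution,
        )
        return estimation.combine_estimates(counted, em), em

    table, counted_table = stage("estimate", estimate)
    hap_frame = pd.DataFrame(
        [
            {"haplotype": "~".join(h.key(cfg.resolution)), "frequency": round(f, 4)}
            for h, f in table.sorted_entries(cfg.resolution)
        ]
    )
    emit("haplotypes", hap_frame, stamp)

    # --- blocks and conserved extended haplotypes ----------------------
    # LD tables work on integer chromosome counts over 2N, as block tables do
    two_n = counted_table.total_chromosomes
    from .tables import HaplotypeTable

    counted_table = HaplotypeTable.from_counts(
        cfg.loci,
        {
            h: round(f * two_n)
            for h, f in counted_table.frequencies.items()
            if round(f * two_n) > 0
        },
        two_n,
    )

    emit(
        "blocks_b_c",
        _ld_frame(
            stage(
                "blocks",
                lambda: ld.block_scan(
                    counted_table,
                    ld.BlockDefinition(("B", "C")),
                    cfg.min_block_count,
                    cfg.resolution,
                ),
            )
        ),
        stamp,
    )
    emit(
        "blocks_drb1_dqb1",
        _ld_frame(
            ld.block_scan(
                counted_table,
                ld.BlockDefinition(("DRB1", "DQB1")),
                cfg.min_block_count,
                cfg.resolution,
            )
        ),
        stamp,
    )
    emit(
        "ceh",
        _ld_frame(
            stage(
                "ceh",
                lambda: ld.extend_block(
                    counted_table,
                    ("B", "C"),
                    ("DRB1", "DQB1"),
                    cfg.min_block_count,
                    cfg.resolution,
                ),
            )
        ),
        stamp,
    )
    emit(
        "ceh_a",
        _ld_frame(
            ld.extend_block(
                counted_table,
                ("A",),
                ("B", "C", "DRB1", "DQB1"),
                cfg.min_block_count,
                cfg.resolution,
            )
        ),
        stamp,
    )

    # --- diversity ------------------------------------------------------
    emit(
        "diversity",
        stage(
            "diversity",
            lambda: diversity_table(cohort.unrelated(), cfg.loci, cfg.resolution, seed=cfg.seed),
        ).round(4),
        stamp,
    )

    # --- ancestry -------------------------------------------------------
    def ancestry_stage():
        if cfg.panels_dir is not None:
            pdir = Path(cfg.panels_dir)
            if not pdir.is_dir():
                raise FileNotFoundError(f"panel directory not found: {pdir}")
            panels = _read_panel_dir(pdir)
        else:
            panels = simulate_reference_panels(demo_pool(cfg.loci), 500, cfg.seed)
        ceh_table = counted_table.marginal(("B", "C", "DRB1", "DQB1"), cfg.resolution)
        assignments, aggregate = mpa_table(ceh_table, panels, cfg.mpa_threshold, cfg.resolution)
        rows = [
            {
                "haplotype": "~".join(a.haplotype.key(cfg.resolution)),
                "mpa": a.label,
                "max_panel_frequency": round(a.max_frequency, 4),
            }
            for a in assignments
        ]
        rows += [
            {"haplotype": f"ABF:{label}", "mpa": "", "max_panel_frequency": round(f, 4)}
            for label, f in sorted(aggregate.items())
        ]
        return pd.DataFrame(rows)

    emit("mpa_abf", stage("mpa", ancestry_stage), stamp)

    # --- non-overlap -----------------------------------------------------
    results = stage(
        "nonoverlap",
        lambda: scan_locus_pairs(
            counted_table, cfg.loci, n_perm=cfg.n_permutations, seed=cfg.seed
        ),
    )
    emit(
        "nonoverlap",
        pd.DataFrame(
            [
                {
                    "pair": "~".join(r.pair),
                    "f_star_adj": round(r.f_star_adj, 4),
                    "null_mean": round(r.null_mean, 4),
                    "null_sd": round(r.null_sd, 6),
                    "z": round(r.z, 2),
                }
                for r in results
            ]
        ),
        stamp,
    )
    return outputs


def _read_panel_dir(pdir: Path):
    """Read a panel directory: a ``manifest.csv`` (file,population,group,n,loci)."""
    from .ancestry import ReferencePanel

    manifest = pdir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"missing panel manifest: {manifest}")
    meta = pd.read_csv(manifest)
    panels = []
    for _, row in meta.iterrows():
        loci = tuple(str(row["loci"]).split("~"))
        table = hio.read_frequency_table(pdir / str(row["file"]), loci)
        panels.append(
            ReferencePanel(
                name=str(row["population"]),
                group=str(row["group"]),
                table=table,
                n=int(row["n"]),
            )
        )
    return panels
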