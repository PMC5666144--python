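"""End-to-end orchestration of the backcross analysis.

:func:`run_demo` composes the full breeding-experiment analysis on
simulated data: three independent backcross lines with selection at the
fertility (FS) and mating-type (MAT) loci, introgression-block
detection per line, consensus across lines, a fertile/sterile
association panel, exact marker-trait tests with candidate-locus
localization, and the comparison of observed retained-gene counts with
the unlinked Leslie-style expectation.

Reproducibility: one global seed is expanded into per-stage child seeds
with :class:`numpy.random.SeedSequence` (spawn order: one child per
line, then the panel), so stages can be re-run standalone bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .backcross_sim import (
    SimConfig,
    make_genome_map,
    run_backcross_line,
    simulate_association_panel,
)
from .genome_io import write_bed, write_genotype_tsv, write_phenotype_tsv
from .inheritance_stats import (
    associate_markers,
    expected_retention,
    rank_candidate_locus,
    segregation_test,
)
from .region_scan import consensus_regions, detect_donor_blocks

logger = logging.getLogger("tricross")

__all__ = ["PipelineConfig", "run_demo", "stage_seeds"]


@dataclass
class PipelineConfig:
    """Flat stage-block configuration with a single global seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    window_markers: int = 25
    min_donor_frac: float = 0.9
    alpha: float = 0.05
    correction: str = "bonferroni"
    segregation_draws: int = 10_000
    seed: int = 0
    out_dir: str = "demo_out"
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("sim", {})
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
        return cls(sim=SimConfig(**sim_raw), **raw)


def stage_seeds(seed: int, n_lines: int) -> list[int]:
    """Deterministic child seeds: one per line plus one for the panel."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_lines + 1)]


def run_demo(config: PipelineConfig) -> dict:
    """Simulate, scan, associate, and compare against expectation.

    Writes intermediate artifacts (genotype/phenotype TSV, block BED,
    consensus/association JSON) under ``config.out_dir`` and returns the
    report dict (also written as ``report.json``).  All artifact paths
    in the report are relative to the output directory, so reports from
    identical seeds are byte-identical regardless of where they ran.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    cfg = config.sim
    gmap = make_genome_map(cfg)
    seeds = stage_seeds(config.seed, cfg.n_lines)
    logger.info("seed=%d stage_seeds=%s", config.seed, seeds)

    # --- breeding lines and introgression blocks
    lines = []
    blocks_per_line = []
    artifacts: dict[str, str] = {}
    for li in range(cfg.n_lines):
        rng = np.random.default_rng(seeds[li])
        hap, truth = run_backcross_line(cfg, rng, gmap)
        blocks = detect_donor_blocks(
            hap.origin, gmap, config.window_markers, config.min_donor_frac
        )
        lines.append((hap, truth))
        blocks_per_line.append(blocks)
        bed = f"line{li + 1}_blocks.bed"
        write_bed(
            [(b.group_id, b.start, b.end, f"line{li + 1}_block") for b in blocks],
            out / bed,
        )
        artifacts[f"line{li + 1}_blocks"] = bed

    consensus, consensus_gene_count = consensus_regions(blocks_per_line, gmap.genes)
    fs_group, fs_pos = gmap.selected_loci["FS"]
    fs_in_consensus = any(
        c.group_id == fs_group and c.start <= fs_pos <= c.end for c in consensus
    )

    # --- association panel (one further cross of line 1)
    rng_panel = np.random.default_rng(seeds[-1])
    panel = simulate_association_panel(
        cfg, rng_panel, line=lines[0][0], line_truth=lines[0][1], gmap=gmap
    )
    write_genotype_tsv(panel.genotypes, out / "panel_genotypes.tsv")
    write_phenotype_tsv(panel.phenotypes, out / "panel_phenotypes.tsv")
    artifacts["panel_genotypes"] = "panel_genotypes.tsv"
    artifacts["panel_phenotypes"] = "panel_phenotypes.tsv"

    assoc = associate_markers(panel.genotypes, panel.phenotypes, config.correction)
    locus = rank_candidate_locus(assoc, config.alpha, truth_locus=(fs_group, fs_pos))

    # unconditional fertile:sterile segregation from fresh gamete draws
    # (panel draws are bin-stopped and therefore biased estimators)
    from .backcross_sim import Haplotype, meiosis_gamete

    recurrent = Haplotype(np.full(gmap.total_markers, 0, dtype=np.int8))
    fs_idx = gmap.locus_index("FS")
    n_seg = config.segregation_draws
    n_fert = sum(
        int(meiosis_gamete(lines[0][0], recurrent, gmap, rng_panel).origin[fs_idx])
        for _ in range(n_seg)
    )
    seg_p = segregation_test(n_fert, n_seg - n_fert)

    # --- retention arithmetic
    expectation = expected_retention(cfg.n_backcrosses, len(gmap.genes) or cfg.n_genes)
    observed_genes = [truth.n_donor_genes(gmap) for _, truth in lines]

    report = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_lines": cfg.n_lines,
        "n_backcrosses": cfg.n_backcrosses,
        "consensus_regions": [
            {"group": c.group_id, "start": c.start, "end": c.end,
             "n_genes": c.n_qualifying}
            for c in consensus
        ],
        "consensus_gene_count": consensus_gene_count,
        "fs_locus": [fs_group, fs_pos],
        "fs_in_consensus": fs_in_consensus,
        "panel": {
            "n_draws": panel.n_draws,
            "n_fertile_draws": panel.n_fertile_draws,
        },
        "segregation": {
            "n_draws": n_seg,
            "fertile_percent": 100.0 * n_fert / n_seg,
            "p_vs_50_50": seg_p,
        },
        "association": [
            {"marker": list(r.marker), "p": r.p_value, "adjusted_p": r.adjusted_p,
             "direction": r.odds_direction}
            for r in assoc
        ],
        "candidate_locus": {
            "group": locus.group_id, "start": locus.start, "end": locus.end,
            "contains_fs": locus.contains_truth, "notice": locus.notice,
        },
        "expected_retention": {
            "fraction": expectation.expected_fraction,
            "genes": expectation.expected_genes,
            "genes_continuous": expectation.expected_genes_continuous,
        },
        "observed_donor_genes_per_line": observed_genes,
        "artifacts": artifacts,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
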