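"""Forward simulation of a haploid recurrent-backcross breeding scheme.

The scheme mirrors the construction of female-fertile lines in a
QM6a-like background: a fertile donor strain (all-donor haplotype) is
crossed to a sterile recurrent strain, and in every subsequent round the
selected progeny is crossed back to the recurrent parent.  Selection
acts on two loci,

* ``FS`` — the fertility locus; only gametes carrying the donor allele
  are fertile and survive selection, and
* ``MAT`` — the mating-type locus; the donor carries MAT1-1, the
  recurrent parent MAT1-2, and a cross requires opposite types, so the
  selected progeny of each round usually keeps the donor MAT1-1 allele.

Meiosis follows the Haldane model: per linkage group the crossover
count is Poisson with mean equal to the genetic length in Morgans,
breakpoints are uniform, and there is no interference, so the
recombination fraction between loci d Morgans apart is
r = (1 - exp(-2 d)) / 2.

Besides the breeding simulator, this module generates every synthetic
input the downstream analyses need: a parental SNP catalog with genome
sequences and gene annotations (including planted coding-effect truth),
genotype/phenotype panels, and expression/growth profile matrices with
planted cluster structure — each with a machine-readable truth record so
recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    DONOR,
    RECURRENT,
    GeneModel,
    GenomeIOError,
    GenomeMap,
    GenotypeTable,
    LinkageGroup,
    PhenotypeTable,
    ProfileMatrix,
    SnpRecord,
    SnpTable,
    write_fasta,
    write_genotype_tsv,
    write_gff3,
    write_phenotype_tsv,
    write_vcf,
)

__all__ = [
    "Haplotype",
    "SimConfig",
    "TruthRecord",
    "PanelResult",
    "make_genome_map",
    "meiosis_gamete",
    "run_backcross_line",
    "simulate_association_panel",
    "emit_dataset",
    "simulate_coding_catalog",
    "simulate_profile_matrix",
    "haldane_r",
]


def haldane_r(d: float) -> float:
    """Recombination fraction for genetic distance ``d`` Morgans (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d))


@dataclass
class Haplotype:
    """Per-marker parental origin of a haploid individual."""

    origin: np.ndarray  # int8 over the GenomeMap's global marker order

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.int8)

    def is_fertile(self, gmap: GenomeMap) -> bool:
        return self.origin[gmap.locus_index("FS")] == DONOR

    def mating_type(self, gmap: GenomeMap) -> str:
        return "MAT1-1" if self.origin[gmap.locus_index("MAT")] == DONOR else "MAT1-2"


@dataclass
class SimConfig:
    """Breeding-scheme parameters.

    Defaults reproduce the study design: 7 linkage groups, 10 total
    crosses, 3 independent lines, a 20 fertile + 20 sterile association
    panel, and per-round selection for the donor (MAT1-1) mating-type
    allele.  ``final_mat_allele`` optionally switches the last round's
    mating-type selection (e.g. to MAT1-2 to obtain FF2-style lines).
    """

    n_groups: int = 7
    genetic_lengths: float | Sequence[float] = 1.0  # Morgans per group
    markers_per_group: int = 1000
    bp_per_group: int = 500_000
    n_genes: int = 9127
    n_backcrosses: int = 10
    n_lines: int = 3
    panel_fertile: int = 20
    panel_sterile: int = 20
    seed: int = 0
    select_mat_allele_per_round: str = "MAT1-1"  # MAT1-1 | MAT1-2 | none
    final_mat_allele: str | None = None
    max_gametes_per_round: int = 10_000

    def __post_init__(self) -> None:
        for name in ("n_groups", "markers_per_group", "n_backcrosses", "n_lines",
                     "panel_fertile", "panel_sterile"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.select_mat_allele_per_round not in ("MAT1-1", "MAT1-2", "none"):
            raise ValueError("select_mat_allele_per_round must be MAT1-1/MAT1-2/none")

    def lengths(self) -> list[float]:
        if np.isscalar(self.genetic_lengths):
            return [float(self.genetic_lengths)] * self.n_groups
        vals = [float(x) for x in self.genetic_lengths]
        if len(vals) != self.n_groups:
            raise ValueError("genetic_lengths length must equal n_groups")
        return vals


@dataclass
class TruthRecord:
    """Ground truth for one simulated line (or panel individual).

    ``donor_intervals`` maps each linkage group to the maximal runs of
    donor-origin markers, as 1-based closed bp intervals over marker
    positions.
    """

    donor_intervals: dict[str, list[tuple[int, int]]]
    origin: np.ndarray | None = None

    def n_donor_genes(self, gmap: GenomeMap) -> int:
        """Genes whose span overlaps any donor interval."""
        n = 0
        for gene in gmap.genes:
            for s, e in self.donor_intervals.get(gene.group_id, ()):
                if gene.start <= e and gene.end >= s:
                    n += 1
                    break
        return n


@dataclass
class PanelResult:
    genotypes: GenotypeTable
    phenotypes: PhenotypeTable
    truth: list[TruthRecord]
    line_truth: TruthRecord
    n_draws: int
    n_fertile_draws: int


# ---------------------------------------------------------------------------
# map construction
# ---------------------------------------------------------------------------


def make_genome_map(config: SimConfig | None = None, **overrides) -> GenomeMap:
    """Build the default synthetic map for a :class:`SimConfig`.

    Markers are evenly spaced; genes are tiled across groups in
    proportion to physical length; the FS locus sits mid-way along the
    sixth group (or the last group when fewer exist) and MAT mid-way
    along the third (or first), so the two selected loci are unlinked.
    """
    cfg = config or SimConfig()
    if overrides:
        cfg = SimConfig(**{**asdict(cfg), **overrides})
    lengths = cfg.lengths()
    groups = [
        LinkageGroup(f"lg{i + 1}", cfg.bp_per_group, lengths[i])
        for i in range(cfg.n_groups)
    ]
    markers = {}
    for g in groups:
        pos = np.linspace(1, g.physical_length, cfg.markers_per_group)
        pos = np.unique(np.round(pos).astype(np.int64))
        markers[g.id] = pos
    fs_group = groups[min(5, cfg.n_groups - 1)].id
    mat_group = groups[min(2, cfg.n_groups - 1)].id if cfg.n_groups > 1 else groups[0].id
    if fs_group == mat_group and cfg.n_groups > 1:
        mat_group = groups[0].id

    def _mid_marker(gid: str) -> int:
        pos = markers[gid]
        return int(pos[len(pos) // 2])

    selected = {"FS": (fs_group, _mid_marker(fs_group)),
                "MAT": (mat_group, _mid_marker(mat_group))}
    # tile genes proportionally to physical length
    genes: list[GeneModel] = []
    total_bp = sum(g.physical_length for g in groups)
    remaining = cfg.n_genes
    for i, g in enumerate(groups):
        n_here = (
            remaining if i == len(groups) - 1
            else int(round(cfg.n_genes * g.physical_length / total_bp))
        )
        n_here = min(n_here, remaining)
        remaining -= n_here
        if n_here == 0:
            continue
        spacing = g.physical_length / n_here
        glen = max(3, int(spacing * 0.6) // 3 * 3)
        for j in range(n_here):
            start = int(j * spacing) + 1
            end = min(start + glen - 1, g.physical_length)
            genes.append(
                GeneModel(
                    gene_id=f"{g.id}_g{j + 1:05d}",
                    group_id=g.id,
                    start=start,
                    end=end,
                    strand="+",
                    cds_segments=((start, end),) if (end - start + 1) % 3 == 0 else (),
                )
            )
    return GenomeMap(groups, markers, genes, selected)


# ---------------------------------------------------------------------------
# meiosis and backcrossing
# ---------------------------------------------------------------------------


def meiosis_gamete(
    parent_a: Haplotype,
    parent_b: Haplotype,
    gmap: GenomeMap,
    rng: np.random.Generator,
) -> Haplotype:
    """Draw one recombinant gamete from a transient a x b diploid.

    Crossovers per group ~ Poisson(genetic length); breakpoints uniform
    in genetic position; the starting parent of each group is a fair
    coin flip; origin alternates at each breakpoint.
    """
    n = gmap.total_markers
    if parent_a.origin.size != n or parent_b.origin.size != n:
        raise GenomeIOError("parent haplotypes indexed on a different marker grid")
    out = np.empty(n, dtype=np.int8)
    for g in gmap.groups:
        sl = gmap.group_slice(g.id)
        gpos = gmap.genetic_positions(g.id)
        k = rng.poisson(g.genetic_length)
        start_with_a = rng.random() < 0.5
        if k == 0:
            src = parent_a.origin[sl] if start_with_a else parent_b.origin[sl]
            out[sl] = src
            continue
        breaks = np.sort(rng.uniform(0.0, g.genetic_length, size=k))
        # parity of crossover count left of each marker decides the parent
        n_left = np.searchsorted(breaks, gpos)
        from_a = (n_left % 2 == 0) if start_with_a else (n_left % 2 == 1)
        seg = np.where(from_a, parent_a.origin[sl], parent_b.origin[sl])
        out[sl] = seg
    return Haplotype(out)


def _mat_ok(h: Haplotype, gmap: GenomeMap, allele: str | None) -> bool:
    if allele in (None, "none"):
        return True
    return h.mating_type(gmap) == allele


def _select_gamete(
    parent: Haplotype,
    recurrent: Haplotype,
    gmap: GenomeMap,
    rng: np.random.Generator,
    mat_allele: str | None,
    cap: int,
) -> Haplotype:
    fs = gmap.locus_index("FS")
    for _ in range(cap):
        g = meiosis_gamete(parent, recurrent, gmap, rng)
        if g.origin[fs] == DONOR and _mat_ok(g, gmap, mat_allele):
            return g
    raise RuntimeError(
        f"selection failed: no qualifying gamete in {cap} draws "
        "(check FS/MAT placement and selection rule)"
    )


def _donor_intervals(origin: np.ndarray, gmap: GenomeMap) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for g in gmap.groups:
        sl = gmap.group_slice(g.id)
        pos = gmap.markers[g.id]
        vec = origin[sl] == DONOR
        runs: list[tuple[int, int]] = []
        i = 0
        while i < vec.size:
            if vec[i]:
                j = i
                while j + 1 < vec.size and vec[j + 1]:
                    j += 1
                runs.append((int(pos[i]), int(pos[j])))
                i = j + 1
            else:
                i += 1
        out[g.id] = runs
    return out


def run_backcross_line(
    config: SimConfig,
    rng: np.random.Generator,
    gmap: GenomeMap | None = None,
) -> tuple[Haplotype, TruthRecord]:
    """Simulate one breeding line: n_backcrosses total crosses with selection.

    Cross 1 pairs the all-donor and all-recurrent parents; every later
    cross pairs the previously selected progeny with the all-recurrent
    parent.  Each round's surviving gamete carries the donor FS allele
    and satisfies the configured mating-type rule.
    """
    gmap = gmap or make_genome_map(config)
    if "FS" not in gmap.selected_loci:
        raise GenomeIOError("GenomeMap lacks an FS locus; selection impossible")
    donor = Haplotype(np.full(gmap.total_markers, DONOR, dtype=np.int8))
    recurrent = Haplotype(np.full(gmap.total_markers, RECURRENT, dtype=np.int8))
    current = donor
    for round_no in range(config.n_backcrosses):
        mat = config.select_mat_allele_per_round
        if round_no == config.n_backcrosses - 1 and config.final_mat_allele is not None:
            mat = config.final_mat_allele
        current = _select_gamete(
            current, recurrent, gmap, rng, mat, config.max_gametes_per_round
        )
    truth = TruthRecord(_donor_intervals(current.origin, gmap), current.origin.copy())
    return current, truth


def default_panel_markers(
    gmap: GenomeMap, line_truth: TruthRecord, per_block: int = 3
) -> list[tuple[str, int]]:
    """Markers genotyped in the association panel.

    Up to ``per_block`` markers (first, middle, last) inside each true
    donor interval of the line, plus one mid-group control marker on
    every linkage group without a donor interval — emulating a small
    panel of SNP-containing genes spanning all retained regions.
    """
    chosen: list[tuple[str, int]] = []
    for g in gmap.groups:
        pos = gmap.markers[g.id]
        blocks = line_truth.donor_intervals.get(g.id, [])
        if not blocks:
            chosen.append((g.id, int(pos[len(pos) // 2])))
            continue
        for s, e in blocks:
            inside = pos[(pos >= s) & (pos <= e)]
            if inside.size == 0:
                continue
            picks = {int(inside[0]), int(inside[inside.size // 2]), int(inside[-1])}
            for p in sorted(picks)[:per_block]:
                chosen.append((g.id, p))
    return chosen


def simulate_association_panel(
    config: SimConfig,
    rng: np.random.Generator,
    line: Haplotype | None = None,
    line_truth: TruthRecord | None = None,
    gmap: GenomeMap | None = None,
    marker_subset: Sequence[tuple[str, int]] | None = None,
) -> PanelResult:
    """One extra cross of a fertile line to the recurrent parent, binning
    gametes by fertility until ``panel_fertile`` + ``panel_sterile``
    individuals are collected and genotyping them at a marker subset."""
    gmap = gmap or make_genome_map(config)
    if line is None:
        line, line_truth = run_backcross_line(config, rng, gmap)
    if line_truth is None:
        line_truth = TruthRecord(_donor_intervals(line.origin, gmap), line.origin.copy())
    if marker_subset is None:
        marker_subset = default_panel_markers(gmap, line_truth)
    if not marker_subset:
        raise GenomeIOError("association panel marker subset is empty")
    idx = np.array([gmap.marker_index(g, p) for g, p in marker_subset])
    recurrent = Haplotype(np.full(gmap.total_markers, RECURRENT, dtype=np.int8))
    fs = gmap.locus_index("FS")

    fertile: list[Haplotype] = []
    sterile: list[Haplotype] = []
    n_draws = n_fertile_draws = 0
    while len(fertile) < config.panel_fertile or len(sterile) < config.panel_sterile:
        g = meiosis_gamete(line, recurrent, gmap, rng)
        n_draws += 1
        if g.origin[fs] == DONOR:
            n_fertile_draws += 1
            if len(fertile) < config.panel_fertile:
                fertile.append(g)
        elif len(sterile) < config.panel_sterile:
            sterile.append(g)
        if n_draws > 1000 * (config.panel_fertile + config.panel_sterile):
            raise RuntimeError("panel binning did not converge")

    individuals, rows, fert, mat, truths = [], [], {}, {}, []
    for tag, group in (("F", fertile), ("S", sterile)):
        for i, h in enumerate(group, 1):
            name = f"{tag}{i:03d}"
            individuals.append(name)
            rows.append(h.origin[idx])
            fert[name] = "fertile" if tag == "F" else "sterile"
            mat[name] = h.mating_type(gmap)
            truths.append(TruthRecord(_donor_intervals(h.origin, gmap), h.origin.copy()))
    genotypes = GenotypeTable(individuals, list(marker_subset), np.asarray(rows))
    phenotypes = PhenotypeTable(fert, mat)
    return PanelResult(genotypes, phenotypes, truths, line_truth, n_draws, n_fertile_draws)


# ---------------------------------------------------------------------------
# synthetic coding catalog (genes + sequences + SNPs with planted effects)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
# codons whose third position is 4-fold degenerate (any base keeps the aa)
_FOURFOLD_PREFIXES = ("GC", "GG", "CC", "CG", "CT", "TC", "GT", "AC")


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in ("TAA", "TAG", "TGA"):
            return c


def simulate_coding_catalog(
    n_genes: int = 50,
    codons_per_gene: int = 40,
    seed: int = 0,
    syn_per_gene: Sequence[int] | None = None,
    nonsyn_per_gene: Sequence[int] | None = None,
    noncoding_per_gene: Sequence[int] | None = None,
    intron_genes: bool = True,
):
    """Generate genes with sequence, planting SNPs of known coding effect.

    Returns ``(genome_seqs, genes, snp_table, truth)`` where truth maps
    gene_id -> (n_syn, n_nonsyn, n_noncoding).  Synonymous SNPs are
    planted at third positions of 4-fold degenerate codons, and
    nonsynonymous SNPs at second positions (always amino-acid changing
    under the standard code); noncoding SNPs go into introns/UTRs inside
    the gene span.  Roughly half the genes are minus strand, and half of
    the multi-codon genes get a 2-segment CDS with an intron.
    """
    rng = np.random.default_rng(seed)
    if syn_per_gene is None:
        syn_per_gene = rng.integers(0, 6, size=n_genes).tolist()
    if nonsyn_per_gene is None:
        nonsyn_per_gene = rng.integers(0, 6, size=n_genes).tolist()
    if noncoding_per_gene is None:
        noncoding_per_gene = rng.integers(0, 3, size=n_genes).tolist()

    flank = 30
    genes: list[GeneModel] = []
    chunks: list[str] = []
    snps: list[SnpRecord] = []
    truth: dict[str, tuple[int, int, int]] = {}
    group_id = "synth1"
    cursor = 1  # next free genomic position

    for gi in range(n_genes):
        n_syn = int(syn_per_gene[gi])
        n_non = int(nonsyn_per_gene[gi])
        n_nc = int(noncoding_per_gene[gi])
        strand = "+" if rng.random() < 0.5 else "-"
        # coding-strand codons, with designated planting sites
        codons = [_random_codon(rng) for _ in range(codons_per_gene)]
        site_pool = rng.permutation(codons_per_gene)
        syn_sites = site_pool[:n_syn]
        non_sites = site_pool[n_syn:n_syn + n_non]
        planted: list[tuple[int, int, str]] = []  # (codon_idx, within, alt coding base)
        for ci in syn_sites:
            prefix = _FOURFOLD_PREFIXES[rng.integers(len(_FOURFOLD_PREFIXES))]
            third = rng.choice(_BASES)
            codons[ci] = prefix + third
            alt = rng.choice([b for b in "ACGT" if b != third])
            planted.append((int(ci), 2, alt))
        for ci in non_sites:
            c = codons[ci]
            # second-position changes are nonsynonymous for every sense codon
            # (a stop gain also counts as nonsynonymous)
            alt = rng.choice([b for b in "ACGT" if b != c[1]])
            planted.append((int(ci), 1, alt))
        cds = "".join(codons)
        genomic_cds = cds if strand == "+" else str(
            "".join(_COMPLEMENT[b] for b in reversed(cds))
        )
        # optional intron splitting the CDS into two genomic segments
        use_intron = intron_genes and codons_per_gene >= 4 and rng.random() < 0.5
        intron_len = int(rng.integers(9, 30)) if use_intron else 0
        split = 3 * int(rng.integers(1, codons_per_gene)) if use_intron else len(cds)
        gene_start = cursor + flank
        if use_intron:
            intron = "".join(rng.choice(_BASES, size=intron_len))
            body = genomic_cds[:split] + intron + genomic_cds[split:]
            seg1 = (gene_start, gene_start + split - 1)
            seg2 = (gene_start + split + intron_len,
                    gene_start + split + intron_len + (len(cds) - split) - 1)
            segs = (seg1, seg2)
        else:
            body = genomic_cds
            segs = ((gene_start, gene_start + len(cds) - 1),)
        gene_end = gene_start + len(body) - 1
        utr_pad = 10
        span_start, span_end = gene_start - utr_pad, gene_end + utr_pad
        left = "".join(rng.choice(_BASES, size=gene_start - cursor))
        right = "".join(rng.choice(_BASES, size=utr_pad + flank))
        chunks.append(left + body + right)
        cursor = gene_end + utr_pad + flank + 1

        gene = GeneModel(
            gene_id=f"syn_g{gi + 1:04d}", group_id=group_id,
            start=span_start, end=span_end, strand=strand, cds_segments=segs,
        )
        genes.append(gene)

        def coding_to_genomic(offset: int) -> int:
            """Genomic position of coding-strand offset (0-based in CDS)."""
            if strand == "-":
                offset = len(cds) - 1 - offset  # position on the + strand CDS
            for s, e in segs:
                seg_len = e - s + 1
                if offset < seg_len:
                    return s + offset
                offset -= seg_len
            raise AssertionError("offset outside CDS")

        for ci, within, alt_coding in planted:
            off = 3 * ci + within
            gpos = coding_to_genomic(off)
            ref_coding = cds[off]
            if strand == "+":
                ref_g, alt_g = ref_coding, alt_coding
            else:
                ref_g, alt_g = _COMPLEMENT[ref_coding], _COMPLEMENT[alt_coding]
            snps.append(SnpRecord(group_id, gpos, ref_g, alt_g))
        # noncoding SNPs: UTR positions inside the span
        utr_positions = list(range(span_start, gene_start)) + list(
            range(gene_end + 1, span_end + 1)
        )
        for p in rng.choice(utr_positions, size=n_nc, replace=False):
            p = int(p)
            chunk_index = p - (cursor - len(chunks[-1]))
            ref = chunks[-1][chunk_index]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            snps.append(SnpRecord(group_id, p, ref, alt))
        truth[gene.gene_id] = (n_syn, n_non, n_nc)

    seq = "".join(chunks)
    genome = {group_id: seq}
    return genome, genes, SnpTable(records=snps), truth


# ---------------------------------------------------------------------------
# synthetic profile matrices
# ---------------------------------------------------------------------------


def simulate_profile_matrix(
    n_rows_per_archetype: Sequence[int] = (60, 60, 60),
    groups: Sequence[str] = ("bgA", "bgA", "bgA", "bgB", "bgB", "bgB"),
    archetype_means: Sequence[tuple[float, float]] = ((4.0, 1.0), (2.0, 2.0), (1.0, 4.0)),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ProfileMatrix, np.ndarray]:
    """Matrix with planted row archetypes across two (or more) sample groups.

    The default three archetypes emulate up-in-background-A / flat /
    up-in-background-B regulation patterns.  Returns the matrix and the
    true archetype label (1-based) per row.
    """
    rng = np.random.default_rng(seed)
    labels = sorted(set(groups))
    rows, truth = [], []
    for ai, n in enumerate(n_rows_per_archetype):
        means = archetype_means[ai]
        for _ in range(n):
            row = [
                max(0.0, means[labels.index(g) % len(means)] + rng.normal(0, noise_sd))
                for g in groups
            ]
            rows.append(row)
            truth.append(ai + 1)
    ids = [f"row{i + 1:04d}" for i in range(len(rows))]
    cols = [f"s{j + 1}_{g}" for j, g in enumerate(groups)]
    df = pd.DataFrame(rows, index=ids, columns=cols)
    matrix = ProfileMatrix(values=df, groups=dict(zip(cols, groups)))
    return matrix, np.asarray(truth)


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------


def emit_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, str]:
    """Write a complete reproducible synthetic dataset to ``out_dir``.

    Outputs: parental SNP catalog (VCF), gene annotations (GFF3), the
    recurrent-parent genome (FASTA), per-line genotype TSV over the full
    marker grid, the association panel genotype/phenotype TSVs, and a
    truth JSON with donor intervals per line.  Byte-identical for equal
    configs (the seed drives every random draw).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    gmap = make_genome_map(config)

    # recurrent-parent genome and a one-SNP-per-marker parental catalog
    seqs: dict[str, str] = {}
    snps = SnpTable()
    for g in gmap.groups:
        seq = rng.choice(_BASES, size=g.physical_length)
        for p in gmap.markers[g.id]:
            ref = seq[p - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            snps.records.append(SnpRecord(g.id, int(p), str(ref), str(alt)))
        seqs[g.id] = "".join(seq)

    lines = []
    truth_json: dict = {"seed": config.seed, "lines": {}}
    for li in range(config.n_lines):
        hap, truth = run_backcross_line(config, rng, gmap)
        lines.append((f"line{li + 1}", hap, truth))
        truth_json["lines"][f"line{li + 1}"] = {
            g: [[int(s), int(e)] for s, e in ivs]
            for g, ivs in truth.donor_intervals.items()
        }

    line_table = GenotypeTable(
        [name for name, _, _ in lines],
        gmap.marker_ids(),
        np.vstack([h.origin for _, h, _ in lines]),
    )
    panel = simulate_association_panel(
        config, rng, line=lines[0][1], line_truth=lines[0][2], gmap=gmap
    )
    truth_json["panel_markers"] = [[g, int(p)] for g, p in panel.genotypes.markers]
    truth_json["panel_n_draws"] = panel.n_draws
    truth_json["panel_n_fertile_draws"] = panel.n_fertile_draws

    paths = {
        "vcf": str(out / "parental_snps.vcf"),
        "gff3": str(out / "genes.gff3"),
        "fasta": str(out / "genome.fasta"),
        "line_genotypes": str(out / "line_genotypes.tsv"),
        "panel_genotypes": str(out / "panel_genotypes.tsv"),
        "panel_phenotypes": str(out / "panel_phenotypes.tsv"),
        "truth": str(out / "truth.json"),
    }
    write_vcf(snps, paths["vcf"],
              contigs={g.id: g.physical_length for g in gmap.groups})
    write_gff3(gmap.genes, paths["gff3"])
    write_fasta(seqs, paths["fasta"])
    write_genotype_tsv(line_table, paths["line_genotypes"])
    write_genotype_tsv(panel.genotypes, paths["panel_genotypes"])
    write_phenotype_tsv(panel.phenotypes, paths["panel_phenotypes"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
    return paths
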