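"""Data model and file I/O for the backcross-genetics pipeline.

This module is the single source of coordinate conventions: every
position in the data model is 1-based and intervals are closed, matching
GFF3 and VCF.  The only 0-based half-open surface is BED export, and the
conversion happens exactly once, at :func:`write_bed` / :func:`read_bed`.

Genotypes are haploid throughout: one allele per call, coded
``donor`` (the introgressing parent, e.g. CBS999.97), ``recurrent``
(the recurrent parent, e.g. QM6a) or ``missing``.  Diploid GT fields in
a VCF are rejected rather than silently collapsed, and missing calls are
never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DONOR",
    "RECURRENT",
    "MISSING",
    "NUCLEOTIDES",
    "GenomeIOError",
    "LinkageGroup",
    "GeneModel",
    "GenomeMap",
    "SnpRecord",
    "SnpTable",
    "GenotypeTable",
    "PhenotypeTable",
    "ProfileMatrix",
    "read_gff3",
    "write_gff3",
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "write_fasta",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "write_bed",
    "read_bed",
]

NUCLEOTIDES = frozenset("ACGT")

# haploid call codes used in GenotypeTable.calls
RECURRENT = 0
DONOR = 1
MISSING = -1

_CALL_TO_TOKEN = {RECURRENT: "recurrent", DONOR: "donor", MISSING: "missing"}
_TOKEN_TO_CALL = {v: k for k, v in _CALL_TO_TOKEN.items()}


class GenomeIOError(ValueError):
    """Raised for malformed input files or inconsistent data-model state."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinkageGroup:
    """A chromosome/scaffold abstraction with physical and genetic length."""

    id: str
    physical_length: int  # bp
    genetic_length: float  # Morgans

    def __post_init__(self) -> None:
        if self.physical_length < 1:
            raise GenomeIOError(f"linkage group {self.id!r}: physical_length must be >= 1")
        if self.genetic_length < 0:
            raise GenomeIOError(f"linkage group {self.id!r}: genetic_length must be >= 0")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its CDS structure in genomic (1-based closed) coordinates.

    ``cds_segments`` are stored in genomic order regardless of strand; the
    coding sequence of a minus-strand gene is the reverse complement of
    the concatenated segments.  ``annotatable`` is False when the total
    CDS length is not divisible by 3; such genes are excluded from
    coding-effect calls but retained for interval-based analyses.
    """

    gene_id: str
    group_id: str
    start: int
    end: int
    strand: str
    cds_segments: tuple[tuple[int, int], ...] = ()
    annotatable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise GenomeIOError(f"gene {self.gene_id!r}: invalid span {self.start}-{self.end}")
        segs = tuple(sorted(tuple(s) for s in self.cds_segments))
        for (s, e) in segs:
            if not (self.start <= s <= e <= self.end):
                raise GenomeIOError(
                    f"gene {self.gene_id!r}: CDS segment {s}-{e} outside span"
                )
        for (_, e1), (s2, _) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise GenomeIOError(f"gene {self.gene_id!r}: overlapping CDS segments")
        object.__setattr__(self, "cds_segments", segs)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_segments)


class GenomeMap:
    """Linkage groups, marker grid, gene annotations and selected loci.

    Markers are 1-based bp positions, strictly increasing within each
    group.  A single global marker ordering (groups in declared order,
    positions ascending) indexes every per-marker vector downstream
    (haplotypes, genotype tables).
    """

    def __init__(
        self,
        groups: Sequence[LinkageGroup],
        markers: Mapping[str, Sequence[int]],
        genes: Sequence[GeneModel] = (),
        selected_loci: Mapping[str, tuple[str, int]] | None = None,
    ) -> None:
        ids = [g.id for g in groups]
        if len(set(ids)) != len(ids):
            raise GenomeIOError("duplicate linkage group ids")
        self.groups: tuple[LinkageGroup, ...] = tuple(groups)
        self._group_by_id = {g.id: g for g in self.groups}
        self.markers: dict[str, np.ndarray] = {}
        for g in self.groups:
            pos = np.asarray(markers.get(g.id, ()), dtype=np.int64)
            if pos.size and not np.all(np.diff(pos) > 0):
                raise GenomeIOError(f"markers on {g.id} not strictly increasing")
            if pos.size and (pos[0] < 1 or pos[-1] > g.physical_length):
                raise GenomeIOError(f"markers on {g.id} outside physical length")
            self.markers[g.id] = pos
        for gene in genes:
            grp = self._group_by_id.get(gene.group_id)
            if grp is None:
                raise GenomeIOError(f"gene {gene.gene_id}: unknown group {gene.group_id}")
            if gene.end > grp.physical_length:
                raise GenomeIOError(
                    f"gene {gene.gene_id}: interval exceeds {grp.id} physical length"
                )
        self.genes: tuple[GeneModel, ...] = tuple(genes)
        self.selected_loci: dict[str, tuple[str, int]] = dict(selected_loci or {})
        # global marker index
        self._offsets: dict[str, int] = {}
        off = 0
        for g in self.groups:
            self._offsets[g.id] = off
            off += self.markers[g.id].size
        self._total = off
        self._index: dict[tuple[str, int], int] = {
            (g.id, int(p)): self._offsets[g.id] + i
            for g in self.groups
            for i, p in enumerate(self.markers[g.id])
        }
        for name, (gid, pos) in self.selected_loci.items():
            if (gid, pos) not in self._index:
                raise GenomeIOError(f"selected locus {name!r} does not resolve to a marker")

    # -- lookup -------------------------------------------------------------

    def group(self, group_id: str) -> LinkageGroup:
        return self._group_by_id[group_id]

    @property
    def total_markers(self) -> int:
        return self._total

    def group_slice(self, group_id: str) -> slice:
        off = self._offsets[group_id]
        return slice(off, off + self.markers[group_id].size)

    def marker_index(self, group_id: str, position: int) -> int:
        try:
            return self._index[(group_id, int(position))]
        except KeyError:
            raise GenomeIOError(f"no marker at {group_id}:{position}") from None

    def locus_index(self, name: str) -> int:
        if name not in self.selected_loci:
            raise GenomeIOError(f"selected locus {name!r} not defined")
        return self.marker_index(*self.selected_loci[name])

    def marker_ids(self) -> list[tuple[str, int]]:
        """Global marker list as (group_id, position) in index order."""
        return [
            (g.id, int(p)) for g in self.groups for p in self.markers[g.id]
        ]

    def genetic_positions(self, group_id: str) -> np.ndarray:
        """Marker positions in Morgans, assuming a uniform recombination rate."""
        g = self._group_by_id[group_id]
        pos = self.markers[group_id]
        return (pos - 0.5) / g.physical_length * g.genetic_length

    def genes_on(self, group_id: str) -> list[GeneModel]:
        return sorted(
            (gm for gm in self.genes if gm.group_id == group_id),
            key=lambda gm: gm.start,
        )


@dataclass
class SnpRecord:
    """A biallelic single-nucleotide variant between the two parents."""

    group_id: str
    position: int
    ref_allele: str
    alt_allele: str
    effect: str | None = None  # noncoding | synonymous | nonsynonymous

    def __post_init__(self) -> None:
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise GenomeIOError(
                f"SNP {self.group_id}:{self.position}: alleles must be A/C/G/T"
            )
        if self.ref_allele == self.alt_allele:
            raise GenomeIOError(
                f"SNP {self.group_id}:{self.position}: ref equals alt"
            )


@dataclass
class SnpTable:
    """SNV records plus tallies of records skipped during import."""

    records: list[SnpRecord] = field(default_factory=list)
    n_skipped_multiallelic: int = 0
    n_skipped_indel: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class GenotypeTable:
    """Haploid calls: individuals x markers, coded DONOR/RECURRENT/MISSING."""

    individuals: list[str]
    markers: list[tuple[str, int]]
    calls: np.ndarray  # int8, shape (n_individuals, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.individuals)) != len(self.individuals):
            raise GenomeIOError("duplicate individual ids")
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise GenomeIOError("genotype call matrix shape mismatch")
        bad = ~np.isin(self.calls, (DONOR, RECURRENT, MISSING))
        if bad.any():
            raise GenomeIOError("genotype calls must be donor/recurrent/missing")

    def row(self, individual: str) -> np.ndarray:
        return self.calls[self.individuals.index(individual)]


@dataclass
class PhenotypeTable:
    """Per-individual fertility and mating type."""

    fertility: dict[str, str]  # id -> fertile | sterile
    mating_type: dict[str, str]  # id -> MAT1-1 | MAT1-2

    def __post_init__(self) -> None:
        if set(self.fertility) != set(self.mating_type):
            raise GenomeIOError("fertility and mating_type must cover the same ids")
        for v in self.fertility.values():
            if v not in ("fertile", "sterile"):
                raise GenomeIOError(f"invalid fertility value {v!r}")
        for v in self.mating_type.values():
            if v not in ("MAT1-1", "MAT1-2"):
                raise GenomeIOError(f"invalid mating type {v!r}")

    def require_cover(self, genotypes: GenotypeTable) -> None:
        missing = set(genotypes.individuals) - set(self.fertility)
        if missing:
            raise GenomeIOError(f"individuals without phenotype: {sorted(missing)}")


@dataclass
class ProfileMatrix:
    """Non-negative expression or growth readings with sample group labels.

    Rows are genes or carbon sources; columns are samples.  Group labels
    with fewer than two samples are flagged in ``small_groups`` — testing
    operations refuse them, purely descriptive uses do not.
    """

    values: pd.DataFrame
    groups: dict[str, str]  # sample column -> group label
    small_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(self.values.columns)
        if unknown:
            raise GenomeIOError(f"group_spec names unknown columns: {sorted(unknown)}")
        counts: dict[str, int] = {}
        for col in self.values.columns:
            if col not in self.groups:
                raise GenomeIOError(f"sample column {col!r} has no group label")
            counts[self.groups[col]] = counts.get(self.groups[col], 0) + 1
        self.small_groups = tuple(sorted(g for g, n in counts.items() if n < 2))

    def group_columns(self, label: str) -> list[str]:
        return [c for c in self.values.columns if self.groups[c] == label]

    def group_values(self, label: str) -> np.ndarray:
        cols = self.group_columns(label)
        if not cols:
            raise GenomeIOError(f"no samples in group {label!r}")
        return self.values[cols].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene and CDS features into :class:`GeneModel` records.

    CDS segments outside their parent gene's span are rejected with a
    warning naming the gene; genes whose total CDS length is not a
    multiple of 3 are returned with ``annotatable=False``.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        segs: list[tuple[int, int]] = []
        for cds in db.children(feat, featuretype="CDS", order_by="start"):
            if cds.start < feat.start or cds.end > feat.end:
                warnings.warn(
                    f"gene {gene_id}: CDS {cds.start}-{cds.end} outside gene span; "
                    "segment rejected",
                    stacklevel=2,
                )
                continue
            segs.append((cds.start, cds.end))
        total = sum(e - s + 1 for s, e in segs)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                group_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                cds_segments=tuple(segs),
                annotatable=(total % 3 == 0 and total > 0),
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.group_id, g.start)):
            fh.write(
                f"{g.group_id}\ttricross\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t."
                f"\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_segments, 1):
                fh.write(
                    f"{g.group_id}\ttricross\tCDS\t{s}\t{e}\t.\t{g.strand}\t0"
                    f"\tID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> tuple[SnpTable, GenotypeTable | None]:
    """Read the biallelic-SNV subset of a VCF 4.x file.

    Multiallelic records and indels are skipped and tallied.  Haploid GT
    fields map 0 -> recurrent (ref), 1 -> donor (alt), '.' -> missing;
    diploid GT fields raise, since progeny are haploid ascospore
    derivatives.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise GenomeIOError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    table = SnpTable()
    per_sample: list[list[int]] = [[] for _ in samples]
    markers: list[tuple[str, int]] = []
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            table.n_skipped_multiallelic += 1
            continue
        ref, alt = rec.ref or "", alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
            table.n_skipped_indel += 1
            continue
        table.records.append(SnpRecord(rec.chrom, rec.pos, ref, alt))
        if samples:
            markers.append((rec.chrom, rec.pos))
            for j, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or len(gt) == 0 or (len(gt) == 1 and gt[0] is None):
                    per_sample[j].append(MISSING)
                elif len(gt) > 1:
                    raise GenomeIOError(
                        f"diploid GT at {rec.chrom}:{rec.pos} for sample {s}; "
                        "haploid calls required"
                    )
                else:
                    per_sample[j].append(DONOR if gt[0] == 1 else RECURRENT)
    genotypes = None
    if samples:
        calls = np.asarray(per_sample, dtype=np.int8)
        if calls.size == 0:
            calls = calls.reshape(len(samples), 0)
        genotypes = GenotypeTable(samples, markers, calls)
    return table, genotypes


def write_vcf(
    snps: SnpTable | Iterable[SnpRecord],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
    genotypes: GenotypeTable | None = None,
    include_effect: bool = True,
) -> None:
    """Write SNV records (and optional haploid genotypes) as uncompressed VCF."""
    records = list(snps.records if isinstance(snps, SnpTable) else snps)
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.group_id] = max(contigs.get(r.group_id, 0), r.position)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    if include_effect:
        header.add_meta(
            "INFO",
            items=[
                ("ID", "EFF"), ("Number", "1"), ("Type", "String"),
                ("Description", "Coding effect: noncoding/synonymous/nonsynonymous"),
            ],
        )
    sample_index: dict[tuple[str, int], int] = {}
    if genotypes is not None:
        header.add_meta(
            "FORMAT",
            items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                   ("Description", "Haploid genotype")],
        )
        for s in genotypes.individuals:
            header.add_sample(s)
        sample_index = {m: i for i, m in enumerate(genotypes.markers)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (r.group_id, r.position)):
            rec = out.new_record(
                contig=r.group_id, start=r.position - 1, stop=r.position,
                alleles=(r.ref_allele, r.alt_allele),
            )
            if include_effect and r.effect is not None:
                rec.info["EFF"] = r.effect
            if genotypes is not None:
                col = sample_index.get((r.group_id, r.position))
                for i, s in enumerate(genotypes.individuals):
                    call = MISSING if col is None else int(genotypes.calls[i, col])
                    rec.samples[s]["GT"] = (None,) if call == MISSING else (call,)
            out.write(rec)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV matrices and tables
# ---------------------------------------------------------------------------


def read_matrix_tsv(path: str | Path, group_spec: Mapping[str, str]) -> ProfileMatrix:
    """Load a genes/carbon-sources x samples matrix with a sample->group map.

    The first column holds row ids; every other cell must be numeric.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise GenomeIOError(f"duplicate row ids: {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna() | df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise GenomeIOError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return ProfileMatrix(values=numeric.astype(float), groups=dict(group_spec))


def write_matrix_tsv(matrix: ProfileMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t")


def write_genotype_tsv(table: GenotypeTable, path: str | Path) -> None:
    cols = [f"{g}:{p}" for g, p in table.markers]
    df = pd.DataFrame(
        [[_CALL_TO_TOKEN[int(c)] for c in row] for row in table.calls],
        index=table.individuals,
        columns=cols,
    )
    df.index.name = "individual"
    df.to_csv(path, sep="\t")


def read_genotype_tsv(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    markers = []
    for col in df.columns:
        group_id, _, pos = col.rpartition(":")
        markers.append((group_id, int(pos)))
    try:
        calls = np.asarray(
            [[_TOKEN_TO_CALL[v] for v in row] for row in df.to_numpy()], dtype=np.int8
        )
    except KeyError as exc:
        raise GenomeIOError(f"invalid genotype token {exc.args[0]!r}") from exc
    if calls.size == 0:
        calls = calls.reshape(len(df.index), 0)
    return GenotypeTable(list(df.index), markers, calls)


def write_phenotype_tsv(table: PhenotypeTable, path: str | Path) -> None:
    ids = sorted(table.fertility)
    df = pd.DataFrame(
        {
            "fertility": [table.fertility[i] for i in ids],
            "mating_type": [table.mating_type[i] for i in ids],
        },
        index=pd.Index(ids, name="individual"),
    )
    df.to_csv(path, sep="\t")


def read_phenotype_tsv(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return PhenotypeTable(
        fertility=dict(zip(df.index, df["fertility"])),
        mating_type=dict(zip(df.index, df["mating_type"])),
    )


# ---------------------------------------------------------------------------
# BED (the single 0-based half-open surface)
# ---------------------------------------------------------------------------


def write_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write (group, start, end, name) 1-based closed intervals as BED."""
    with open(path, "w") as fh:
        for group_id, start, end, name in intervals:
            fh.write(f"{group_id}\t{start - 1}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED back into 1-based closed intervals (lossless round trip)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            group_id, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            out.append((group_id, start0 + 1, end0, name))
    return out
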