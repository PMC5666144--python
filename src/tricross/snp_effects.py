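"""Coding-effect classification of SNVs against gene models.

Each SNP is classified relative to a gene as ``noncoding`` (inside the
gene span but outside every CDS segment), ``synonymous`` (the codon
substitution preserves the amino acid) or ``nonsynonymous`` (it does
not; stop gain and stop loss are folded into nonsynonymous, since the
downstream analyses use a binary synonymous/nonsynonymous split).

Multiple SNPs in one codon are evaluated independently against the
reference codon, matching standard per-SNP annotators.  Translation
uses the standard genetic code (fungal nuclear genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .genome_io import GeneModel, GenomeIOError, SnpRecord, SnpTable

__all__ = [
    "NONCODING",
    "SYNONYMOUS",
    "NONSYNONYMOUS",
    "GeneEffectCounts",
    "EffectAssignment",
    "classify_snp",
    "classify_all",
    "count_effects",
    "select_genes",
]

NONCODING = "noncoding"
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOP = "*"


def _translate_codon(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return _STOP
    return standard_dna_table.forward_table[codon]


@dataclass(frozen=True)
class GeneEffectCounts:
    """Per-gene SNP tallies; total = synonymous + nonsynonymous + noncoding."""

    gene_id: str
    n_snps_total: int
    n_synonymous: int
    n_nonsynonymous: int
    n_noncoding_in_span: int

    def __post_init__(self) -> None:
        parts = (self.n_synonymous, self.n_nonsynonymous, self.n_noncoding_in_span)
        if any(x < 0 for x in parts) or self.n_snps_total != sum(parts):
            raise ValueError(f"inconsistent counts for gene {self.gene_id}")


@dataclass(frozen=True)
class EffectAssignment:
    """One (SNP, gene) classification; a SNP in two genes yields two."""

    snp: SnpRecord
    gene_id: str
    effect: str


def _coding_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of ``pos`` in the gene's coding sequence, or None.

    The coding sequence is the concatenation of CDS segments in genomic
    order, reverse-complemented for minus-strand genes.
    """
    forward = 0
    for s, e in gene.cds_segments:
        if s <= pos <= e:
            forward += pos - s
            break
        forward += e - s + 1
    else:
        return None
    if gene.strand == "+":
        return forward
    return gene.cds_length - 1 - forward


def classify_snp(
    snp: SnpRecord, gene: GeneModel, genome_seq: str | Mapping[str, str]
) -> str:
    """Classify one SNP against one gene model.

    ``genome_seq`` is the reference (recurrent-parent) sequence of the
    gene's linkage group, or a mapping of group id to sequence.  The
    record's ref allele must match the sequence — a mismatch indicates a
    coordinate bug and raises.
    """
    seq = genome_seq[gene.group_id] if isinstance(genome_seq, Mapping) else genome_seq
    if not gene.contains(snp.position):
        raise GenomeIOError(
            f"SNP {snp.group_id}:{snp.position} outside gene {gene.gene_id}"
        )
    if not gene.annotatable:
        raise GenomeIOError(f"gene {gene.gene_id} is not annotatable (CDS length % 3 != 0)")
    observed = seq[snp.position - 1]
    if observed != snp.ref_allele:
        raise GenomeIOError(
            f"SNP {snp.group_id}:{snp.position}: ref allele {snp.ref_allele} "
            f"disagrees with genome sequence base {observed}"
        )
    off = _coding_offset(gene, snp.position)
    if off is None:
        return NONCODING
    ref_base = snp.ref_allele if gene.strand == "+" else _COMPLEMENT[snp.ref_allele]
    alt_base = snp.alt_allele if gene.strand == "+" else _COMPLEMENT[snp.alt_allele]
    codon_start = off - off % 3
    ref_codon = _coding_codon(gene, seq, codon_start)
    assert ref_codon[off % 3] == ref_base, "coding-coordinate mapping error"
    alt_codon = ref_codon[: off % 3] + alt_base + ref_codon[off % 3 + 1 :]
    return SYNONYMOUS if _translate_codon(ref_codon) == _translate_codon(alt_codon) else NONSYNONYMOUS


def _coding_codon(gene: GeneModel, seq: str, codon_start: int) -> str:
    """Extract the codon beginning at coding offset ``codon_start``."""
    # genomic positions of the gene's coding sequence, 5'->3'
    out = []
    for k in range(codon_start, codon_start + 3):
        gpos = _genomic_position(gene, k)
        base = seq[gpos - 1]
        out.append(base if gene.strand == "+" else _COMPLEMENT[base])
    return "".join(out)


def _genomic_position(gene: GeneModel, coding_offset: int) -> int:
    if gene.strand == "-":
        coding_offset = gene.cds_length - 1 - coding_offset
    for s, e in gene.cds_segments:
        seg_len = e - s + 1
        if coding_offset < seg_len:
            return s + coding_offset
        coding_offset -= seg_len
    raise GenomeIOError(f"coding offset outside CDS of gene {gene.gene_id}")


def classify_all(
    snps: SnpTable | Iterable[SnpRecord],
    genes: Sequence[GeneModel],
    genome_seq: Mapping[str, str],
    annotate_records: bool = True,
) -> tuple[list[EffectAssignment], int]:
    """Classify every SNP against every overlapping annotatable gene.

    Returns the assignments and the number of SNPs that fell in more
    than one gene (each is counted in every gene it overlaps).  When
    ``annotate_records`` is set, each SNP record's ``effect`` field is
    set to its most severe classification (nonsynonymous > synonymous >
    noncoding) for VCF pass-through.
    """
    records = list(snps.records if isinstance(snps, SnpTable) else snps)
    by_group: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_group.setdefault(g.group_id, []).append(g)
    for glist in by_group.values():
        glist.sort(key=lambda g: g.start)
    severity = {NONCODING: 0, SYNONYMOUS: 1, NONSYNONYMOUS: 2}
    assignments: list[EffectAssignment] = []
    n_multi = 0
    for snp in records:
        hits = [
            g for g in by_group.get(snp.group_id, ())
            if g.contains(snp.position) and g.annotatable
        ]
        if len(hits) > 1:
            n_multi += 1
        best: str | None = None
        for g in hits:
            eff = classify_snp(snp, g, genome_seq)
            assignments.append(EffectAssignment(snp, g.gene_id, eff))
            if best is None or severity[eff] > severity[best]:
                best = eff
        if annotate_records and best is not None:
            snp.effect = best
    return assignments, n_multi


def count_effects(
    assignments: Iterable[EffectAssignment], genes: Sequence[GeneModel]
) -> list[GeneEffectCounts]:
    """Aggregate per-(SNP, gene) classifications into per-gene counts.

    Every gene gets a record, including genes with no SNPs (all-zero).
    """
    tallies: dict[str, dict[str, int]] = {
        g.gene_id: {SYNONYMOUS: 0, NONSYNONYMOUS: 0, NONCODING: 0} for g in genes
    }
    for a in assignments:
        if a.gene_id not in tallies:
            raise GenomeIOError(f"assignment references unknown gene {a.gene_id}")
        tallies[a.gene_id][a.effect] += 1
    out = []
    for g in genes:
        t = tallies[g.gene_id]
        out.append(
            GeneEffectCounts(
                gene_id=g.gene_id,
                n_snps_total=t[SYNONYMOUS] + t[NONSYNONYMOUS] + t[NONCODING],
                n_synonymous=t[SYNONYMOUS],
                n_nonsynonymous=t[NONSYNONYMOUS],
                n_noncoding_in_span=t[NONCODING],
            )
        )
    return out


def select_genes(
    counts: Iterable[GeneEffectCounts], rule: str, threshold: int = 10
) -> set[str]:
    """Gene sets by nonsynonymous-SNP burden.

    ``zero_nonsyn`` selects genes with no nonsynonymous SNPs (candidates
    under purifying constraint); ``high_nonsyn`` selects genes with
    strictly more than ``threshold`` nonsynonymous SNPs (candidates
    under diversifying pressure).
    """
    if rule == "zero_nonsyn":
        return {c.gene_id for c in counts if c.n_nonsynonymous == 0}
    if rule == "high_nonsyn":
        return {c.gene_id for c in counts if c.n_nonsynonymous > threshold}
    raise ValueError(f"unknown selection rule {rule!r}")
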