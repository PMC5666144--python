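"""Genomic interval detection.

Three scans share the :class:`RegionCall` result type:

* :func:`scan_nonsyn_regions` — runs of neighbouring genes each carrying
  a high nonsynonymous-SNP burden, flagging chromosomal areas under
  diversifying pressure;
* :func:`detect_donor_blocks` — introgression blocks, i.e. sliding
  marker windows dominated by donor-origin calls in a backcrossed line;
* :func:`consensus_regions` — interval intersection of donor blocks
  across independent lines, the signature of a shared selected locus.

Detection is deterministic (density criteria, no significance model),
mirroring how retained regions are identified from SNP abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import (
    DONOR,
    MISSING,
    GeneModel,
    GenomeIOError,
    GenomeMap,
)
from .snp_effects import GeneEffectCounts

__all__ = [
    "RegionCall",
    "scan_nonsyn_regions",
    "detect_donor_blocks",
    "consensus_regions",
]


@dataclass(frozen=True)
class RegionCall:
    """A called genomic interval with its members and triggering statistic."""

    group_id: str
    start: int
    end: int
    statistic: str  # nonsyn_cluster | donor_block
    member_genes: tuple[str, ...] = ()
    n_qualifying: int = 0
    support: tuple[bool, ...] = ()

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, other: "RegionCall") -> bool:
        return (
            self.group_id == other.group_id
            and self.start <= other.end
            and self.end >= other.start
        )


# ---------------------------------------------------------------------------
# nonsynonymous-density gene clusters
# ---------------------------------------------------------------------------


def scan_nonsyn_regions(
    counts: Sequence[GeneEffectCounts],
    genes: Sequence[GeneModel],
    min_genes: int = 5,
    min_snps_per_gene: int = 10,
    max_gap_genes: int = 0,
    cumulative: bool = False,
) -> list[RegionCall]:
    """Maximal runs of positionally consecutive high-nonsyn genes.

    A gene qualifies when its nonsynonymous count is >= ``min_snps_per_gene``.
    A run may skip up to ``max_gap_genes`` consecutive below-threshold
    genes between qualifying ones and becomes a region when it holds at
    least ``min_genes`` qualifying genes.  With ``cumulative=True`` the
    per-gene threshold is dropped and a window of ``min_genes``
    consecutive genes qualifies when its summed nonsynonymous count
    reaches ``min_snps_per_gene`` (sensitivity-analysis mode).

    ``genes`` supplies positions; input must be sorted by (group, start).
    """
    count_by_gene = {c.gene_id: c for c in counts}
    ordered = [g for g in genes if g.gene_id in count_by_gene]
    keys = [(g.group_id, g.start) for g in ordered]
    if keys != sorted(keys):
        raise GenomeIOError("genes must be sorted by (group, start)")
    regions: list[RegionCall] = []
    by_group: dict[str, list[GeneModel]] = {}
    for g in ordered:
        by_group.setdefault(g.group_id, []).append(g)
    for group_id, glist in by_group.items():
        nsyn = np.array([count_by_gene[g.gene_id].n_nonsynonymous for g in glist])
        if cumulative:
            regions.extend(
                _cumulative_regions(group_id, glist, nsyn, min_genes, min_snps_per_gene)
            )
        else:
            regions.extend(
                _threshold_regions(
                    group_id, glist, nsyn, min_genes, min_snps_per_gene, max_gap_genes
                )
            )
    return regions


def _threshold_regions(group_id, glist, nsyn, min_genes, min_snps, max_gap):
    qual = nsyn >= min_snps
    regions = []
    i = 0
    n = len(glist)
    while i < n:
        if not qual[i]:
            i += 1
            continue
        # extend: qualifying genes separated by at most max_gap non-qualifying
        last_q = i
        j = i + 1
        gap = 0
        while j < n:
            if qual[j]:
                last_q = j
                gap = 0
            else:
                gap += 1
                if gap > max_gap:
                    break
            j += 1
        members = glist[i : last_q + 1]
        n_qual = int(qual[i : last_q + 1].sum())
        if n_qual >= min_genes:
            regions.append(
                RegionCall(
                    group_id=group_id,
                    start=members[0].start,
                    end=max(g.end for g in members),
                    statistic="nonsyn_cluster",
                    member_genes=tuple(g.gene_id for g in members),
                    n_qualifying=n_qual,
                )
            )
        i = last_q + 1
    return regions


def _cumulative_regions(group_id, glist, nsyn, min_genes, min_snps_total):
    flagged = np.zeros(len(glist), dtype=bool)
    csum = np.concatenate([[0], np.cumsum(nsyn)])
    for i in range(len(glist) - min_genes + 1):
        if csum[i + min_genes] - csum[i] >= min_snps_total:
            flagged[i : i + min_genes] = True
    regions = []
    i = 0
    while i < flagged.size:
        if flagged[i]:
            j = i
            while j + 1 < flagged.size and flagged[j + 1]:
                j += 1
            members = glist[i : j + 1]
            regions.append(
                RegionCall(
                    group_id=group_id,
                    start=members[0].start,
                    end=max(g.end for g in members),
                    statistic="nonsyn_cluster",
                    member_genes=tuple(g.gene_id for g in members),
                    n_qualifying=len(members),
                )
            )
            i = j + 1
        else:
            i += 1
    return regions


# ---------------------------------------------------------------------------
# donor introgression blocks
# ---------------------------------------------------------------------------


def detect_donor_blocks(
    calls: np.ndarray,
    gmap: GenomeMap,
    window_markers: int = 25,
    min_donor_frac: float = 0.9,
    min_informative_frac: float = 0.5,
) -> list[RegionCall]:
    """Sliding-window introgression-block detection on one haploid line.

    ``calls`` is the line's call vector over the map's global marker
    order.  Windows of ``window_markers`` consecutive markers whose
    donor fraction among non-missing calls is >= ``min_donor_frac`` are
    flagged; overlapping or adjacent flagged windows merge into maximal
    blocks spanning first to last flagged marker.  Windows with fewer
    than ``min_informative_frac`` non-missing calls are skipped.
    """
    calls = np.asarray(calls)
    if calls.ndim != 1 or calls.size != gmap.total_markers:
        raise GenomeIOError("calls vector does not match the marker grid")
    blocks: list[RegionCall] = []
    for g in gmap.groups:
        sl = gmap.group_slice(g.id)
        vec = calls[sl]
        pos = gmap.markers[g.id]
        m = vec.size
        if m == 0:
            continue
        w = window_markers
        if w > m:
            warnings.warn(
                f"window ({w} markers) exceeds {g.id} marker count ({m}); "
                "scanning the group as a single window",
                stacklevel=2,
            )
            w = m
        donor = (vec == DONOR).astype(np.int32)
        informative = (vec != MISSING).astype(np.int32)
        cd = np.concatenate([[0], np.cumsum(donor)])
        ci = np.concatenate([[0], np.cumsum(informative)])
        flagged_marker = np.zeros(m, dtype=bool)
        for i in range(m - w + 1):
            n_inf = ci[i + w] - ci[i]
            if n_inf < min_informative_frac * w:
                continue
            if (cd[i + w] - cd[i]) / n_inf >= min_donor_frac:
                flagged_marker[i : i + w] = True
        i = 0
        while i < m:
            if flagged_marker[i]:
                j = i
                while j + 1 < m and flagged_marker[j + 1]:
                    j += 1
                blocks.append(
                    RegionCall(
                        group_id=g.id,
                        start=int(pos[i]),
                        end=int(pos[j]),
                        statistic="donor_block",
                    )
                )
                i = j + 1
            else:
                i += 1
    return blocks


# ---------------------------------------------------------------------------
# consensus across lines
# ---------------------------------------------------------------------------


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def consensus_regions(
    blocks_per_line: Sequence[Sequence[RegionCall]],
    genes: Sequence[GeneModel] = (),
) -> tuple[list[RegionCall], int]:
    """Intervals retained in every line, with overlapping genes.

    Returns the consensus calls and the total gene count across them.
    Associative and order-independent in the line arguments.
    """
    if len(blocks_per_line) < 2:
        raise GenomeIOError("consensus requires blocks from at least 2 lines")
    groups = sorted({b.group_id for blocks in blocks_per_line for b in blocks})
    consensus: list[RegionCall] = []
    total_genes = 0
    for gid in groups:
        per_line = [
            _merge([(b.start, b.end) for b in blocks if b.group_id == gid])
            for blocks in blocks_per_line
        ]
        inter = per_line[0]
        for ivs in per_line[1:]:
            inter = _intersect(inter, ivs)
            if not inter:
                break
        for s, e in inter:
            members = tuple(
                g.gene_id
                for g in sorted(genes, key=lambda g: (g.group_id, g.start))
                if g.group_id == gid and g.start <= e and g.end >= s
            )
            total_genes += len(members)
            consensus.append(
                RegionCall(
                    group_id=gid,
                    start=s,
                    end=e,
                    statistic="donor_block",
                    member_genes=members,
                    n_qualifying=len(members),
                    support=tuple([True] * len(blocks_per_line)),
                )
            )
    return consensus, total_genes
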