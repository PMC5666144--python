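"""Region detection: nonsyn clusters, donor blocks, consensus intervals."""

import numpy as np
import pytest

import tricross as tc
from tricross.genome_io import DONOR, GeneModel, GenomeMap, LinkageGroup, MISSING
from tricross.region_scan import (
    RegionCall,
    consensus_regions,
    detect_donor_blocks,
    scan_nonsyn_regions,
)
from tricross.snp_effects import GeneEffectCounts


def genes_with_counts(nonsyn_counts, group="lg1", gene_len=100, gap=10):
    genes, counts = [], []
    pos = 1
    for i, n in enumerate(nonsyn_counts):
        g = GeneModel(f"g{i+1}", group, pos, pos + gene_len - 1, "+")
        genes.append(g)
        counts.append(GeneEffectCounts(g.gene_id, n, 0, n, 0))
        pos += gene_len + gap
    return genes, counts


def brute_force_regions(nonsyn_counts, min_genes, min_snps, max_gap):
    """Oracle: enumerate all index windows, keep maximal valid runs.

    A window [i..j] is valid iff its ends qualify, it has >= min_genes
    qualifying members and no gap of consecutive non-qualifying members
    exceeds max_gap.  Maximal = not contained in a longer valid window.
    """
    qual = [c >= min_snps for c in nonsyn_counts]
    n = len(qual)
    valid = []
    for i in range(n):
        for j in range(i, n):
            if not (qual[i] and qual[j]):
                continue
            run = qual[i : j + 1]
            gap, max_run_gap = 0, 0
            for q in run:
                gap = 0 if q else gap + 1
                max_run_gap = max(max_run_gap, gap)
            if sum(run) >= min_genes and max_run_gap <= max_gap:
                valid.append((i, j))
    return [w for w in valid
            if not any(v != w and v[0] <= w[0] and w[1] <= v[1] for v in valid)]


class TestScanNonsynRegions:
    def test_five_consecutive_high_genes_form_one_region(self):
        genes, counts = genes_with_counts([12, 15, 11, 20, 13])
        (region,) = scan_nonsyn_regions(counts, genes)
        assert region.member_genes == ("g1", "g2", "g3", "g4", "g5")
        assert region.n_qualifying == 5
        assert region.span == (genes[0].start, genes[-1].end)

    @pytest.mark.parametrize(
        "counts,gap,expected_n",
        [([12, 15, 3, 11, 20, 13], 0, 0), ([12, 15, 3, 11, 20, 13], 1, 1)],
    )
    def test_gap_allowance_matches_brute_force(self, counts, gap, expected_n):
        genes, ctab = genes_with_counts(counts)
        regions = scan_nonsyn_regions(ctab, genes, max_gap_genes=gap)
        oracle = brute_force_regions(counts, 5, 10, gap)
        assert len(regions) == expected_n == len(oracle)
        for r, (i, j) in zip(regions, oracle):
            assert r.member_genes == tuple(f"g{k+1}" for k in range(i, j + 1))

    def test_random_profiles_match_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            counts = rng.choice([0, 3, 11, 15], size=20).tolist()
            gap = int(rng.integers(0, 3))
            genes, ctab = genes_with_counts(counts)
            got = [
                tuple(int(m[1:]) - 1 for m in (r.member_genes[0], r.member_genes[-1]))
                for r in scan_nonsyn_regions(ctab, genes, min_genes=3, max_gap_genes=gap)
            ]
            assert got == brute_force_regions(counts, 3, 10, gap)

    def test_all_below_threshold_yields_empty(self):
        genes, counts = genes_with_counts([1, 2, 9, 0, 5, 9])
        assert scan_nonsyn_regions(counts, genes) == []

    def test_unsorted_input_errors(self):
        genes, counts = genes_with_counts([12, 12, 12, 12, 12])
        with pytest.raises(Exception, match="sorted"):
            scan_nonsyn_regions(counts, genes[::-1])

    def test_reversal_invariance_of_called_intervals(self):
        """Mirroring gene order along a group calls the same intervals."""
        rng = np.random.default_rng(32)
        counts = rng.choice([0, 12, 15], size=30).tolist()
        genes, ctab = genes_with_counts(counts)
        fwd = scan_nonsyn_regions(ctab, genes, min_genes=3, max_gap_genes=1)
        # mirror: same geometry, reversed count profile
        genes_r, ctab_r = genes_with_counts(counts[::-1])
        rev = scan_nonsyn_regions(ctab_r, genes_r, min_genes=3, max_gap_genes=1)
        total = len(counts) + 1
        mirrored = sorted(
            (total - int(r.member_genes[-1][1:]), total - int(r.member_genes[0][1:]))
            for r in rev
        )
        assert sorted(
            (int(r.member_genes[0][1:]), int(r.member_genes[-1][1:])) for r in fwd
        ) == mirrored

    def test_cumulative_mode_flags_dense_windows(self):
        genes, ctab = genes_with_counts([4, 4, 4, 0, 0, 0, 0, 0])
        regions = scan_nonsyn_regions(
            ctab, genes, min_genes=3, min_snps_per_gene=10, cumulative=True
        )
        (r,) = regions
        assert r.member_genes == ("g1", "g2", "g3")


def marker_map(n_markers=1000, phys=1_000_000):
    return GenomeMap(
        [LinkageGroup("lg1", phys, 1.0)],
        {"lg1": np.linspace(1, phys, n_markers).round().astype(int)},
    )


class TestDetectDonorBlocks:
    def test_all_recurrent_line_has_no_blocks(self):
        gmap = marker_map()
        assert detect_donor_blocks(np.zeros(1000, dtype=np.int8), gmap) == []

    def test_all_donor_line_is_one_block_per_group(self):
        gmap = marker_map()
        (block,) = detect_donor_blocks(np.ones(1000, dtype=np.int8), gmap)
        assert block.start == int(gmap.markers["lg1"][0])
        assert block.end == int(gmap.markers["lg1"][-1])

    def test_planted_block_recovered_within_one_window(self):
        """A planted 60-marker donor block in a 1,000-marker group is
        called with boundaries within one window of the truth."""
        gmap = marker_map()
        calls = np.zeros(1000, dtype=np.int8)
        calls[400:460] = DONOR
        window = 25
        (block,) = detect_donor_blocks(calls, gmap, window_markers=window)
        pos = gmap.markers["lg1"]
        true_start, true_end = int(pos[400]), int(pos[459])
        spacing = float(np.diff(pos).mean())
        assert abs(block.start - true_start) <= window * spacing
        assert abs(block.end - true_end) <= window * spacing

    def test_missing_calls_excluded_from_denominator(self):
        gmap = marker_map(100, 100_000)
        calls = np.zeros(100, dtype=np.int8)
        calls[40:60] = DONOR
        calls[45:50] = MISSING  # missing inside the block must not break it
        blocks = detect_donor_blocks(calls, gmap, window_markers=10)
        assert len(blocks) == 1

    def test_window_larger_than_group_scans_single_window(self):
        gmap = marker_map(20, 10_000)
        calls = np.ones(20, dtype=np.int8)
        with pytest.warns(UserWarning, match="single window"):
            (block,) = detect_donor_blocks(calls, gmap, window_markers=50)
        assert block.start == int(gmap.markers["lg1"][0])

    def test_simulator_truth_blocks_recovered(self, small_cfg, small_map):
        """Detection recovers >= 95% of true donor blocks spanning at
        least 2x the window, with boundaries within one window."""
        rng = np.random.default_rng(33)
        window = 10
        found = total = 0
        for _ in range(40):
            hap, truth = tc.run_backcross_line(small_cfg, rng, small_map)
            blocks = detect_donor_blocks(hap.origin, small_map, window_markers=window)
            for g in small_map.groups:
                pos = small_map.markers[g.id]
                for s, e in truth.donor_intervals[g.id]:
                    n_markers = int(((pos >= s) & (pos <= e)).sum())
                    if n_markers < 2 * window:
                        continue
                    total += 1
                    if any(b.group_id == g.id and b.start <= e and b.end >= s
                           for b in blocks):
                        found += 1
        assert total > 20
        assert found / total >= 0.95


class TestConsensusRegions:
    def test_identical_blocks_intersect_to_themselves(self):
        b = [RegionCall("lg1", 100, 200, "donor_block")]
        genes = [GeneModel("g1", "lg1", 150, 180, "+")]
        cons, n = consensus_regions([b, b, b], genes)
        assert [(c.start, c.end) for c in cons] == [(100, 200)]
        assert n == 1 and cons[0].member_genes == ("g1",)

    def test_staggered_blocks_intersect(self):
        lines = [
            [RegionCall("lg1", 100_000, 200_000, "donor_block")],
            [RegionCall("lg1", 150_000, 250_000, "donor_block")],
            [RegionCall("lg1", 180_000, 300_000, "donor_block")],
        ]
        cons, _ = consensus_regions(lines, ())
        assert [(c.start, c.end) for c in cons] == [(180_000, 200_000)]

    def test_disjoint_blocks_give_empty_consensus(self):
        lines = [
            [RegionCall("lg1", 100, 200, "donor_block")],
            [RegionCall("lg1", 300, 400, "donor_block")],
        ]
        cons, n = consensus_regions(lines, ())
        assert cons == [] and n == 0

    def test_associative_and_order_independent(self):
        rng = np.random.default_rng(34)
        def random_blocks():
            out = []
            for _ in range(rng.integers(1, 5)):
                s = int(rng.integers(1, 900))
                out.append(RegionCall("lg1", s, s + int(rng.integers(10, 200)),
                                      "donor_block"))
            return out
        lines = [random_blocks() for _ in range(4)]
        base, _ = consensus_regions(lines, ())
        perm, _ = consensus_regions(lines[::-1], ())
        assert [(c.start, c.end) for c in base] == [(c.start, c.end) for c in perm]
        # associativity: consensus(consensus(l1,l2) x l3...) == consensus(all)
        step12, _ = consensus_regions(lines[:2], ())
        nested, _ = consensus_regions([step12, *[l for l in lines[2:]]], ())
        assert [(c.start, c.end) for c in nested] == [(c.start, c.end) for c in base]

    def test_fewer_than_two_lines_errors(self):
        with pytest.raises(Exception, match="2 lines"):
            consensus_regions([[RegionCall("lg1", 1, 2, "donor_block")]], ())

    def test_truth_consensus_always_contains_fs(self, small_cfg, small_map):
        """Selection keeps the donor FS allele in every line, so the
        intersection of true donor intervals always contains FS."""
        rng = np.random.default_rng(35)
        fs_g, fs_p = small_map.selected_loci["FS"]
        for _ in range(10):
            lines = []
            for _ in range(3):
                _, truth = tc.run_backcross_line(small_cfg, rng, small_map)
                lines.append([
                    RegionCall(g, s, e, "donor_block")
                    for g, ivs in truth.donor_intervals.items() for s, e in ivs
                ])
            cons, _ = consensus_regions(lines, ())
            assert any(c.group_id == fs_g and c.start <= fs_p <= c.end for c in cons)
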