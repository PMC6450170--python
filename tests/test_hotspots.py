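import math

import numpy as np
import pytest

from targettriage import hotspots, synthetic_data
from targettriage.errors import DomainError
from targettriage.io import GeneLocus

from oracles import hypergeom_tail_comb, hypergeom_tail_enumerate


def layout_from_flags(flags, chromosome="chr1"):
    """Build a one-chromosome layout from a DEG indicator list."""
    loci = [GeneLocus(chromosome, i * 100, i * 100 + 50, f"G{i:03d}")
            for i in range(len(flags))]
    deg_set = {f"G{i:03d}" for i, f in enumerate(flags) if f}
    return hotspots.build_layout(loci, deg_set)


class TestWindowPvalue:
    def test_k_zero_is_one(self):
        assert hotspots.window_pvalue(4, 0, 5, 10) == 1.0

    def test_enumerated_example(self):
        assert hotspots.window_pvalue(4, 4, 5, 10) == pytest.approx(5 / 210, abs=1e-12)

    def test_single_term_tail(self):
        assert hotspots.window_pvalue(6, 6, 6, 40) == pytest.approx(
            1 / math.comb(40, 6), rel=1e-12)

    def test_bounds_rejected(self):
        with pytest.raises(DomainError):
            hotspots.window_pvalue(4, 5, 5, 10)
        with pytest.raises(DomainError):
            hotspots.window_pvalue(11, 2, 5, 10)

    def test_agrees_with_comb_oracle_to_1e12(self):
        for G in (10, 14, 20, 25):
            for K in (2, G // 3, G // 2):
                for w in range(1, G + 1):
                    for k in range(0, min(w, K) + 1):
                        assert hotspots.window_pvalue(w, k, K, G) == pytest.approx(
                            hypergeom_tail_comb(k, G, K, w), abs=1e-12)

    def test_comb_oracle_agrees_with_enumeration(self):
        # validates the closed-form oracle itself by brute subset counting
        for (G, K, w) in [(8, 3, 4), (10, 5, 4), (12, 4, 6)]:
            for k in range(0, min(w, K) + 1):
                assert hypergeom_tail_comb(k, G, K, w) == pytest.approx(
                    hypergeom_tail_enumerate(k, G, K, w), abs=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        ps = [hotspots.window_pvalue(8, k, 10, 30) for k in range(9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def brute_force_hotspot_intervals(flags, G, K, min_degs, p_max):
    """Independent O(G^2) scan: test every window, trim to DEG
    endpoints, merge overlapping or book-ended significant intervals."""
    n = len(flags)
    deg_idx = [i for i, f in enumerate(flags) if f]
    significant = []
    for i in range(n):
        for j in range(i, n):
            inside = [d for d in deg_idx if i <= d <= j]
            if len(inside) < min_degs:
                continue
            lo, hi = inside[0], inside[-1]
            w, k = hi - lo + 1, len(inside)
            if hypergeom_tail_comb(k, G, K, w) <= p_max:
                significant.append((lo, hi))
    merged = []
    for lo, hi in sorted(set(significant)):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


class TestScan:
    def test_no_degs_no_hotspots(self):
        layout = layout_from_flags([False] * 20)
        assert hotspots.scan_hotspots(layout) == []

    def test_toy_single_cluster(self):
        flags = [5 <= i <= 10 for i in range(20)]
        layout = layout_from_flags(flags)
        (spot,) = hotspots.scan_hotspots(layout, min_degs=5, p_max=0.001)
        assert spot.k == 6 and spot.w == 6
        assert spot.p == pytest.approx(1 / math.comb(20, 6), rel=1e-12)
        assert spot.genes == [f"G{i:03d}" for i in range(5, 11)]
        assert spot.deg_genes == set(spot.genes)

    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(15, 40))
            flags = (rng.random(n) < 0.3).tolist()
            layout = layout_from_flags(flags)
            spots = hotspots.scan_hotspots(layout, min_degs=3, p_max=0.05)
            got = [(int(s.span[0] // 100), int(s.span[1] // 100)) for s in spots]
            expected = brute_force_hotspot_intervals(
                flags, layout.G, layout.K, min_degs=3, p_max=0.05)
            assert got == [(lo, hi) for lo, hi in expected]

    def test_post_hoc_invariants(self):
        matrixless_degs = {f"G{i:04d}" for i in np.random.default_rng(3).choice(500, 60, replace=False)}
        loci, _ = synthetic_data.simulate_genome_map(500, 3, [], matrixless_degs, seed=3)
        layout = hotspots.build_layout(loci, matrixless_degs)
        for spot in hotspots.scan_hotspots(layout, min_degs=3, p_max=0.05):
            assert spot.k >= 3
            assert spot.p <= 0.05
            assert spot.deg_genes <= set(spot.genes)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(8)
        degs = {f"G{i:04d}" for i in rng.choice(300, 40, replace=False)}
        loci, _ = synthetic_data.simulate_genome_map(300, 2, [], degs, seed=8)
        shuffled = [loci[i] for i in rng.permutation(len(loci))]
        a = hotspots.scan_hotspots(hotspots.build_layout(loci, degs), 3, 0.05)
        b = hotspots.scan_hotspots(hotspots.build_layout(shuffled, degs), 3, 0.05)
        assert [(s.chromosome, s.span, s.p) for s in a] == \
               [(s.chromosome, s.span, s.p) for s in b]

    def test_unmapped_degs_reported(self):
        layout = layout_from_flags([True] * 3 + [False] * 5)
        loci = [GeneLocus("chr1", i * 100, i * 100 + 50, f"G{i:03d}") for i in range(8)]
        built = hotspots.build_layout(loci, {"G000", "G001", "NOT_ON_MAP"})
        assert built.unmapped_degs == {"NOT_ON_MAP"}
        assert built.K == 2
        assert layout.G == 8

    def test_planted_cluster_recovery_sample(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            genes = synthetic_data.default_gene_names(2000)
            deg_set = {genes[i] for i in rng.choice(2000, 200, replace=False)}
            loci, truth = synthetic_data.simulate_genome_map(
                2000, 5, [synthetic_data.ClusterSpec("chr2", 100, 8, 6)],
                deg_set, seed=seed, genes=genes)
            layout = hotspots.build_layout(loci, deg_set)
            spots = hotspots.scan_hotspots(layout, min_degs=5, p_max=0.001)
            planted = set(truth.clusters[0]["deg_genes"])
            if any(planted <= s.deg_genes for s in spots):
                hits += 1
        assert hits / n_seeds >= 0.95


class TestOverlap:
    def make_spot(self, chrom, start, end, degs):
        return hotspots.HotSpot(chromosome=chrom, span=(start, end),
                                genes=sorted(degs), deg_genes=set(degs),
                                w=len(degs), k=len(degs), p=1e-4)

    def test_half_open_boundary(self):
        a = self.make_spot("chr1", 100, 200, {"A"})
        b = self.make_spot("chr1", 200, 300, {"A"})
        assert hotspots.overlap_hotspots([a], [b]) == []

    def test_enumerable_overlap(self):
        a = self.make_spot("chr1", 100, 250, {"A", "B", "C"})
        b = self.make_spot("chr1", 200, 300, {"B", "C", "D"})
        ((ha, hb, shared),) = hotspots.overlap_hotspots([a], [b])
        assert (ha, hb) == (a, b)
        assert shared == {"B", "C"}

    def test_different_chromosomes_never_overlap(self):
        a = self.make_spot("chr1", 100, 250, {"A"})
        b = self.make_spot("chr2", 100, 250, {"A"})
        assert hotspots.overlap_hotspots([a], [b]) == []

    def test_planted_co_cluster_recovered(self):
        genes = synthetic_data.default_gene_names(600)
        rng = np.random.default_rng(4)
        shared = {genes[i] for i in rng.choice(600, 6, replace=False)}
        loci, truth = synthetic_data.simulate_genome_map(
            600, 3, [synthetic_data.ClusterSpec("chr1", 40, 8, 6)],
            shared, seed=4, genes=genes)
        layout_a = hotspots.build_layout(loci, shared)
        layout_b = hotspots.build_layout(loci, shared)
        spots_a = hotspots.scan_hotspots(layout_a, min_degs=5, p_max=0.001)
        spots_b = hotspots.scan_hotspots(layout_b, min_degs=5, p_max=0.001)
        pairs = hotspots.overlap_hotspots(spots_a, spots_b)
        assert len(pairs) == 1
        assert pairs[0][2] == set(truth.clusters[0]["deg_genes"])


def test_hotspot_tsv_round_trip(tmp_path):
    spot = hotspots.HotSpot("chr1", (0, 500), ["A", "B"], {"A", "B"}, 6, 5, 1e-4)
    hotspots.write_hotspots([spot], tmp_path / "h.tsv")
    (back,) = hotspots.read_hotspots(tmp_path / "h.tsv")
    assert (back.chromosome, back.span, back.w, back.k) == ("chr1", (0, 500), 6, 5)
    assert back.deg_genes == {"A", "B"}
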