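"""Multi-individual clustering against the brute-force window/closure
oracle, and the pairwise detector against the all-pairs maximal-run
oracle."""

import numpy as np
import pandas as pd
import pytest

from ibdscan.clustering import (ARRAY_PRESET, ClusteringParams,
                                PairwiseDetectorParams, cluster_at_position,
                                cluster_field_scan, detect_pairwise_segments)
from ibdscan.ibd_io import ClusterField, GeneticMap, PhasedHaplotypes

from conftest import random_haplotypes
from oracles import brute_force_clusters, brute_force_segments


def make_haps(rows, positions_bp, length_cM=10.0, chrom="1"):
    H = np.asarray(rows, dtype=np.int8)
    haps = PhasedHaplotypes(
        samples=[f"S{i}" for i in range(H.shape[0] // 2)],
        variants=pd.DataFrame({"chrom": chrom, "pos": positions_bp,
                               "ref": "A", "alt": "C"}),
        haplotypes=H)
    return haps, GeneticMap.uniform({chrom: length_cM})


class TestClusteringParams:
    def test_trim_capped_at_half_length(self):
        with pytest.raises(ValueError):
            ClusteringParams(length_cM=2.0, trim_cM=1.01)
        ClusteringParams(length_cM=2.0, trim_cM=1.0)  # boundary admissible

    def test_positive(self):
        with pytest.raises(ValueError):
            ClusteringParams(length_cM=-1.0, trim_cM=0.1)


class TestClusterAtPosition:
    def test_identical_haplotypes_one_cluster(self):
        pos = np.arange(1, 10_000_001, 250_000)
        haps, gmap = make_haps(np.ones((8, len(pos))), pos)
        for focal in (0.5, 5.0, 9.5):
            field = cluster_at_position(haps, gmap,
                                        ClusteringParams(2.0, 0.5), focal)
            assert len(np.unique(field.labels)) == 1

    def test_all_distinct_haplotypes_singletons(self):
        pos = np.arange(1, 10_000_001, 500_000)
        rows = np.arange(6)[:, None] % 2 * 0 + np.arange(6)[:, None]
        H = (np.arange(6)[:, None] >> np.arange(len(pos))[None, :]) & 1
        # make every pair differ densely: use distinct constant patterns
        H = np.tile(np.eye(6, dtype=np.int8), (1, len(pos) // 6 + 1))[:, :len(pos)]
        haps, gmap = make_haps(H, pos)
        field = cluster_at_position(haps, gmap, ClusteringParams(2.0, 0.5), 5.0)
        assert len(np.unique(field.labels)) == 6

    def test_transitive_merging(self):
        # A==B on [0,3] cM, B==C on [2,5] cM; focal 2.5 with L=2, T=0.5
        # merges all three even though A and C share no qualifying window
        pos = np.arange(1, 10_000_001, 100_000)
        cm = (pos - 1) / 1e6
        A = np.zeros(len(pos), dtype=np.int8)
        B = np.zeros(len(pos), dtype=np.int8)
        C = np.zeros(len(pos), dtype=np.int8)
        A[cm > 3.0] = 1          # differs from B after 3 cM
        C[cm < 2.0] = 1          # differs from B before 2 cM
        D = 1 - np.zeros(len(pos), dtype=np.int8)  # unrelated filler
        haps, gmap = make_haps([A, B, C, D], pos)
        field = cluster_at_position(haps, gmap, ClusteringParams(2.0, 0.5), 2.5)
        labs = field.labels
        assert labs[0] == labs[1] == labs[2]
        assert labs[3] != labs[0]
        oracle = brute_force_clusters(haps, gmap, 2.5, 2.0, 0.5)
        assert ClusterField("1", 1, 2.5, labs) == ClusterField("1", 1, 2.5, oracle)

    def test_focal_outside_chromosome_raises(self, mosaic_haps):
        haps, gmap = mosaic_haps
        with pytest.raises(ValueError):
            cluster_at_position(haps, gmap, ClusteringParams(2.0, 0.5), 11.0)

    @pytest.mark.parametrize("L,T", [(2.0, 0.25), (2.0, 0.5), (2.0, 0.9),
                                     (3.0, 0.25), (3.0, 0.5), (3.0, 1.0)])
    def test_matches_brute_force_oracle(self, L, T):
        haps, gmap = random_haplotypes(30, 600, length_cM=10.0, seed=7)
        for focal in (0.15, 2.5, 5.0, 7.77, 9.9):
            field = cluster_at_position(haps, gmap, ClusteringParams(L, T),
                                        focal)
            oracle = brute_force_clusters(haps, gmap, focal, L, T)
            assert field.same_partition(
                ClusterField("1", 1, focal, oracle)), (L, T, focal)

    def test_monotone_in_thresholds(self):
        """Raising L or T only refines the partition (never merges)."""
        haps, gmap = random_haplotypes(24, 500, length_cM=10.0, seed=9)
        focal = 5.0
        def partition(L, T):
            return cluster_at_position(haps, gmap, ClusteringParams(L, T),
                                       focal).canonical()
        base = partition(2.0, 0.25)
        for L, T in [(3.0, 0.25), (2.0, 0.5), (3.0, 1.0)]:
            finer = partition(L, T)
            # each finer cluster must lie inside one base cluster
            for lab in np.unique(finer):
                members = np.nonzero(finer == lab)[0]
                assert len(np.unique(base[members])) == 1


class TestScan:
    def test_grid_count(self, mosaic_haps):
        haps, gmap = mosaic_haps
        fields = cluster_field_scan(haps, gmap, ClusteringParams(2.0, 0.5), 0.1)
        assert len(fields) == 101

    def test_spacing_larger_than_chromosome(self, mosaic_haps):
        haps, gmap = mosaic_haps
        fields = cluster_field_scan(haps, gmap, ClusteringParams(2.0, 0.5), 50.0)
        assert len(fields) == 1
        assert fields[0].position_cM == pytest.approx(0.0)

    def test_scan_consistent_with_single_position(self):
        haps, gmap = random_haplotypes(20, 400, length_cM=10.0, seed=5)
        params = ClusteringParams(2.0, 0.5)
        fields = cluster_field_scan(haps, gmap, params, 1.0)
        for f in fields:
            single = cluster_at_position(haps, gmap, params, f.position_cM)
            assert f.same_partition(single)


class TestPairwiseDetector:
    def test_single_long_run(self):
        # two haplotypes identical on cM [1, 6] of a 10 cM chromosome
        pos = np.arange(1, 10_000_001, 50_000)
        cm = (pos - 1) / 1e6
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, len(pos)).astype(np.int8)
        b = rng.integers(0, 2, len(pos)).astype(np.int8)
        share = (cm >= 1.0) & (cm <= 6.0)
        b[share] = a[share]
        b[~share] = 1 - a[~share]   # force mismatch outside the run
        c = 1 - a                   # filler to keep sites polymorphic
        d = rng.integers(0, 2, len(pos)).astype(np.int8)
        haps, gmap = make_haps([a, b, c, d], pos)
        params = PairwiseDetectorParams(min_seed_cM=0.5, min_extend_cM=0.2,
                                        min_output_cM=2.0,
                                        min_minor_allele_count=1)
        segs = detect_pairwise_segments(haps, gmap, params)
        ours = segs[(segs.sample1 == "S0") & (segs.sample2 == "S0")]
        assert len(ours) == 1
        assert ours["length_cM"].iloc[0] == pytest.approx(5.0, abs=0.1)

    def test_short_run_rejected(self):
        pos = np.arange(1, 10_000_001, 50_000)
        cm = (pos - 1) / 1e6
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, len(pos)).astype(np.int8)
        b = 1 - a
        share = (cm >= 4.0) & (cm <= 5.5)   # only 1.5 cM
        b[share] = a[share]
        haps, gmap = make_haps([a, b, a.copy(), 1 - b], pos)
        params = PairwiseDetectorParams(min_seed_cM=0.5, min_extend_cM=0.2,
                                        min_output_cM=2.0,
                                        min_minor_allele_count=1)
        segs = detect_pairwise_segments(haps, gmap, params)
        mask = ((segs.sample1 == "S0") & (segs.hap1 == 1)
                & (segs.sample2 == "S0") & (segs.hap2 == 2))
        assert not mask.any()

    def test_matches_all_pairs_oracle(self):
        haps, gmap = random_haplotypes(20, 500, length_cM=10.0, seed=13)
        params = PairwiseDetectorParams(min_seed_cM=0.5, min_extend_cM=0.2,
                                        min_output_cM=2.0,
                                        min_minor_allele_count=2)
        segs = detect_pairwise_segments(haps, gmap, params)
        got = {(2 * (s.sample1 == np.array(haps.samples)).argmax() + s.hap1 - 1,
                2 * (s.sample2 == np.array(haps.samples)).argmax() + s.hap2 - 1,
                s.start_bp, s.end_bp)
               for s in segs.itertuples(index=False)}
        expected = brute_force_segments(haps, gmap, 2.0, min_mac=2)
        assert got == expected

    def test_array_preset_min_markers(self):
        assert ARRAY_PRESET.min_seed_markers == 50
        assert ARRAY_PRESET.min_output_cM == 3.0
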