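"""Scan drivers, the two-step procedure, the single-variant comparator,
and the experiment harnesses at smoke scale."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import t as t_dist

from ibdscan.clustering import ClusteringParams
from ibdscan.ibd_io import GeneticMap, PhasedHaplotypes
from ibdscan.scan import (DataBundle, ExperimentConfig, ScanConfig,
                          genome_scan, prepare_study, single_variant_comparator,
                          two_step_scan, type1_experiment)
from ibdscan.simdata import SimConfig, simulate_phenotypes


@pytest.fixture(scope="module")
def small_study():
    cfg = ExperimentConfig(
        sim=SimConfig(n_individuals=60, n_chromosomes=2,
                      chromosome_length_cM=8.0, demography="uk-scaled",
                      seed=77),
        clustering=ClusteringParams(2.0, 0.25),
        spacing_cM=0.2, n_alpha_replicates=4, ou_replicates=500, seed=77)
    return cfg, prepare_study(cfg)


@pytest.fixture(scope="module")
def null_bundle(small_study):
    _, study = small_study
    y = simulate_phenotypes(study.psi, None, 1, seed=5)[0]
    return study.bundle(y)


class TestGenomeScan:
    def test_grid_row_count(self, null_bundle):
        df = genome_scan(null_bundle, ScanConfig(spacing_cM=0.2))
        assert len(df) == 2 * 41
        assert df["converged"].all()
        assert (df["W"] >= 0).all()

    def test_sample_permutation_invariance(self, small_study, null_bundle):
        """Relabeling samples consistently in every input leaves all W
        unchanged."""
        _, study = small_study
        rng = np.random.default_rng(0)
        n = study.haps.n_samples
        perm = rng.permutation(n)
        hap_perm = np.empty(2 * n, dtype=int)
        hap_perm[0::2] = 2 * perm
        hap_perm[1::2] = 2 * perm + 1
        from ibdscan.ibd_io import ClusterField
        fields_p = [ClusterField(f.chrom, f.position_bp, f.position_cM,
                                 f.labels[hap_perm]) for f in study.fields]
        psi_p = study.psi[perm][:, perm]
        bundle_p = DataBundle(
            samples=[study.haps.samples[i] for i in perm],
            y=null_bundle.y[perm], psi=psi_p.tocsr(), fields=fields_p,
            gmap=study.gmap)
        cfg = ScanConfig(spacing_cM=0.4)
        base = genome_scan(null_bundle, cfg)
        permuted = genome_scan(bundle_p, cfg)
        np.testing.assert_allclose(permuted["W"].to_numpy(),
                                   base["W"].to_numpy(), atol=1e-5)

    def test_mismatched_bundle_rejected(self, small_study):
        _, study = small_study
        with pytest.raises(ValueError, match="trait"):
            DataBundle(samples=study.haps.samples, y=np.zeros(3),
                       psi=study.psi, fields=study.fields, gmap=study.gmap)


class TestTwoStepScan:
    def test_signal_found_by_both(self, small_study):
        """A strong local effect simulated on a cluster field is flagged
        by the full scan and the two-step scan at the same position."""
        _, study = small_study
        rng = np.random.default_rng(9)
        target = study.fields[len(study.fields) // 3]
        from ibdscan.relatedness import phi_from_field
        phi = phi_from_field(target, study.haps.n_samples)
        L = np.linalg.cholesky(phi.toarray() + 1e-9 * np.eye(phi.shape[0]))
        y = 2.0 * L @ rng.standard_normal(phi.shape[0]) \
            + rng.standard_normal(phi.shape[0])
        bundle = study.bundle(y)
        cfg = ScanConfig(spacing_cM=0.2, top_k=3)
        full = genome_scan(bundle, cfg)
        two = two_step_scan(bundle, cfg)
        best_full = full.loc[full["p"].idxmin()]
        fine = two[two["stage"] == "fine"]
        assert fine["p"].min() <= best_full["p"] * 1.001

    def test_small_chromosome_all_coarse_points_zoomed(self, small_study):
        _, study = small_study
        y = simulate_phenotypes(study.psi, None, 1, seed=6)[0]
        cfg = ScanConfig(spacing_cM=0.2, coarse_spacing_cM=1.0, top_k=50)
        two = two_step_scan(study.bundle(y), cfg)
        fine = two[two["stage"] == "fine"]
        # zoom windows cover each chromosome entirely when K exceeds the
        # number of coarse points
        for chrom in ("1", "2"):
            pts = fine[fine["chrom"] == chrom]["position_cM"]
            assert pts.min() == pytest.approx(0.0)
            assert pts.max() == pytest.approx(8.0)


class TestSingleVariantComparator:
    def make_tiny(self):
        # 6 individuals, 2 markers with hand-checkable dosages
        H = np.array([
            [1, 0], [0, 0],
            [1, 1], [1, 0],
            [0, 0], [0, 0],
            [1, 0], [1, 1],
            [0, 1], [0, 0],
            [1, 0], [0, 0]], dtype=np.int8)
        haps = PhasedHaplotypes(
            samples=[f"I{i}" for i in range(6)],
            variants=pd.DataFrame({"chrom": "1", "pos": [1000, 2000],
                                   "ref": "A", "alt": "C"}),
            haplotypes=H)
        return haps, GeneticMap.uniform({"1": 1.0})

    def test_textbook_regression_p(self):
        haps, gmap = self.make_tiny()
        rng = np.random.default_rng(1)
        y = rng.standard_normal(6)
        res = single_variant_comparator(haps, y, ("1", 0.0, 1.0), gmap)
        # hand computation at each marker, min over the two
        ps = []
        for mi in range(2):
            d = haps.dosage(np.array([mi])).astype(float).ravel()
            d = d if d.mean() <= 1 else 2 - d
            r = np.corrcoef(y, d)[0, 1]
            t = r * np.sqrt(4 / (1 - r ** 2))
            ps.append(2 * t_dist.sf(abs(t), 4))
        assert res["min_p"] == pytest.approx(min(ps), abs=1e-10)

    def test_construction_signal_attains_min(self):
        haps, gmap = self.make_tiny()
        d = haps.dosage(np.array([0])).astype(float).ravel()
        y = 2.0 * d + 0.01 * np.random.default_rng(2).standard_normal(6)
        res = single_variant_comparator(haps, y, ("1", 0.0, 1.0), gmap)
        assert res["best_cM"] == pytest.approx(
            gmap.interpolate("1", 1000), abs=1e-6)

    def test_null_min_p_order_statistic(self):
        """With m independent-ish null markers the min p behaves like the
        first order statistic: its median is well below 0.5 and above
        the Bonferroni-adjusted point."""
        rng = np.random.default_rng(3)
        n, m = 80, 20
        H = rng.integers(0, 2, size=(2 * n, m)).astype(np.int8)
        haps = PhasedHaplotypes(
            samples=[f"I{i}" for i in range(n)],
            variants=pd.DataFrame({"chrom": "1",
                                   "pos": np.arange(1, m + 1) * 1000,
                                   "ref": "A", "alt": "C"}),
            haplotypes=H)
        gmap = GeneticMap.uniform({"1": 1.0})
        mins = [single_variant_comparator(
            haps, rng.standard_normal(n), ("1", 0.0, 1.0), gmap)["min_p"]
            for _ in range(200)]
        med = np.median(mins)
        # Beta(1, m) median = 1 - 0.5**(1/m)
        expected = 1 - 0.5 ** (1 / m)
        assert 0.3 * expected < med < 3 * expected

    def test_monomorphic_markers_skipped(self):
        haps, gmap = self.make_tiny()
        H = haps.haplotypes.copy()
        H[:, 1] = 0
        haps2 = PhasedHaplotypes(haps.samples, haps.variants, H)
        res = single_variant_comparator(haps2, np.arange(6.0),
                                        ("1", 0.0, 1.0), gmap)
        assert res["n_markers"] == 1 and res["n_skipped"] == 1


class TestExperimentHarness:
    def test_type1_smoke_reproducible_and_ordered(self, small_study):
        cfg, study = small_study
        rep1 = type1_experiment(cfg, n_replicates=6, study=study)
        rep2 = type1_experiment(cfg, n_replicates=6, study=study)
        assert rep1.rates == rep2.rates
        np.testing.assert_array_equal(rep1.details["max_w_per_replicate"],
                                      rep2.details["max_w_per_replicate"])
        # Bonferroni is at least as strict as the OU threshold
        assert rep1.rates["fwer_bonferroni"] <= rep1.rates["fwer_ou"]
        assert rep1.details["p_threshold"] < 0.05
        assert rep1.details["p_threshold"] > rep1.details["bonferroni_p"]

    def test_report_round_trips_to_json(self, small_study, tmp_path):
        cfg, study = small_study
        rep = type1_experiment(cfg, n_replicates=4, study=study)
        out = tmp_path / "report.json"
        rep.to_json(out)
        import json
        data = json.loads(out.read_text())
        assert data["n_replicates"] == 4
        assert set(data["rates"]) == {"fwer_ou", "fwer_bonferroni"}
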