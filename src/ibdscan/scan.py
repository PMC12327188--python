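"""Genome-wide scan drivers and the simulation-study harnesses.

A scan runs the variance-component LOD test on a regular cM grid; each
grid point uses the nearest available cluster field (IBD state changes
slowly along the chromosome, so fields computed at 0.1 cM intervals
serve any nearby test position).  The two-step scan tests a coarse 1 cM
grid first, then zooms into 1 cM windows around the top hits per
chromosome at the fine spacing.

The experiment harnesses reproduce the validation design: family-wise
type I error from null phenotype replicates with the OU-based and
Bonferroni thresholds, and power per MAF class from causal-region
phenotypes, with a single-variant regression comparator on SNP-array
data.  Replicate scans share all position-dependent precomputation
(cluster fields, block structure), so the dominant cost is the REML
optimizations themselves.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import binomtest, t as t_dist

from .clustering import (ClusteringParams, PairwiseDetectorParams,
                         SEQUENCE_PRESET, cluster_at_position,
                         cluster_field_scan, detect_pairwise_segments,
                         grid_positions)
from .ibd_io import ClusterField, GeneticMap, PhasedHaplotypes
from .ou import OUModel, ThresholdResult, estimate_alpha, genome_threshold
from .relatedness import (ensure_psd, global_ibd_matrix, kinship_from_segments,
                          phi_from_field, region_ibd_matrix)
from .simdata import (SimConfig, VARIANT_CLASSES, select_causal_region,
                      simulate_phenotypes, simulate_population, make_snp_array)
from .vc import TWO_LN_TEN, VarianceComponentModel, VCFit

__all__ = [
    "ScanConfig",
    "DataBundle",
    "ExperimentConfig",
    "ExperimentReport",
    "genome_scan",
    "two_step_scan",
    "single_variant_comparator",
    "prepare_study",
    "type1_experiment",
    "power_experiment",
]

logger = logging.getLogger(__name__)

SCAN_COLUMNS = ["chrom", "position_cM", "position_bp", "field_cM", "W", "LOD",
                "p", "sigma_a2", "sigma_q2", "sigma_e2", "converged"]


@dataclass
class ScanConfig:
    """Scan settings: fine grid spacing, two-step parameters, and the
    significance-threshold source ("ou", "bonferroni" or a fixed
    per-test p-value)."""

    spacing_cM: float = 0.1
    two_step: bool = False
    coarse_spacing_cM: float = 1.0
    top_k: int = 10
    zoom_halfwidth_cM: float = 0.5
    threshold: str | float = "ou"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.spacing_cM <= 0 or self.coarse_spacing_cM <= 0:
            raise ValueError("spacings must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class DataBundle:
    """Everything one scan needs, with consistent sample sets."""

    samples: list[str]
    y: np.ndarray
    psi: sp.spmatrix
    fields: list[ClusterField]
    gmap: GeneticMap
    X: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.samples)
        self.y = np.asarray(self.y, dtype=float).ravel()
        problems = []
        if self.y.size != n:
            problems.append(f"trait has {self.y.size} values for {n} samples")
        if self.psi.shape != (n, n):
            problems.append(f"psi is {self.psi.shape}, expected {(n, n)}")
        for f in self.fields:
            if f.n_haplotypes != 2 * n:
                problems.append(
                    f"cluster field at {f.chrom}:{f.position_cM} has "
                    f"{f.n_haplotypes} haplotypes, expected {2 * n}")
                break
        if self.X is not None and np.asarray(self.X).shape[0] != n:
            problems.append("covariate rows do not match samples")
        if problems:
            raise ValueError("inconsistent data bundle: " + "; ".join(problems))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def fields_by_chrom(self) -> dict[str, list[ClusterField]]:
        out: dict[str, list[ClusterField]] = {}
        for f in self.fields:
            out.setdefault(f.chrom, []).append(f)
        for lst in out.values():
            lst.sort(key=lambda f: f.position_cM)
        return out


def _nearest(sorted_vals: np.ndarray, x: float) -> int:
    i = int(np.searchsorted(sorted_vals, x))
    if i == 0:
        return 0
    if i == len(sorted_vals):
        return len(sorted_vals) - 1
    return i if sorted_vals[i] - x < x - sorted_vals[i - 1] else i - 1


class _FieldTester:
    """Caches per-field models and per-trait null fits so repeated tests
    share every expensive precomputation."""

    def __init__(self, bundle: DataBundle, fast: bool = False) -> None:
        self.bundle = bundle
        self.fast = fast
        self._models: dict[int, VarianceComponentModel] = {}
        self._null_model: VarianceComponentModel | None = None
        self._null_fit: VCFit | None = None
        self._results: dict[int, dict] = {}

    def set_trait(self, y: np.ndarray) -> None:
        if self._null_model is None:
            self._null_model = VarianceComponentModel(
                y, self.bundle.psi, None, self.bundle.X)
        else:
            self._null_model = self._null_model.with_endog(y)
        self._null_fit = self._null_model.fit()
        self._results.clear()
        self._y = y

    @property
    def null_fit(self) -> VCFit:
        return self._null_fit

    def test_field(self, field_index: int) -> dict:
        if field_index in self._results:
            return self._results[field_index]
        f = self.bundle.fields[field_index]
        model = self._models.get(field_index)
        if model is None:
            phi = phi_from_field(f, self.bundle.n_samples)
            model = VarianceComponentModel(
                self._y, self.bundle.psi, phi, self.bundle.X,
                chrom=f.chrom, position_cM=f.position_cM,
                position_bp=f.position_bp)
            self._models[field_index] = model
        else:
            model = model.with_endog(self._y)
            self._models[field_index] = model
        res = model.lod_test(null_fit=self._null_fit, fast=self.fast)
        out = {"W": res.W, "p": res.p_value,
               "sigma_a2": res.alt_fit.sigma_a2,
               "sigma_q2": res.alt_fit.sigma_q2,
               "sigma_e2": res.alt_fit.sigma_e2,
               "converged": res.converged,
               "field_cM": f.position_cM}
        self._results[field_index] = out
        return out


def _scan_rows(bundle: DataBundle, tester: _FieldTester,
               positions: dict[str, np.ndarray]) -> pd.DataFrame:
    by_chrom = bundle.fields_by_chrom()
    index_of = {id(f): i for i, f in enumerate(bundle.fields)}
    rows = []
    for chrom, pos_list in positions.items():
        flds = by_chrom.get(chrom)
        if not flds:
            raise ValueError(f"no cluster fields on chromosome {chrom!r}")
        fcms = np.array([f.position_cM for f in flds])
        for pos in pos_list:
            f = flds[_nearest(fcms, pos)]
            res = tester.test_field(index_of[id(f)])
            rows.append({
                "chrom": chrom, "position_cM": float(pos),
                "position_bp": int(round(bundle.gmap.inverse(chrom, pos))),
                "field_cM": res["field_cM"], "W": res["W"],
                "LOD": res["W"] / TWO_LN_TEN, "p": res["p"],
                "sigma_a2": res["sigma_a2"], "sigma_q2": res["sigma_q2"],
                "sigma_e2": res["sigma_e2"], "converged": res["converged"]})
    df = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    return df.sort_values(["chrom", "position_cM"], ignore_index=True)


def genome_scan(bundle: DataBundle, config: ScanConfig | None = None,
                fast: bool = False) -> pd.DataFrame:
    """LOD test at every grid point of every chromosome covered by the
    bundle's cluster fields."""
    config = config or ScanConfig()
    tester = _FieldTester(bundle, fast=fast)
    tester.set_trait(bundle.y)
    positions = {
        chrom: grid_positions(bundle.gmap.span_cM(chrom), config.spacing_cM)
        for chrom in bundle.fields_by_chrom()}
    return _scan_rows(bundle, tester, positions)


def two_step_scan(bundle: DataBundle, config: ScanConfig | None = None) -> pd.DataFrame:
    """Coarse scan, then fine tests in merged windows around the top
    ``top_k`` coarse hits per chromosome (ranked by ascending p)."""
    config = config or ScanConfig(two_step=True)
    tester = _FieldTester(bundle)
    tester.set_trait(bundle.y)
    coarse_pos = {
        chrom: grid_positions(bundle.gmap.span_cM(chrom),
                              config.coarse_spacing_cM)
        for chrom in bundle.fields_by_chrom()}
    coarse = _scan_rows(bundle, tester, coarse_pos)
    coarse["stage"] = "coarse"

    fine_frames = [coarse]
    for chrom, grp in coarse.groupby("chrom"):
        top = grp.nsmallest(config.top_k, "p")
        windows = sorted((p - config.zoom_halfwidth_cM,
                          p + config.zoom_halfwidth_cM)
                         for p in top["position_cM"])
        merged: list[list[float]] = []
        for lo, hi in windows:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        span = bundle.gmap.span_cM(chrom)
        pts: list[float] = []
        for lo, hi in merged:
            lo, hi = max(lo, span[0]), min(hi, span[1])
            n = int(np.floor((hi - lo) / config.spacing_cM + 1e-9)) + 1
            pts.extend(lo + config.spacing_cM * np.arange(n))
        fine = _scan_rows(bundle, tester, {chrom: np.unique(np.round(pts, 9))})
        fine["stage"] = "fine"
        fine_frames.append(fine)
    return pd.concat(fine_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Single-variant comparator
# ---------------------------------------------------------------------------

def single_variant_comparator(haps: PhasedHaplotypes, y: np.ndarray,
                              region: tuple[str, float, float],
                              gmap: GeneticMap,
                              exclude_bp: set | None = None) -> dict:
    """Minimum single-variant p in a region: simple linear regression of
    the trait on minor-allele copy number at every marker, two-sided t
    test on the slope.  Monomorphic markers are skipped; ``exclude_bp``
    drops trait-associated positions (the array never carries causal
    variants)."""
    chrom, start_cM, end_cM = region
    sub = haps.restrict(chrom)
    cm = np.asarray(gmap.interpolate(chrom, sub.variants["pos"].to_numpy()))
    sel = np.nonzero((cm >= start_cM - 1e-9) & (cm <= end_cM + 1e-9))[0]
    if exclude_bp:
        pos_sel = sub.variants["pos"].to_numpy()[sel]
        sel = sel[[p not in exclude_bp for p in pos_sel]]
    if sel.size == 0:
        raise ValueError(f"region {region} contains no markers")
    y = np.asarray(y, dtype=float)
    n = y.size
    D = sub.haplotypes[:, sel].reshape(n, 2, -1).sum(axis=1).astype(float)
    freq = D.mean(axis=0) / 2.0
    D = np.where(freq <= 0.5, D, 2.0 - D)  # minor-allele copy number

    sd = D.std(axis=0)
    poly = sd > 0
    n_skipped = int((~poly).sum())
    if n_skipped:
        logger.info("skipping %d monomorphic markers in %s", n_skipped, region)
    if not poly.any():
        return {"min_p": np.nan, "n_markers": 0, "best_cM": np.nan,
                "n_skipped": n_skipped}
    Dc = D[:, poly] - D[:, poly].mean(axis=0)
    yc = y - y.mean()
    r = (yc @ Dc) / (np.sqrt(yc @ yc) * np.sqrt((Dc * Dc).sum(axis=0)))
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
    pvals = 2.0 * t_dist.sf(np.abs(tstat), n - 2)
    best = int(np.argmin(pvals))
    return {"min_p": float(pvals[best]), "n_markers": int(poly.sum()),
            "best_cM": float(cm[sel[poly][best]]), "n_skipped": n_skipped}


# ---------------------------------------------------------------------------
# Experiment harnesses
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Shared configuration for the simulation-study harnesses."""

    sim: SimConfig = dc_field(default_factory=SimConfig)
    clustering: ClusteringParams = dc_field(default_factory=ClusteringParams)
    detector: PairwiseDetectorParams | None = None
    spacing_cM: float = 0.1
    n_alpha_replicates: int = 10
    ou_replicates: int = 10_000
    level: float = 0.95
    seed: int = 0

    def detector_params(self) -> PairwiseDetectorParams:
        """The sequence hap-ibd preset, with the minor-allele-count
        filter held at the same 1% of haplotypes it represents at full
        scale when the sample is smaller."""
        if self.detector is not None:
            return self.detector
        mac = min(SEQUENCE_PRESET.min_minor_allele_count,
                  max(2, round(0.01 * 2 * self.sim.n_individuals)))
        return PairwiseDetectorParams(
            min_seed_cM=SEQUENCE_PRESET.min_seed_cM,
            min_extend_cM=SEQUENCE_PRESET.min_extend_cM,
            min_output_cM=SEQUENCE_PRESET.min_output_cM,
            min_minor_allele_count=mac,
            min_seed_markers=SEQUENCE_PRESET.min_seed_markers)


@dataclass
class Study:
    """Simulated data plus everything derived from genotypes alone."""

    haps: PhasedHaplotypes
    gmap: GeneticMap
    psi: sp.csr_matrix
    fields: list[ClusterField]
    config: ExperimentConfig

    @property
    def chrom_lengths(self) -> list[float]:
        return [self.gmap.span_cM(c)[1] - self.gmap.span_cM(c)[0]
                for c in self.gmap.chromosomes]

    def bundle(self, y: np.ndarray, X=None) -> DataBundle:
        return DataBundle(samples=self.haps.samples, y=y, psi=self.psi,
                          fields=self.fields, gmap=self.gmap, X=X)


def prepare_study(config: ExperimentConfig) -> Study:
    """Simulate genotypes and build the genotype-derived inputs:
    pairwise segments -> kinship -> Psi, and cluster fields on the test
    grid."""
    t0 = time.time()
    haps, gmap = simulate_population(config.sim)
    logger.info("simulated %d samples x %d markers in %.1fs",
                haps.n_samples, haps.n_markers, time.time() - t0)
    segs = detect_pairwise_segments(haps, gmap, config.detector_params())
    kin = kinship_from_segments(segs, gmap)
    psi = ensure_psd(global_ibd_matrix(kin, haps.samples))
    fields = cluster_field_scan(haps, gmap, config.clustering,
                                config.spacing_cM)
    logger.info("study ready: %d segments, %d kinship pairs, %d fields "
                "(%.1fs)", len(segs), len(kin), len(fields), time.time() - t0)
    return Study(haps=haps, gmap=gmap, psi=psi, fields=fields, config=config)


@dataclass
class ExperimentReport:
    """Per-replicate outcomes, summary rates with binomial CIs, and
    full provenance for exact re-runs."""

    name: str
    n_replicates: int
    rates: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    details: dict
    provenance: dict

    @staticmethod
    def rate_with_ci(hits: int, n: int) -> tuple[float, tuple[float, float]]:
        ci = binomtest(hits, n).proportion_ci(0.95, method="wilson")
        return hits / n, (float(ci.low), float(ci.high))

    def summary(self) -> str:
        lines = [f"{self.name} ({self.n_replicates} replicates)"]
        for key, rate in self.rates.items():
            lo, hi = self.intervals.get(key, (np.nan, np.nan))
            lines.append(f"  {key:<28}{rate:8.4f}  [{lo:.4f}, {hi:.4f}]")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=default)


def null_scan_panel(study: Study, n_replicates: int, seed,
                    X=None) -> tuple[np.ndarray, list[np.ndarray]]:
    """W statistics for null-phenotype replicates at every cluster-field
    position.  Returns (W matrix (reps, n_fields), per-chromosome field
    cM grids in field order)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    Y = simulate_phenotypes(study.psi, None, n_replicates, rng)
    tester = _FieldTester(study.bundle(Y[0], X), fast=True)
    W = np.empty((n_replicates, len(study.fields)))
    for r in range(n_replicates):
        tester.set_trait(Y[r])
        for fi in range(len(study.fields)):
            W[r, fi] = tester.test_field(fi)["W"]
    chrom_order = [f.chrom for f in study.fields]
    grids = []
    for chrom in dict.fromkeys(chrom_order):
        grids.append(np.array([i for i, c in enumerate(chrom_order)
                               if c == chrom]))
    return W, grids


def ou_threshold_from_null_scans(study: Study, W: np.ndarray,
                                 grids: list[np.ndarray],
                                 seed) -> tuple[float, ThresholdResult]:
    """Estimate alpha from replicate null scans (pairs pooled within
    chromosomes) and derive the Monte-Carlo genome-wide threshold."""
    scans = [[W[r, g] for r in range(W.shape[0])] for g in grids]
    lags = np.round(study.config.spacing_cM * np.arange(1, 11), 10)
    alpha = estimate_alpha(scans, study.config.spacing_cM, lags_cM=lags)
    model = OUModel(alpha=alpha, spacing_cM=study.config.spacing_cM,
                    chrom_lengths_cM=study.chrom_lengths)
    thr = genome_threshold(model, n_replicates=study.config.ou_replicates,
                           level=study.config.level, seed=seed)
    return alpha, thr


def type1_experiment(config: ExperimentConfig, n_replicates: int = 1000,
                     study: Study | None = None) -> ExperimentReport:
    """Family-wise type I error of the genome scan under the global
    null, with the OU-derived threshold and the Bonferroni threshold.

    Null traits are Y = g + eps with g ~ N(0, Psi_hat); each replicate
    is scanned at every grid position, alpha is estimated from the
    first ``n_alpha_replicates`` scans, and a replicate counts as a
    family-wise error when any position beats the threshold.
    """
    ss = np.random.SeedSequence(config.seed)
    s_pheno, s_ou = ss.spawn(2)
    if study is None:
        study = prepare_study(config)

    W, grids = null_scan_panel(study, n_replicates,
                               np.random.default_rng(s_pheno))
    n_alpha = min(config.n_alpha_replicates, n_replicates)
    alpha, thr = ou_threshold_from_null_scans(
        study, W[:n_alpha], grids, np.random.default_rng(s_ou))

    max_w = W.max(axis=1)
    n_tests = W.shape[1]
    bonferroni_p = (1 - config.level) / n_tests
    w_bonf = _w_from_p(bonferroni_p)
    hits_ou = int((max_w >= thr.w_critical).sum())
    hits_bf = int((max_w >= w_bonf).sum())

    rate_ou, ci_ou = ExperimentReport.rate_with_ci(hits_ou, n_replicates)
    rate_bf, ci_bf = ExperimentReport.rate_with_ci(hits_bf, n_replicates)
    return ExperimentReport(
        name="genome-wide type I error",
        n_replicates=n_replicates,
        rates={"fwer_ou": rate_ou, "fwer_bonferroni": rate_bf},
        intervals={"fwer_ou": ci_ou, "fwer_bonferroni": ci_bf},
        details={"alpha_hat": alpha, "w_critical": thr.w_critical,
                 "p_threshold": thr.p_threshold, "n_tests": n_tests,
                 "bonferroni_p": bonferroni_p,
                 "max_w_per_replicate": max_w},
        provenance={"seed": config.seed, "n_replicates": n_replicates,
                    "config": _config_dict(config)})


def _w_from_p(p: float) -> float:
    """Invert the mixture p-value: W such that chi2.sf(W,1)/2 = p."""
    from scipy.stats import chi2
    return float(chi2.isf(min(2.0 * p, 1.0), 1))


def power_experiment(config: ExperimentConfig, variant_class: str,
                     n_replicates: int = 1000,
                     study: Study | None = None,
                     p_threshold: float | None = None,
                     sv_threshold: float | None = None,
                     array_markers_per_chrom: int | None = None,
                     classes=None,
                     variance_per_variant: float = 0.05) -> ExperimentReport:
    """Power to detect a 0.05 cM causal region of the given MAF class.

    Each replicate picks a fresh qualifying region, simulates the trait,
    and tests the region directly with the local IBD matrix averaged
    over the region's start and end positions; detection means region
    p <= ``p_threshold`` (the OU genome-wide threshold, computed from
    null scans when not supplied).  The single-variant comparator takes
    the minimum regression p over the region's markers in the SNP-array
    version of the data, judged at ``sv_threshold`` (default: 0.05 over
    the array marker count, the scan-wide Bonferroni level).
    """
    ss = np.random.SeedSequence(config.seed + 1)
    s_pheno, s_region, s_array, s_ou = ss.spawn(4)
    if study is None:
        study = prepare_study(config)
    if p_threshold is None:
        W, grids = null_scan_panel(study, config.n_alpha_replicates,
                                   np.random.default_rng(s_ou))
        _, thr = ou_threshold_from_null_scans(
            study, W, grids, np.random.default_rng(s_ou))
        p_threshold = thr.p_threshold

    if array_markers_per_chrom is None:
        # the full-scale array density: 30,000 markers per 100 cM
        array_markers_per_chrom = int(round(
            300 * config.sim.chromosome_length_cM))
    array = make_snp_array(study.haps, None, array_markers_per_chrom,
                           seed=int(s_array.generate_state(1)[0] % (2**31)))
    if sv_threshold is None:
        sv_threshold = 0.05 / max(array.n_markers, 1)

    rng_pheno = np.random.default_rng(s_pheno)
    region_seeds = s_region.generate_state(n_replicates) % (2 ** 31)
    hits_ibd = hits_sv = 0
    causal_on_array = 0
    classes = classes or VARIANT_CLASSES
    vclass = classes[variant_class]
    vc_label = vclass.label
    array_pos = {c: set(array.restrict(c).variants["pos"]) for c in array.chromosomes}
    for r in range(n_replicates):
        spec = select_causal_region(study.haps, study.gmap, vclass,
                                    seed=int(region_seeds[r]),
                                    variance_per_variant=variance_per_variant)
        y = simulate_phenotypes(study.psi, spec, 1, rng_pheno,
                                haps=study.haps)[0]
        f0 = cluster_at_position(study.haps, study.gmap, config.clustering,
                                 spec.start_cM, chrom=spec.chrom)
        f1 = cluster_at_position(study.haps, study.gmap, config.clustering,
                                 spec.end_cM, chrom=spec.chrom)
        phi = region_ibd_matrix([f0, f1], study.haps.n_samples)
        model = VarianceComponentModel(y, study.psi, phi, None,
                                       chrom=spec.chrom,
                                       position_cM=spec.start_cM)
        res = model.lod_test()
        if np.isfinite(res.p_value) and res.p_value <= p_threshold:
            hits_ibd += 1
        causal_pos = set(study.haps.variants["pos"].to_numpy()
                         [spec.causal_indices])
        causal_on_array += bool(causal_pos & array_pos.get(spec.chrom, set()))
        try:
            sv = single_variant_comparator(
                array, y, (spec.chrom, spec.start_cM, spec.end_cM),
                study.gmap, exclude_bp=causal_pos)
        except ValueError:   # no non-causal array marker in the region
            sv = {"min_p": np.nan}
        if np.isfinite(sv["min_p"]) and sv["min_p"] <= sv_threshold:
            hits_sv += 1

    rate_ibd, ci_ibd = ExperimentReport.rate_with_ci(hits_ibd, n_replicates)
    rate_sv, ci_sv = ExperimentReport.rate_with_ci(hits_sv, n_replicates)
    return ExperimentReport(
        name=f"power, {vc_label} causal variants",
        n_replicates=n_replicates,
        rates={"power_ibd": rate_ibd, "power_single_variant": rate_sv},
        intervals={"power_ibd": ci_ibd, "power_single_variant": ci_sv},
        details={"p_threshold": p_threshold, "sv_threshold": sv_threshold,
                 "array_markers": array.n_markers,
                 "variance_per_variant": variance_per_variant,
                 "replicates_with_causal_on_array": causal_on_array},
        provenance={"seed": config.seed, "variant_class": vc_label,
                    "n_replicates": n_replicates,
                    "config": _config_dict(config)})


def _config_dict(config: ExperimentConfig) -> dict:
    out = asdict(config)
    out["detector_effective"] = asdict(config.detector_params())
    return out
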