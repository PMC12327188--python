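"""Synthetic data for validating the IBD mapping test.

Two generators are provided.  ``simulate_population`` produces phased
whole-genome haplotypes for an outbred population by coalescent
simulation (msprime), one independent tree sequence per chromosome,
under a three-epoch demography that mimics a large, recently expanded
population of the UK type: present-day effective size 10^6 shrinking
exponentially back to 10^4 at 100 generations ago, constant 10^4 before
that.  This yields IBD segments concentrated in small clusters of
distantly related individuals — the regime the mapping test assumes.
Mutation and recombination both default to 1e-8 per bp per generation,
so the genetic map is uniform at 1 cM/Mb and is emitted explicitly.

``generate_structured_fixture`` skips genotypes entirely and emits
cluster fields and a kinship table with known ground truth, so the
variance-component test and the OU adjustment can be exercised in
seconds without a coalescent backend.

Phenotypes follow Y = X beta + g + sum_l theta_l q_l + eps with
g ~ N(0, Psi_hat), eps ~ N(0, I), q_l the minor-allele dosage at causal
marker l, and theta_l = sqrt(0.05 / (2 MAF_l (1 - MAF_l))) so each
causal variant contributes 0.05 to the trait variance (a literal
non-square-root reading is selectable via ``effect_scale``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from .ibd_io import ClusterField, GeneticMap, PhasedHaplotypes, KINSHIP_COLUMNS
from .relatedness import block_partition, ensure_psd

__all__ = [
    "SimConfig",
    "VariantClass",
    "VARIANT_CLASSES",
    "PhenotypeSpec",
    "StructuredSpec",
    "simulate_population",
    "generate_structured_fixture",
    "select_causal_region",
    "simulate_phenotypes",
    "make_snp_array",
]


@dataclass
class SimConfig:
    """Coalescent simulation settings.  Defaults are the full-scale
    study conditions (5,000 individuals, 30 chromosomes of 100 cM,
    mutation and recombination at 1e-8); scale down for desk runs."""

    n_individuals: int = 5000
    n_chromosomes: int = 30
    chromosome_length_cM: float = 100.0
    mutation_rate: float = 1e-8
    recombination_rate: float = 1e-8
    demography: str = "uk"
    seed: int = 1

    @property
    def chrom_names(self) -> list[str]:
        return [str(c + 1) for c in range(self.n_chromosomes)]


@dataclass(frozen=True)
class VariantClass:
    """MAF class of causal variants; bounds are (lo, hi] on MAF."""

    label: str
    maf_lo: float
    maf_hi: float
    min_region_variants: int
    causal_fraction: float

    def mask(self, maf: np.ndarray) -> np.ndarray:
        return (maf > self.maf_lo) & (maf <= self.maf_hi)


#: common/low-frequency regions need >= 4 class variants (half causal);
#: rare/ultra-rare need >= 8 (a quarter causal)
VARIANT_CLASSES: Mapping[str, VariantClass] = {
    "common": VariantClass("common", 0.10, 0.50, 4, 0.5),
    "low_frequency": VariantClass("low_frequency", 0.01, 0.10, 4, 0.5),
    "rare": VariantClass("rare", 0.0005, 0.01, 8, 0.25),
    "ultra_rare": VariantClass("ultra_rare", 0.0, 0.0005, 8, 0.25),
}


def scaled_variant_classes(n_haplotypes: int) -> Mapping[str, VariantClass]:
    """MAF classes for desk-scale samples.

    The ultra-rare bound (MAF < 0.05%) presumes thousands of haplotypes;
    in a sample of 2N haplotypes the finest nonzero frequency is 1/2N,
    so the scaled ultra-rare class is the singleton class (one copy) and
    the rare class covers everything above it up to 1%.  The common and
    low-frequency bounds are sample-size independent and unchanged.
    """
    ultra_hi = 1.5 / n_haplotypes
    if ultra_hi < 0.0005:
        return VARIANT_CLASSES
    # desk scale: singletons are "ultra-rare"; "rare" covers allele
    # counts from two up, staying strictly below the 1% SNP-array
    # cutoff whenever the sample allows it, so that (as at full scale)
    # no rare-class variant is ever genotyped
    rare_hi = max(min(0.0095, 4.5 / n_haplotypes), 2.5 / n_haplotypes)
    return {
        "common": VariantClass("common", 0.10, 0.50, 4, 0.5),
        "low_frequency": VariantClass("low_frequency", rare_hi, 0.10, 4, 0.5),
        "rare": VariantClass("rare", ultra_hi, rare_hi, 8, 0.25),
        "ultra_rare": VariantClass("ultra_rare", 0.0, ultra_hi, 8, 0.25),
    }


@dataclass
class PhenotypeSpec:
    """Causal architecture of a simulated trait."""

    chrom: str
    start_cM: float
    end_cM: float
    causal_indices: np.ndarray
    thetas: np.ndarray
    variant_class: str = ""
    covariates: np.ndarray | None = None
    covariate_coefs: np.ndarray | None = None
    seed: int | None = None


def _demography(name: str):
    import msprime

    dem = msprime.Demography()
    if name == "uk":
        growth = np.log(1_000_000 / 10_000) / 100.0
        dem.add_population(name="pop", initial_size=1_000_000,
                           growth_rate=growth)
        dem.add_population_parameters_change(time=100, initial_size=10_000,
                                             growth_rate=0.0)
    elif name == "uk-scaled":
        # same three-epoch shape with a smaller present-day size, so that
        # desk-scale samples (hundreds of individuals) see a per-position
        # IBD-cluster density comparable to the full-scale study
        growth = np.log(100_000 / 10_000) / 60.0
        dem.add_population(name="pop", initial_size=100_000,
                           growth_rate=growth)
        dem.add_population_parameters_change(time=60, initial_size=10_000,
                                             growth_rate=0.0)
    elif name == "founder":
        # recent founder event with rapid regrowth: high coalescent
        # intensity in the last ~20 generations makes low-count variants
        # young and IBD-tagged even in samples of a few hundred — the
        # regime where multi-individual IBD mapping is informative at
        # desk scale
        growth = np.log(100_000 / 1_000) / 20.0
        dem.add_population(name="pop", initial_size=100_000,
                           growth_rate=growth)
        dem.add_population_parameters_change(time=20, initial_size=10_000,
                                             growth_rate=0.0)
    elif name == "constant":
        dem.add_population(name="pop", initial_size=10_000)
    else:
        raise ValueError(f"unknown demography {name!r} "
                         "(use 'uk', 'uk-scaled', 'founder' or 'constant')")
    return dem


def simulate_population(config: SimConfig) -> tuple[PhasedHaplotypes, GeneticMap]:
    """Phased haplotypes and uniform genetic map, one independent
    coalescent tree sequence per chromosome; bit-reproducible given the
    seed."""
    import msprime

    dem = _demography(config.demography)
    length_bp = config.chromosome_length_cM / (config.recombination_rate * 100) \
        if config.recombination_rate > 0 else config.chromosome_length_cM * 1e6
    length_bp = int(round(length_bp))
    seeds = (np.random.SeedSequence(config.seed)
             .generate_state(2 * config.n_chromosomes).astype(np.int64)
             % (2 ** 31 - 2) + 1)

    frames, mats = [], []
    for ci, chrom in enumerate(config.chrom_names):
        ts = msprime.sim_ancestry(
            samples=config.n_individuals, demography=dem, ploidy=2,
            sequence_length=length_bp,
            recombination_rate=config.recombination_rate,
            random_seed=int(seeds[2 * ci]))
        mts = msprime.sim_mutations(
            ts, rate=config.mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=int(seeds[2 * ci + 1]))
        G = mts.genotype_matrix().astype(np.int8)          # sites x 2N
        pos = mts.tables.sites.position.astype(np.int64) + 1
        seg = G.min(axis=1) != G.max(axis=1)
        G, pos = G[seg], pos[seg]
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "ref": "A", "alt": "C"}))
        mats.append(G.T)

    variants = pd.concat(frames, ignore_index=True)
    haps = PhasedHaplotypes(
        samples=[f"S{i:05d}" for i in range(config.n_individuals)],
        variants=variants,
        haplotypes=np.concatenate(mats, axis=1))
    gmap = GeneticMap.uniform(
        {c: config.chromosome_length_cM for c in config.chrom_names},
        cm_per_mb=config.recombination_rate * 1e8)
    return haps, gmap


# ---------------------------------------------------------------------------
# Structured desk-scale fixture
# ---------------------------------------------------------------------------

@dataclass
class StructuredSpec:
    """Ground-truth layout for the structured fixture: how many IBD
    clusters of each size exist at every position, and what fraction of
    individuals form close-relative pairs."""

    cluster_sizes: Mapping[int, int] = field(default_factory=lambda: {2: 8, 3: 3, 4: 1})
    n_positions: int = 1
    related_fraction: float = 0.05
    related_kinship: float = 0.125
    chrom: str = "1"
    start_cM: float = 0.0
    spacing_cM: float = 0.1


def generate_structured_fixture(n_individuals: int, spec: StructuredSpec,
                                seed: int | None = None
                                ) -> tuple[list[ClusterField], pd.DataFrame]:
    """Cluster fields plus kinship table with known ground truth.

    At each position, the requested numbers of IBD clusters of each
    size are drawn over distinct haplotypes; everything else is a
    singleton.  A ``related_fraction`` of individuals is split into
    disjoint relative pairs at the given kinship.
    """
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    need = sum(s * c for s, c in spec.cluster_sizes.items())
    if need > n_hap:
        raise ValueError("cluster specification exceeds available haplotypes")

    fields = []
    for k in range(spec.n_positions):
        labels = np.arange(n_hap, dtype=np.int64)
        chosen = rng.choice(n_hap, size=need, replace=False)
        at = 0
        for size, count in spec.cluster_sizes.items():
            for _ in range(count):
                members = chosen[at:at + size]
                labels[members] = labels[members[0]]
                at += size
        cm = spec.start_cM + k * spec.spacing_cM
        fields.append(ClusterField(
            chrom=spec.chrom, position_bp=int(round(cm * 1e6)) + 1,
            position_cM=cm, labels=labels))

    n_pairs = int(round(spec.related_fraction * n_individuals / 2))
    picked = rng.choice(n_individuals, size=2 * n_pairs, replace=False)
    kin = pd.DataFrame(
        [(f"S{picked[2 * i]:05d}", f"S{picked[2 * i + 1]:05d}",
          spec.related_kinship) for i in range(n_pairs)],
        columns=KINSHIP_COLUMNS)
    return fields, kin


# ---------------------------------------------------------------------------
# Causal architecture and phenotypes
# ---------------------------------------------------------------------------

def _theta(maf: np.ndarray, effect_scale: str,
           variance_per_variant: float) -> np.ndarray:
    base = variance_per_variant / (2.0 * maf * (1.0 - maf))
    if effect_scale == "sqrt":
        return np.sqrt(base)
    if effect_scale == "literal":
        return base
    raise ValueError("effect_scale must be 'sqrt' or 'literal'")


def select_causal_region(haps: PhasedHaplotypes, gmap: GeneticMap,
                         variant_class: str | VariantClass,
                         seed: int | None = None,
                         region_length_cM: float = 0.05,
                         effect_scale: str = "sqrt",
                         variance_per_variant: float = 0.05) -> PhenotypeSpec:
    """Choose a causal region of the given MAF class uniformly among
    qualifying tiling windows and assign effect sizes.

    Common/low-frequency regions need at least 4 class variants and half
    become causal; rare/ultra-rare need at least 8 and a random quarter
    become causal.
    """
    vc = (VARIANT_CLASSES[variant_class]
          if isinstance(variant_class, str) else variant_class)
    rng = np.random.default_rng(seed)
    maf = haps.minor_allele_frequency()
    cms = haps.marker_cM(gmap)
    in_class = vc.mask(maf)

    candidates = []
    for chrom in haps.chromosomes:
        sl = haps._chrom_slices()[chrom]
        span = gmap.span_cM(chrom)
        edges = np.arange(span[0], span[1], region_length_cM)
        cm_chr = cms[sl]
        cls_chr = in_class[sl]
        idx_base = sl.start
        for w0 in edges:
            w1 = w0 + region_length_cM
            lo = int(np.searchsorted(cm_chr, w0, side="left"))
            hi = int(np.searchsorted(cm_chr, w1, side="left"))
            count = int(cls_chr[lo:hi].sum())
            if count >= vc.min_region_variants:
                candidates.append((chrom, w0, w1, idx_base + lo, idx_base + hi))
    if not candidates:
        raise ValueError(
            f"no {region_length_cM} cM region holds "
            f">= {vc.min_region_variants} {vc.label} variants; "
            "simulate a larger population or genome")

    chrom, w0, w1, lo, hi = candidates[rng.integers(len(candidates))]
    members = np.arange(lo, hi)[in_class[lo:hi]]
    n_causal = max(1, int(len(members) * vc.causal_fraction))
    causal = np.sort(rng.choice(members, size=n_causal, replace=False))
    return PhenotypeSpec(chrom=chrom, start_cM=float(w0), end_cM=float(w1),
                         causal_indices=causal,
                         thetas=_theta(maf[causal], effect_scale,
                                       variance_per_variant),
                         variant_class=vc.label, seed=seed)


def _block_cholesky(psi: sp.spmatrix) -> tuple[list[np.ndarray], list[np.ndarray]]:
    psi = ensure_psd(sp.csr_matrix(psi))
    blocks = block_partition(psi)
    factors = []
    for b in blocks:
        if b.size == 1:
            factors.append(np.sqrt(psi[b[0], b[0]]) * np.ones((1, 1)))
        else:
            dense = psi[np.ix_(b, b)].toarray()
            factors.append(scipy.linalg.cholesky(dense, lower=True))
    return blocks, factors


def simulate_phenotypes(psi: sp.spmatrix, spec: PhenotypeSpec | None = None,
                        n_replicates: int = 1, seed=None,
                        haps: PhasedHaplotypes | None = None) -> np.ndarray:
    """Trait replicates Y = X beta + g + sum theta_l q_l + eps,
    shape (n_replicates, N).

    g is drawn block-wise from N(0, Psi_hat); eps is standard normal.
    With ``spec`` None the trait is the pure null model g + eps.  The
    causal genotype term requires ``haps``.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = psi.shape[0]
    blocks, factors = _block_cholesky(psi)
    g = np.empty((n_replicates, n))
    eta = rng.standard_normal((n_replicates, n))
    for b, L in zip(blocks, factors):
        g[:, b] = eta[:, b] @ L.T
    y = g + rng.standard_normal((n_replicates, n))

    if spec is not None:
        fixed = np.zeros(n)
        if spec.causal_indices is not None and len(spec.causal_indices):
            if haps is None:
                raise ValueError("haps required for causal genotype effects")
            q = np.atleast_2d(haps.dosage(spec.causal_indices).T)
            q = q.reshape(len(spec.causal_indices), n)
            fixed = fixed + spec.thetas @ q
        if spec.covariates is not None:
            fixed = fixed + np.asarray(spec.covariates) @ np.asarray(
                spec.covariate_coefs)
        y = y + fixed
    return y


def make_snp_array(haps: PhasedHaplotypes, phenospec: PhenotypeSpec | None,
                   n_per_chromosome: int = 30_000,
                   seed: int | None = None,
                   min_maf: float = 0.01) -> PhasedHaplotypes:
    """SNP-array downsampling: drop variants below ``min_maf`` and all
    trait-associated (causal) variants, then sample up to
    ``n_per_chromosome`` of the rest per chromosome without replacement.
    """
    import warnings

    rng = np.random.default_rng(seed)
    maf = haps.minor_allele_frequency()
    keep = maf >= min_maf
    if phenospec is not None and len(phenospec.causal_indices):
        keep[np.asarray(phenospec.causal_indices)] = False

    chosen: list[np.ndarray] = []
    for chrom, sl in haps._chrom_slices().items():
        idx = np.arange(sl.start, sl.stop)[keep[sl]]
        if idx.size < n_per_chromosome:
            warnings.warn(
                f"chromosome {chrom}: only {idx.size} qualifying variants "
                f"(requested {n_per_chromosome}); keeping all", RuntimeWarning)
            chosen.append(idx)
        else:
            chosen.append(np.sort(rng.choice(idx, size=n_per_chromosome,
                                             replace=False)))
    return haps.subset_markers(np.concatenate(chosen))
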