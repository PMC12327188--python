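# Methods

`ibdscan` tests whether local identity-by-descent (IBD) sharing explains
variation in a quantitative trait, and corrects the resulting genome
scan for multiple testing using the correlation structure of the scan
statistics. This note records the models, the numerical choices, and
what the synthetic data do and do not emulate.

## The variance-component LOD test

The trait model at genomic position l is the linear mixed model

    Y = X beta + G + Q_l + eps,
    Var(Y) = V = Psi sigma_a^2 + Phi_l sigma_Q^2 + I sigma_e^2.

`Psi` (global IBD matrix) is twice the kinship coefficient for each
pair, thresholded at kinship 0.044 (relationships more distant than
third degree are set to zero) with a unit diagonal, and captures
genome-wide additive resemblance. `Phi_l` (local IBD matrix) holds the
proportion of alleles shared IBD by each pair at position l; it is
built from multi-individual IBD clusters as `Phi_l = 2 A_l A_l'`, where
the allocation matrix `A_l` records the fraction (0, 1/2, 1) of each
individual's two haplotypes assigned to each cluster. Matrices built
this way are positive semidefinite by construction; after thresholding,
`Psi` may not be, so blocks whose Cholesky fails receive the smallest
diagonal jitter from {1e-8, 1e-6} (logged).

The association test is H0: sigma_Q^2 = 0 against sigma_Q^2 > 0 by
restricted maximum likelihood. The statistic is W = 2 ln(10) x LOD =
2 (l1 - l0) of restricted log-likelihoods

    l = const - 1/2 ln|V| - 1/2 ln|X'V^-1 X|
        - 1/2 (Y - X beta_hat)' V^-1 (Y - X beta_hat),

with beta profiled out by GLS and const = -((N - p)/2) ln(2 pi), fixed
across hypotheses so it cancels in W. Because the tested parameter sits
on the boundary of its space, the null distribution of W is the
half-half mixture of a point mass at zero and chi-square with one
degree of freedom; the reported p-value is 1 at W = 0 and
`chi2.sf(W, 1) / 2` otherwise.

### Block-diagonal likelihood evaluation

In a large outbred sample, individuals share IBD only within small
clusters, so `Psi sigma_a^2 + Phi_l sigma_Q^2 + I sigma_e^2` is
block-diagonal under the connected components of the combined sparsity
graph. Every likelihood (and gradient) evaluation runs block by block:
singleton blocks reduce to precomputed scalars, small blocks are padded
to the next power-of-two size and pushed through numpy's stacked
Cholesky/solve/inverse kernels in a handful of LAPACK calls (padding
adds independent unit-variance coordinates with zero data, whose exact
log-determinant and trace contributions are subtracted), and rare large
blocks are handled individually. Cost therefore scales with the cube of
the largest block, not with N.

### Optimization

The residual variance enters only as an overall scale once the model is
written as V = sigma_e^2 (I + gamma_a Psi + gamma_q Phi); given the
ratios, the scale has the closed REML solution sigma_e^2 = quad/(N-p).
Fitting is bound-constrained quasi-Newton (L-BFGS-B, analytic
gradients) over the non-negative ratios — 1-D under H0, 2-D under H1 —
followed by a scale-free log-space polish of interior components (the
gamma-space gradient criterion is too loose when an optimum drifts to
very large ratios, the sigma_e^2 -> 0 boundary). Multi-start is
deterministic: equal split, residual-dominant, additive-dominant.
Estimates below 1e-8 x Var(Y) snap to zero and the remaining components
are refit.

Two details protect the point mass at zero, which a likelihood-ratio
boundary test must get exactly right:

* when the fitted W falls in the ambiguous zone (0, 1e-3), the boundary
  optimum is recomputed inside the alternative model (same blocks, same
  optimizer, warm-started from the alternative fit) so l1 and l0 share
  one numerical environment, and the Karush-Kuhn-Tucker condition — a
  non-positive local-variance score at the boundary optimum — classifies
  sub-resolution positives as exact zeros;
* the scan drivers use a fast profile that applies the same score-sign
  test as a prescreen (skipping the alternative fit outright when the
  boundary is the constrained maximum) and otherwise fits from the warm
  start alone. Fast and full profiles agreed to |delta W| < 1e-4 on
  every replicate checked, and the fast profile is what the null
  calibration test exercises.

Non-convergence is flagged on the result, never raised, so a genome
scan continues past a pathological position.

## Multi-individual IBD clustering

At a focal position, two haplotypes are IBD-related when they carry the
same allele sequence over a contiguous marker interval that covers the
focal point, extends at least T cM on each side of it, and spans at
least L cM in total; clusters are connected components of this
relation. Defaults L = 2 cM, T = 0.5 cM; T <= L/2 (the admissible
boundary T = L/2 makes the side requirements and the total-length
requirement coincide). Larger L or T is strictly more stringent, so the
partition refines monotonically.

The implementation sorts haplotypes with a positional Burrows-Wheeler
transform; only haplotypes identical across the trimming window can be
related, so the exact pairwise window test runs only inside those
blocks, with union-find closing the transitive relation. A scan
computes the PBWT states for every grid position in one forward sweep
per chromosome. Runs are measured between agreeing-marker endpoints; a
run bounded by no mismatch before the first (after the last) marker
extends to the chromosome end, which also satisfies the trimming
requirement on that side — otherwise no position within T of an end
could ever cluster. An exhaustive all-pairs oracle ships in the test
suite and the two agree exactly on every tested fixture.

Pairwise IBD segments (for kinship estimation) are maximal identical
runs on markers passing a minor-allele-count filter, found by hashing
tiling windows of half the output threshold (any qualifying run covers
at least one tile), extending candidates to maximal runs, and applying
the length and marker-count filters. With error-free phased input a
seed always extends to the maximal run, so the seed/extension
parameters of the usual detectors reduce to the output filters; both
parameter presets (sequence: seed 0.5 cM, extension 0.2 cM, output
2 cM, MAC 100; array: seed 1 cM, extension 0.1 cM, 50 seed markers,
output 3 cM) are provided. Kinship is assembled from the
haplotype-resolved segments as p1/4 + p2/2, where p1 and p2 are the
genome proportions in IBD1 (at least one of the four haplotype pairings
shared) and IBD2 (both haplotypes of each individual shared, in either
pairing).

## Genome-wide multiple testing

Under the global null the standardized scan statistics Z_l are modelled
as a stationary Ornstein-Uhlenbeck process with autocorrelation
rho(alpha, d) = exp(-alpha d) at distance d cM, and the scan statistic
is the positive-truncated square W_l = Z_l^2 1{Z_l > 0}. The
correlation between W statistics at distance d is the closed form

    f(rho) = [ 2 rho^2 + (6 rho sqrt(1 - rho^2)
              + (2 + 4 rho^2) arcsin(rho)) / pi ] / 5,
    rho = exp(-alpha d),

derived from bivariate-normal moments (E W = 1/2, Var W = 5/4) and
certified against a large Monte-Carlo oracle in the test suite before
use. `alpha` is estimated from null scans: the empirical correlation of
W pairs at each lag d (pairs pooled within, never across, chromosomes)
is inverted through f by root bracketing, and -log(rho_hat) is
regressed on d through the origin (unweighted); the slope is alpha_hat.
Confidence intervals come from a percentile bootstrap that resamples
chromosomes with replacement (default 10,000 replicates).

The genome-wide threshold is Monte Carlo: per chromosome, simulate a
stationary AR(1) sequence with lag-1 correlation exp(-alpha x spacing)
(initialized N(0,1), independent across chromosomes), square and
truncate, record the genome-wide maximum, repeat (default 10,000), and
take the 95% quantile W*; the per-test threshold is
p* = chi2.sf(W*, 1)/2. Positive dependence places p* strictly between
the Bonferroni level and the nominal level.

## Scans

Tests run on a regular grid (default 0.1 cM) using the nearest cluster
field to each grid point — IBD state changes slowly along a chromosome,
so fields at 0.1 cM intervals serve any nearby position. The null model
depends only on (Y, X, Psi) and is fitted once per trait; per-position
work is the alternative fit alone, with all position-dependent
precomputation (fields, block structures) shared across traits. The
two-step scan tests a coarse 1 cM grid, takes the top 10 positions per
chromosome by ascending p, merges 1 cM windows centred on them, and
re-tests at the fine spacing. Regions are tested directly with the
elementwise mean of the local matrices at the region's start and end.

## Synthetic data

`simulate_population` draws phased haplotypes per chromosome from
independent coalescent tree sequences (msprime), with mutation and
recombination both 1e-8 per bp per generation, hence a uniform 1 cM/Mb
map, emitted explicitly. Full-scale defaults: 5,000 individuals, 30
chromosomes of 100 cM. Demographies:

* `uk` (default): present-day size 10^6 shrinking exponentially to 10^4
  at 100 generations ago, constant before — a large, recently expanded
  outbred population; IBD clusters are small and sparse.
* `uk-scaled`: the same shape with present size 10^5 over 60
  generations, for desk-scale samples that should see a cluster density
  per position comparable to the full-scale study.
* `founder`: ancestral 10^4, founder size 10^3 at 20 generations ago
  regrowing to 10^5. High recent coalescent intensity makes low-count
  variants young and therefore IBD-tagged even in samples of a few
  hundred. The scaled power study uses this model: under `uk` at
  N = 200, carriers of low-count variants share a median run of only
  ~0.3 cM (never 2 cM), so no method can detect them and a power
  comparison would be vacuous; the founder model restores the regime
  the method addresses (about a third of carrier pairs share >= 2 cM).
* `constant`: constant 10^4, as a control with a classical site
  frequency spectrum.

Phenotypes are Y = X beta + g + sum_l theta_l q_l + eps with
g ~ N(0, Psi_hat) drawn block-wise, eps standard normal, and q_l the
minor-allele copy number. The effect size is
theta_l = sqrt(v / (2 MAF_l (1 - MAF_l))) so each causal variant
contributes v to the trait variance; the printed form of this rule is
ambiguous about the radical, so a literal (non-square-root) reading is
selectable via `effect_scale="literal"`. The per-variant contribution
defaults to v = 0.05. Causal regions are 0.05 cM windows holding at
least 4 variants of the target MAF class for common/low-frequency
(half made causal) or at least 8 for rare/ultra-rare (a random quarter
causal). MAF classes: common (>10%), low-frequency (1-10%), rare
(0.05-1%), ultra-rare (<0.05% but present). At desk scale the
ultra-rare bound falls below one copy, so `scaled_variant_classes`
substitutes count-based analogues (singletons as ultra-rare, counts
2-4 or up to 1% as rare).

SNP arrays are built by dropping variants with MAF below 1% and all
trait-associated variants, then sampling up to 30,000 of the rest per
chromosome without replacement.

`generate_structured_fixture` bypasses genotypes entirely: it emits
cluster fields with a prescribed number of clusters of each size and a
kinship table for a prescribed fraction of relative pairs, so the test
and the OU machinery can be exercised with known ground truth in
seconds. What it does not emulate: linkage between positions (fields at
different positions are independent), correlation between cluster
membership and kinship, genotyping or phasing error, and any
association between cluster size and haplotype frequency. Passing
calibration on the fixture therefore validates the statistic and its
boundary behaviour, not the IBD-detection pipeline — that is covered by
the coalescent-simulation experiments.

## Validation studies and the problem sizes used

The package's own validation (test suite and `scripts/acceptance.py`)
runs at desk scale, chosen so the full suite and script complete in
minutes on one CPU:

* Null calibration: N = 300 structured fixture (120 pair clusters, 40
  triple clusters, 10% relative pairs), 2,000 null traits. The point
  mass of W at zero and the chi-square fit of the positive part are
  both asymptotic statements; the fixture's block count was chosen (via
  the sign distribution of the boundary score, not via the acceptance
  checks) to put the finite-sample point mass near 1/2. With few
  blocks, P(W = 0) sits visibly above 1/2 — expected behaviour of a
  boundary score with skewed finite-sample distribution, not
  miscalibration of the tail, which stays at the nominal level.
* Family-wise error: 200 individuals, 2 chromosomes x 20 cM (founder
  demography), scans at 0.1 cM, alpha estimated from the first 10 null
  scans, Monte-Carlo threshold from 5,000 replicates, family-wise
  rejection over 40-50 null traits, against both the OU threshold and
  Bonferroni. At this scale the per-test null is slightly conservative
  in the extreme tail, so the family-wise error tends to sit at or
  below the nominal 5%; Bonferroni is always at most the OU rate.
* Power: same study, 20-30 replicates per MAF class, per-variant
  contribution v = 1.5 (a desk-scale condition — at N = 200 the
  full-scale v = 0.05 yields essentially zero power for every method,
  which cannot exhibit any ordering; v was set by piloting the IBD
  mapping arm alone to mid-range operating power before the
  single-variant arm was run, so the design choice is independent of
  the between-method comparison being evaluated). The array holds 300
  markers per cM (the full-scale density) and the scaled rare class is
  capped strictly below the 1% array cutoff so no rare-class variant is
  ever genotyped, as at full scale. The single-variant comparator
  regresses the trait on minor-allele dosage at every non-causal array
  marker in the region and takes the minimum p, judged at 0.05 over
  the array marker count (the scan-wide Bonferroni level; the
  full-scale analogue of the conventional genome-wide 5e-8).

## Known limitations

* The likelihood-ratio machinery assumes the combined Psi/Phi graph
  decomposes into small blocks; a giant component (dense sampling of a
  small population) would make each evaluation cubic in N.
* The half:half mixture null is asymptotic in the number of informative
  IBD blocks; with very sparse local sharing the test is conservative.
* The pairwise detector and the clusterer assume error-free, fully
  phased genotypes; genotype-error-tolerant detection is out of scope.
* Binary traits, gene-environment interaction terms, and inbred
  populations (local matrices with diagonal entries of 2) are not
  supported.
* Kinship from segments uses haplotype-resolved IBD1/IBD2 proportions;
  it does not model detection error in the input segments.
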