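# Methods

## Allele-frequency genotypes

Tetraploid dosage calling needs ~60–80× coverage per site; GBS delivers a
median of ~10×.  The pipeline therefore works directly with the per-sample
alternative-read fraction `X_ik = AC_alt/(AC_ref+AC_alt) ∈ [0, 1]`, whose
expectation is dosage/4 (up to sequencing error), and treats a cell as
missing exactly when its total depth is zero.  No genotype, no imputation
model — just the raw frequency and, downstream, mean imputation.

Marker filters are applied in a fixed order: (1) locus mean depth (over
non-missing cells) within [5, 60]; (2) locus mean allele frequency strictly
inside (0.01, 0.99) — with `maf_min = 0` this rule is skipped entirely, so a
fully permissive configuration is the identity; (3) locus missingness
≤ 50 %; (4) sample missingness ≤ 70 %, computed on the surviving loci.
Order matters only for the report bookkeeping and the sample rule (which
must come last so that "samples missing too much" refers to the selected
markers); each step's removals are tallied in a `FilterReport` that always
reconciles with the output dimensions.  The stringent set (markers ≤ 1 %
missing, then samples ≤ 10 % missing) trades marker count for completeness
and is the remedy for the batch artifact below.

## Environmental adjustment

Phenotypes from several years and locations are adjusted with

    y = μ + genotype (random, iid σ²_gen) + year (fixed) + location (fixed) + e,

fitted by REML.  The implementation profiles the restricted likelihood over
the single variance ratio on the eigenstructure of the genotype-incidence
cross-product (`_mixed.profile_reml`): with one random effect the REML
problem is exactly one-dimensional, so a bounded scalar optimisation on a
log grid is both exact and deterministic.  The same engine solves GBLUP.
The estimated year and location effects are subtracted from every record
and corrected records averaged per genotype; μ is retained (only "the
effects" are subtracted), and the first (sorted) level of each factor is
the reference (effect 0).  Consequences worth knowing:

- adjusted means are invariant to a constant added to any *non-reference*
  level's records (the effect estimate absorbs it); a constant added to the
  *reference* level moves μ and hence all adjusted means equally — genotype
  contrasts are invariant either way, which is what matters downstream;
- when panels are only ever phenotyped in their own environments (the UK
  panel at UK sites), location effects are partially confounded with the
  panels' genetic means — with a shrunken random genotype effect part of
  the genetic difference leaks into the location estimate.  This is a
  property of such study designs, not of the solver; the estimates are
  still the right quantities to subtract for ranking.  Recovery is
  validated on a crossed design (years × locations within genotypes).

Cross-check: the fitted fixed effects and variance components agree with
statsmodels `MixedLM` (REML) to 3–4 decimals on shared test problems.

Derived phenotypes: dry matter from buoyancy, `DM% = 214·(Wa/(Wa−Ww) −
0.988)` (guarded against Wa ≤ Ww); the 1–6 light-to-dark chip scale is
mapped to the 1–9 dark-to-light scale with the endpoint-anchored negative
linear map `s9 = 9 − (8/5)(s6 − 1)`.  Published converted ranges that fall
outside [1, 9] cannot be produced by any endpoint-anchored linear map, so
the slope and intercept are configurable rather than guessed; out-of-range
inputs convert with a warning.

## Relationship matrix

With locus means `p_k` (non-missing cells only) and VanRaden's missing-data
weights `w_i = Σ_k p_k(1−p_k) / Σ_{k observed in i} p_k(1−p_k) ≥ 1`,

    Z_ik = (X_ik − p_k)·w_i,   missing cells set to exactly 0,
    G = ZZ′ / (0.25·Σ_k p_k(1−p_k)).

Because `Var(X) = p(1−p)/4` under random-union (Hardy–Weinberg)
equilibrium for an autotetraploid, the denominator is the expected average
diagonal of ZZ′ — the 0.25 *is* the tetraploid adjustment; the calibration
test checks mean diag(G) ≈ 1 on an equilibrium population.  Setting missing
cells to zero after centring is mean imputation; the w_i weights compensate
the lost variance in expectation.  PCA treats G as a data matrix
(column-centred, SVD), matching common statistical tooling; raw-G PCA is a
flag away.

Mean imputation has a sharp failure mode that the simulator reproduces:
when two sequencing libraries drop different marker subsets, all samples of
a batch are imputed at the same loci and acquire a shared score offset — in
PCA the batches separate by an approximately common displacement vector
("parallel dislocation"), visible as duplicated individuals genotyped in
both batches landing in two places.  Stringent filtering removes the
batch-specific loci and collapses the displacement (≥ 2× in the test, ~3–5×
typically).

## GBLUP

Model: `y = 1μ + g + e`, `g ~ N(0, G σ²_g)`, `e ~ N(0, I σ²_e)`.

- **REML path** (default, deterministic): the restricted likelihood over
  the phenotyped block of G is profiled over δ = σ²_e/σ²_g as above; GEBVs
  for all individuals, phenotyped or not, are
  `ĝ = G[:, t](G_tt + δI)⁻¹(y_t − μ̂)` — the joint mixed-model equations
  with test records treated as missing, so no test phenotype can leak in.
- **Gibbs path**: conjugate sampler over (μ, α, σ²_g, σ²_e) in the
  eigenbasis of G (`g = U√D α`), scaled-inverse-χ² priors with 5 degrees of
  freedom and scales that put the prior mode at an even split of the
  phenotypic variance (the common default of Bayesian whole-genome
  regression software; configurable).  12 000 iterations / 2 000 burn-in by
  default.  GEBVs are the Rao-Blackwellised posterior mean (the conditional
  mean of α is accumulated instead of its draws), which cuts the
  Monte-Carlo error enough that doubling the chain moves GEBVs by less
  than 0.01 sd(y) on the standard fixture.  Chains are bit-reproducible by
  seed.  When every individual in G is phenotyped the update is diagonal
  and the sampler costs O(n) per sweep; otherwise the α block is sampled
  jointly via Cholesky.
- **SNP-BLUP oracle**: ridge regression on Z with shrinkage λ equals GBLUP
  with `G = ZZ′/c` at fixed ratio δ = λ/c, exactly; the equivalence (max
  abs GEBV difference < 1e-6 over randomised instances) is the standing
  cross-check that the GBLUP algebra is right.

G is validated as PSD with a two-level tolerance: eigenvalues below
−1e−5·λ_max are an error; small negative round-off (single-precision
cross-products of very large marker panels land around −1e−6·λ_max) is
repaired by a diagonal jitter of |λ_min| + 1e−8·λ_max.

REML solvers agree with the Gibbs posterior means to r ≥ 0.99 on
family-structured fixtures; on weakly structured (equilibrium) populations
the prior pulls the posterior slightly away from the REML optimum, which is
expected behaviour, not a defect.

## Cross-validation and the experiment grid

Within-population accuracy uses repeated 5-fold CV (50 repeats at study
scale; smaller in the test suite): per repeat a fresh random partition
(remainder spread one-per-fold), every fold predicted from the rest, and
**per-individual GEBVs averaged over repeats before computing the headline
r and β**; per-repeat statistics are kept for spread estimates.
Leave-one-out is k = n with a single pass.  Across-population prediction
fits once on the training panel and scores the test panel inside one joint
G.  Combined-population CV pools all panels into the folds and reports each
panel separately (results are invariant to panel-label order).  β is the
OLS slope of observed on predicted: shrunken (deflated) predictions give
β > 1.

The grid runner crosses {training set} × {prediction set, incl. combined} ×
{marker set: full, stringent, random × 10} × {subsample sizes × 10} into a
tidy table with means and standard deviations over instances; infeasible
cells are recorded as failed without stopping the grid.  Seeds derive from
one master seed and a cell counter (`SeedSequence((seed, counter))`), so
every cell is independently reproducible.  There is no separate CLI: the
grid function, the library API and the narrative example scripts are the
interface.

## Simulator

What it emulates: tetraploid meiosis as random bivalent pairing without
double reduction (gamete = 2 of 4 homologous copies per locus, alt count
hypergeometric(4, dosage, 2)); unlinked loci (the analysis uses only
marker-wise frequencies and genome-wide relationships, so a linkage map
would add nothing the tests could see); full-diallel founder crosses,
random mating of arbitrary individuals (phase never needs tracking beyond
founders precisely because loci are unlinked), truncation-selected panels,
and clonal duplicates; additive traits (QTL drawn among the markers,
normal effects) with the residual calibrated so realised h² hits its
target — within populations when a group map is supplied, since
between-panel divergence would otherwise silently deflate the
within-panel heritability; GBS depths Poisson (mean 12 by default, inside
the 5–60× filter window with both tails reachable), sequencing error 0.005,
and per-(batch, locus) all-or-none dropout, which is what restriction-site
undersampling does per library preparation.

What it does not emulate: linkage and LD decay, double reduction,
dominance/epistasis, genotype-by-environment interaction, selection over
multiple cycles, or sequence-level artefacts (PCR duplicates, allele-biased
capture).  Passing tests therefore demonstrate correctness of the
*statistical machinery* under the model's own assumptions, not performance
on real potato data.

`simulate_study` wires the pieces into a three-panel design: a large
unselected diallel population (default 755), a small selected panel from
the same founder pool (default 80, sharing the 18 founders), a selected
panel from a mostly distinct pool (default 290), a handful of shared
varieties genotyped in two batches, crossed year × location phenotype
records, and one GBS library per panel.  Default marker count is 20 000
(configurable; the tests run 2 000-marker studies for speed and one
150 000-marker fixture for the marker-density experiment).

## Fixture and size choices in the tests

- The "standard fixture" for variance-component work is a clonally
  replicated panel: 150 diallel genotypes × 2 ramets = 300 entries,
  3 000 markers, 100 QTL, h² = 0.5.  Clonal replication is the design a
  vegetatively propagated crop actually affords, and at n = 300 it is the
  most informative layout for REML heritability (single-generation designs
  of the same size have asymptotic SE(ĥ²) ≥ 0.15, which no estimator can
  beat; replicated clones bring it under 0.06).
- Across-population and marker-density experiments use h² = 0.7 traits
  (typical for dry matter) and populations of 200–500 with family sizes
  ≥ 5, because accuracy comparisons at smaller sizes are dominated by
  family-level sampling noise rather than the effects under test.
- The marker-density fixture is 150 000 markers × 550 individuals in
  single precision; everything else runs in float64.
- The acceptance script runs a scaled study (2 000 markers,
  150 + 60 + 90 clones) so a full from-scratch reproduction takes seconds.

## Known limitations

- The profile-REML engine is O(n³) in the phenotyped block per fit; CV at
  n ≈ 1 000 with many repeats is minutes, not seconds.  No sparse or
  low-rank shortcuts are attempted.
- Allele-frequency genotypes conflate sequencing error with low-frequency
  dosage signal; no error-rate estimation is performed (filters are the
  only guard).
- The Gibbs sampler reports posterior means only; credible intervals are
  not collected (the REML path is the reference for uncertainty-free
  quantities, and nothing downstream consumes posterior spread).
- `adjust_environment` fits a single genotype variance for all panels
  jointly; heterogeneous residuals or G×E are out of scope by design.
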