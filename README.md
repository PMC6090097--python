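# tetrags

Genomic selection for autotetraploid crops (potato, foremost) from
genotyping-by-sequencing (GBS) data, without ever calling genotypes.

Shallow restriction-site sequencing gives too few reads per site to call a
tetraploid genotype (dosage 0–4), but the per-sample **alternative-read
fraction** `AF = AC_alt / (AC_ref + AC_alt)` is an unbiased, continuous
dosage proxy.  `tetrags` implements the analysis pipeline built on that
idea:

1. **genotypes** — read per-sample allele depths (VCF `FORMAT/AD`), form
   the allele-frequency genotype matrix, and filter markers/samples
   (coverage 5–60×, mean AF strictly inside (0.01, 0.99), ≤ 50 % missing
   per marker, samples > 70 % missing removed), plus a stringent
   high-completeness marker set and random marker/sample subsetting.
2. **phenotypes** — derived traits (dry matter from above/under-water
   weights, `DM% = 214·(Wa/(Wa−Ww) − 0.988)`; chip-score scale conversion)
   and environmental adjustment by the REML mixed model
   `y = μ + genotype (random) + year + location + e`, subtracting the fixed
   effects and averaging per genotype.
3. **grm** — the tetraploid-scaled VanRaden relationship matrix
   `Z_ik = (X_ik − p_k)·w_i` (missing → 0 = mean imputation),
   `G = ZZ′ / 0.25·Σ p_k(1−p_k)`, and PCA diagnostics on G — including the
   library-batch "parallel dislocation" artifact and its removal by
   stringent filtering.
4. **gblup** — GBLUP `y = 1μ + g + e`, `g ~ N(0, G σ²_g)`, with a
   deterministic profile-REML solver and a conjugate Gibbs sampler
   (default 12 000 iterations, 2 000 burn-in); predictions for
   unphenotyped individuals via the joint mixed-model equations; a
   SNP-BLUP ridge solver as the algebraic cross-check.
5. **evaluation** — repeated k-fold and leave-one-out cross-validation,
   across-population and combined-population prediction, accuracy
   `r(GEBV : y)` and bias slope β (observed regressed on predicted;
   β = 1 unbiased, β > 1 deflated predictions), and a tidy experiment grid
   over training set × prediction set × marker set × subsample.
6. **simulate** — a first-class generator for everything above: tetraploid
   founders, full-diallel and random-mating crosses (bivalent pairing, no
   double reduction), selected panels, additive traits with calibrated
   heritability and year/location effects, and GBS read depths with
   batch-specific marker dropout.

## Worked example

`examples/` contains one narrative script per capability.  Running
`python examples/04_gblup_prediction.py` simulates a three-panel study
(150 + 60 + 90 clones, 2 000 markers, h² = 0.7), pushes it through the full
pipeline and prints:

```
REML:  h2 = 0.46  (sigma2_g = 57.85, sigma2_e = 69.14)
Gibbs: h2 = 0.50; GEBV correlation with REML = 0.999

prediction experiments (r = accuracy, beta = bias slope):
  within MASPOT   r =  0.32  beta =  1.04  (n = 150)
  within DK       r =  0.28  beta =  0.94  (n = 60)
  within UK       r =  0.47  beta =  1.16  (n = 90)
  MASPOT -> UK    r =  0.26  beta =  1.12  (across founder pools: lower, as expected)
  combined -> MASPOT   r =  0.38  beta =  1.10
  combined -> DK       r =  0.42  beta =  0.92
  combined -> UK       r =  0.45  beta =  1.27
```

The two solvers agree on the breeding values (r = 0.999); prediction
across founder pools is clearly worse than within-population
cross-validation; and pooling the three panels into one training set keeps
(or improves) each panel's own accuracy — training populations can be
expanded additively.  `examples/03_grm_and_pca.py` shows the
batch-dropout PCA artifact shrinking ~3× under stringent filtering.

## Library layout

```
src/tetrags/
  genotypes.py    # AD/AF matrices, VCF I/O, marker & sample filters
  phenotypes.py   # dry matter, chip-score conversion, REML adjustment
  grm.py          # centred genotype matrix, tetraploid G, PCA
  gblup.py        # REML and Gibbs GBLUP, SNP-BLUP ridge oracle
  evaluation.py   # CV schemes, accuracy/bias, experiment grid
  simulate.py     # breeding-population / trait / GBS generator
  _mixed.py       # shared profile-REML engine
```

See `docs/methods.md` for the statistical model, its assumptions, the
numerical choices and the known limitations.
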