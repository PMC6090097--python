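"""Tetraploid genomic relationship matrix and PCA batch-artifact diagnosis.

G = ZZ' / (0.25 * sum p(1-p)) with Z the centred, missingness-weighted
allele-frequency scores; the 0.25 is the tetraploid adjustment (under
random-union equilibrium Var(AF) = p(1-p)/4, so the average diagonal of G
is ~1).  A population genotyped in two sequencing batches with different
dropped-locus sets shows a spurious parallel displacement in PCA under mean
imputation; stringent filtering removes it.
"""

import numpy as np

import tetrags as tg

# calibration: equilibrium population, clean frequencies
rng = np.random.default_rng(1)
dos = tg.hwe_dosages(rng.uniform(0.1, 0.9, 2000), 200, seed=2)
G = tg.grm_from_af(tg.allele_frequencies_from_dosages(dos))
print(f"equilibrium population: mean diag(G) = {np.diag(G.matrix).mean():.3f} "
      "(1.0 expected: the scaling denominator equals the genotype variance)")

# batch artifact: 6 individuals genotyped in both of two batches
f = tg.simulate_founders(10, 2000, seed=3)
base = tg.cross_diallel(f, 3, seed=4).subset(np.arange(80))
dups = base.sample_ids[:6]
pop = tg.with_duplicates(base, dups, suffix="_b2")
batches = {s: ("A" if i < 60 else "B") for i, s in enumerate(base.sample_ids)}
batches.update({s: "A" for s in dups})
batches.update({s + "_b2": "B" for s in dups})
ad = tg.simulate_gbs(pop, tg.GBSModel(batch_dropout={"A": 0.05, "B": 0.30}),
                     batch_assignment=batches, seed=5)
af, _ = tg.filter_markers(tg.compute_allele_frequencies(ad))


def mean_displacement(afm):
    res = tg.pca(tg.grm_from_af(afm), n_components=3)
    pos = {s: i for i, s in enumerate(res.sample_ids)}
    v = np.array([res.scores[pos[s]] - res.scores[pos[s + "_b2"]]
                  for s in dups if s in pos and s + "_b2" in pos])
    return np.linalg.norm(v, axis=1).mean(), res


disp_raw, res = mean_displacement(af)
print(f"\ndefault filters ({af.n_loci} markers): duplicate-pair PCA "
      f"displacement = {disp_raw:.3f}")
print(f"  leading variance proportions: "
      f"{np.round(res.variance_proportion, 3)}")
strict, _ = tg.stringent_marker_set(af)
disp_strict, _ = mean_displacement(strict)
print(f"stringent filters ({strict.n_loci} markers): displacement = "
      f"{disp_strict:.3f}  ({disp_raw / disp_strict:.1f}x smaller)")
print("the displacement is a mean-imputation artifact of batch-specific "
      "marker dropout, not real genetic divergence")
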