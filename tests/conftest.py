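import numpy as np
import pandas as pd
import pytest

import tetrags as tg


@pytest.fixture
def toy_af():
    """Hand-built 4-sample x 6-locus AF matrix exercising every filter rule.

    Locus layout (columns):
      L0: clean, mid-frequency           -> survives everything
      L1: mean AF 0.995                  -> fails the MAF rule
      L2: mean depth 2 (< 5)             -> fails the coverage rule
      L3: missing in 3 of 4 samples      -> fails marker missingness (0.75)
      L4: mean depth 80 (> 60)           -> fails the coverage rule
      L5: clean, mid-frequency           -> survives
    """
    af = np.array([
        [0.25, 1.00, 0.50, np.nan, 0.50, 0.40],
        [0.50, 1.00, 0.50, np.nan, 0.25, 0.60],
        [0.75, 0.99, np.nan, np.nan, 0.75, 0.50],
        [0.50, 0.99, 0.50, 0.50, 0.50, 0.50],
    ])
    depth = np.array([
        [10, 12, 2, 0, 80, 10],
        [12, 10, 2, 0, 80, 12],
        [8, 14, 0, 0, 80, 9],
        [11, 11, 2, 6, 80, 11],
    ])
    return tg.AlleleFrequencyMatrix(
        [f"S{i}" for i in range(4)], [f"1:{k+1}:A:C" for k in range(6)],
        af, depth)


@pytest.fixture(scope="session")
def sim_fixture():
    """Small simulated population shared across solver tests.

    Diallel offspring of 10 founders, 800 unlinked loci, additive trait with
    h2 = 0.5; allele-frequency genotypes are noise-free (dosage / 4) so the
    relationship matrix reflects the true genotypes.
    """
    founders = tg.simulate_founders(10, 800, seed=11)
    pop = tg.cross_diallel(founders, 4, seed=12)   # 45 crosses x 4 = 180
    pop = pop.subset(np.arange(150))
    arch = tg.TraitArchitecture(n_qtl=80, heritability=0.5)
    records, true_bv = tg.simulate_phenotypes(pop, arch, seed=13)
    af = tg.allele_frequencies_from_dosages(pop.dosages, sample_ids=pop.sample_ids)
    G = tg.grm_from_af(af)
    y = pd.Series(records["value"].to_numpy(), index=records["genotype_id"].to_numpy())
    return {"pop": pop, "af": af, "G": G, "y": y, "true_bv": true_bv}
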