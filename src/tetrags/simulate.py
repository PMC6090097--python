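"""Synthetic tetraploid breeding populations with GBS-style genotyping.

The generator mirrors the data-generating process the downstream analysis
assumes: autotetraploid founders crossed in a full diallel, purely additive
traits recorded across years and locations, and shallow restriction-site
sequencing that reports per-locus read depths rather than called genotypes.

Meiosis is modelled as random bivalent pairing without double reduction:
each gamete receives 2 of the parent's 4 homologous chromosomes, drawn
without replacement independently at every locus (loci are unlinked).
Library-preparation batches drop each locus entirely with a batch-specific
probability, which reproduces the panel-specific marker dropout that shallow
restriction-site genotyping shows in practice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import AlleleDepthMatrix

__all__ = [
    "FounderSet",
    "SimulatedPopulation",
    "TraitArchitecture",
    "GBSModel",
    "simulate_founders",
    "cross_diallel",
    "simulate_phenotypes",
    "simulate_gbs",
    "hwe_dosages",
    "truncation_select",
    "concat_populations",
    "with_duplicates",
    "simulate_study",
]

PLOIDY = 4

# the 6 unordered ways of drawing 2 of 4 homologous copies
_GAMETE_PAIRS = np.array(list(itertools.combinations(range(PLOIDY), 2)))


@dataclass
class FounderSet:
    """Tetraploid founder haplotypes.

    ``haplotypes`` is (n_founders, n_loci, 4) with 0/1 allele indicators per
    homologous copy; ``locus_af`` holds the sampling frequency each copy was
    drawn from.
    """

    haplotypes: np.ndarray
    locus_af: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[2] != PLOIDY:
            raise ValueError("haplotypes must be (n_founders, n_loci, 4)")
        if not self.ids:
            self.ids = [f"F{i:02d}" for i in range(self.n_founders)]

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def dosages(self) -> np.ndarray:
        """Founder allele dosage, 0..4 per founder x locus."""
        return self.haplotypes.sum(axis=2)

    def subset(self, founder_idx) -> "FounderSet":
        idx = np.asarray(founder_idx)
        return FounderSet(self.haplotypes[idx], self.locus_af,
                          ids=[self.ids[i] for i in idx])


@dataclass
class SimulatedPopulation:
    """A set of tetraploid individuals with integer allele dosages 0..4."""

    sample_ids: list[str]
    dosages: np.ndarray                   # (n, n_loci) uint8
    pedigree: pd.DataFrame                # columns mother, father, indexed by sample id
    population_label: str = "pop"

    def __post_init__(self):
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("dosages rows must match sample_ids")
        if self.dosages.min() < 0 or self.dosages.max() > PLOIDY:
            raise ValueError("dosages must lie in 0..4")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def subset(self, idx, label: str | None = None) -> "SimulatedPopulation":
        idx = np.asarray(idx)
        ids = [self.sample_ids[i] for i in idx]
        return SimulatedPopulation(ids, self.dosages[idx],
                                   self.pedigree.loc[ids],
                                   label or self.population_label)


@dataclass
class TraitArchitecture:
    """Additive trait: QTL effects plus year/location fixed effects.

    ``heritability`` is the narrow-sense h2 realised against the residual:
    the residual s.d. is calibrated from the realised genetic variance so
    that Var(g)/(Var(g)+Var(e)) equals the target.  With ``heritability=0``
    the trait is pure noise and ``residual_sd`` must be supplied.
    """

    n_qtl: int = 100
    effect_distribution: str = "normal"
    heritability: float = 0.5
    year_effects: dict = field(default_factory=dict)
    location_effects: dict = field(default_factory=dict)
    residual_sd: float | None = None
    mu: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must be in [0, 1]")
        if self.heritability == 0.0 and not (self.residual_sd and self.residual_sd > 0):
            raise ValueError("heritability 0 requires a positive residual_sd")


@dataclass
class GBSModel:
    """Read-depth model for genotyping-by-sequencing.

    Depths are Poisson with the given mean (the downstream coverage filter
    window is 5-60x, so the default mean of 12 produces loci inside and, in
    the tails, outside that window); alternative reads are binomial with
    success probability (d/4)(1-eps) + (1-d/4)eps for dosage d and
    sequencing error eps.  ``batch_dropout`` maps a library batch to the
    probability that a locus is entirely unobserved in that batch.
    """

    depth_mean: float = 12.0
    depth_distribution: str = "poisson"
    sequencing_error: float = 0.005
    batch_dropout: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if not 0.0 <= self.sequencing_error < 0.5:
            raise ValueError("sequencing_error must be in [0, 0.5)")
        for b, p in self.batch_dropout.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dropout probability for batch {b!r} not in [0, 1]")


def simulate_founders(n_founders: int, n_loci: int,
                      af_params=(0.05, 0.95), seed: int = 0) -> FounderSet:
    """Draw founder haplotypes with independent copies per locus.

    ``af_params`` is either a (low, high) tuple for uniform per-locus
    sampling frequencies or an explicit array of frequencies.  Each of the
    four homologous copies carries the alternative allele independently with
    the locus frequency.
    """
    if n_founders < 2 or n_loci < 1:
        raise ValueError("need n_founders >= 2 and n_loci >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(af_params, (tuple, list)) and len(af_params) == 2:
        af = rng.uniform(af_params[0], af_params[1], size=n_loci)
    else:
        af = np.broadcast_to(np.asarray(af_params, dtype=float), (n_loci,)).copy()
    if af.min() < 0 or af.max() > 1:
        raise ValueError("allele frequencies must lie in [0, 1]")
    hap = (rng.random((n_founders, n_loci, PLOIDY)) < af[None, :, None]).astype(np.uint8)
    return FounderSet(hap, af)


def _gametes(parent_haplotypes: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Alt-allele counts of n gametes from one parent (bivalent pairing).

    Drawing 2 of 4 copies without replacement is drawing one of the 6
    unordered copy-pairs uniformly; the per-locus alt count is therefore
    hypergeometric(4, dosage, 2).
    """
    n_loci = parent_haplotypes.shape[0]
    pair_idx = rng.integers(0, len(_GAMETE_PAIRS), size=(n, n_loci))
    pairs = _GAMETE_PAIRS[pair_idx]                      # (n, n_loci, 2)
    cols = np.arange(n_loci)
    return (parent_haplotypes[cols, pairs[..., 0]]
            + parent_haplotypes[cols, pairs[..., 1]]).astype(np.uint8)


def cross_diallel(founders: FounderSet, n_offspring_per_cross: int,
                  selfing_allowed: bool = False, seed: int = 0,
                  label: str = "D") -> SimulatedPopulation:
    """Full-diallel cross: every unordered parent pair produces offspring.

    Offspring dosage is the union of one gamete from each parent.
    """
    if n_offspring_per_cross < 1:
        raise ValueError("n_offspring_per_cross must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(founders.n_founders), 2))
    if selfing_allowed:
        pairs += [(i, i) for i in range(founders.n_founders)]
    dosage_blocks, mothers, fathers = [], [], []
    for i, j in pairs:
        gm = _gametes(founders.haplotypes[i], n_offspring_per_cross, rng)
        gf = _gametes(founders.haplotypes[j], n_offspring_per_cross, rng)
        dosage_blocks.append(gm + gf)
        mothers += [founders.ids[i]] * n_offspring_per_cross
        fathers += [founders.ids[j]] * n_offspring_per_cross
    dosages = np.vstack(dosage_blocks)
    ids = [f"{label}{k:05d}" for k in range(dosages.shape[0])]
    ped = pd.DataFrame({"mother": mothers, "father": fathers}, index=ids)
    return SimulatedPopulation(ids, dosages, ped, population_label=label)


def random_mating(pop: SimulatedPopulation, n_offspring: int, seed: int = 0,
                  label: str = "RM") -> SimulatedPopulation:
    """Offspring of random (distinct) parent pairs from an existing population.

    Because loci are unlinked, a gamete's alt count at a locus depends only
    on the parent's dosage and is hypergeometric(4, dosage, 2); phase never
    needs to be tracked beyond the founders.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    if pop.n < 2:
        raise ValueError("need at least 2 potential parents")
    rng = np.random.default_rng(seed)
    mothers = rng.integers(0, pop.n, size=n_offspring)
    fathers = (mothers + rng.integers(1, pop.n, size=n_offspring)) % pop.n
    dm = pop.dosages[mothers].astype(np.int64)
    df = pop.dosages[fathers].astype(np.int64)
    gam_m = rng.hypergeometric(dm, PLOIDY - dm, 2)
    gam_f = rng.hypergeometric(df, PLOIDY - df, 2)
    dosages = (gam_m + gam_f).astype(np.uint8)
    ids = [f"{label}{k:05d}" for k in range(n_offspring)]
    ped = pd.DataFrame({"mother": [pop.sample_ids[i] for i in mothers],
                        "father": [pop.sample_ids[i] for i in fathers]}, index=ids)
    return SimulatedPopulation(ids, dosages, ped, population_label=label)


def simulate_phenotypes(pop: SimulatedPopulation, arch: TraitArchitecture,
                        design: pd.DataFrame | None = None, seed: int = 0,
                        trait: str = "trait",
                        calibration_groups: dict | None = None):
    """Phenotype records ``mu + g_i + year_j + location_k + e`` plus true BVs.

    ``design`` assigns records: a DataFrame with columns genotype_id, year,
    location (one row per record).  Default: one record per individual in a
    single environment.  Returns ``(records, true_bv)`` where records has
    columns genotype_id, trait, value, year, location and true_bv is a
    Series of centred breeding values indexed by sample id.

    ``calibration_groups`` (sample id -> group label) makes the residual
    calibration use the size-weighted mean of the *within-group* genetic
    variances instead of the total.  For a multi-panel population this keeps
    the heritability a within-population quantity: otherwise genetic
    divergence between panels would silently deflate it.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = pd.DataFrame({"genotype_id": pop.sample_ids,
                               "year": "Y1", "location": "L1"})
    missing = set(design["genotype_id"]) - set(pop.sample_ids)
    if missing:
        raise ValueError(f"design references unknown genotypes: {sorted(missing)[:3]}")
    if arch.n_qtl > pop.n_loci:
        raise ValueError("n_qtl exceeds the number of loci")

    qtl = rng.choice(pop.n_loci, size=arch.n_qtl, replace=False)
    if arch.effect_distribution == "normal":
        effects = rng.normal(0.0, 1.0, size=arch.n_qtl)
    elif arch.effect_distribution == "laplace":
        effects = rng.laplace(0.0, 1.0, size=arch.n_qtl)
    else:
        raise ValueError(f"unknown effect distribution {arch.effect_distribution!r}")

    g = pop.dosages[:, qtl].astype(float) @ effects
    g -= g.mean()
    if arch.heritability == 0.0:
        g = np.zeros_like(g)
        sigma_e = float(arch.residual_sd)
    elif arch.heritability == 1.0:
        sigma_e = 0.0
    else:
        if calibration_groups is None:
            var_g = float(g.var())
        else:
            labels = pd.Series([calibration_groups.get(s, "_") for s in pop.sample_ids])
            var_g = float(pd.Series(g).groupby(labels).var(ddof=0)
                          .mul(labels.value_counts(normalize=True)).sum())
        if var_g == 0.0:
            raise ValueError("realised genetic variance is zero; cannot calibrate h2")
        sigma_e = float(np.sqrt(var_g * (1.0 - arch.heritability) / arch.heritability))

    bv = pd.Series(g, index=pop.sample_ids, name="true_bv")
    idx = pd.Index(pop.sample_ids).get_indexer(design["genotype_id"])
    year_eff = design["year"].map(lambda yy: arch.year_effects.get(yy, 0.0)).to_numpy(float)
    loc_eff = design["location"].map(lambda ll: arch.location_effects.get(ll, 0.0)).to_numpy(float)
    noise = rng.normal(0.0, sigma_e, size=len(design)) if sigma_e > 0 else 0.0
    values = arch.mu + g[idx] + year_eff + loc_eff + noise
    records = pd.DataFrame({
        "genotype_id": design["genotype_id"].to_numpy(),
        "trait": trait,
        "value": values,
        "year": design["year"].to_numpy(),
        "location": design["location"].to_numpy(),
    })
    return records, bv


def simulate_gbs(pop: SimulatedPopulation, model: GBSModel | None = None,
                 batch_assignment: dict | None = None, seed: int = 0) -> AlleleDepthMatrix:
    """GBS read depths for a population.

    ``batch_assignment`` maps sample id -> batch label; unlisted samples go
    to batch "B0".  For every (batch, locus) the locus is dropped entirely
    (depth 0 for all samples of the batch) with the batch's dropout
    probability; otherwise depth is Poisson and alternative reads binomial
    given dosage and sequencing error.
    """
    model = model or GBSModel()
    rng = np.random.default_rng(seed)
    n, L = pop.dosages.shape
    batch_assignment = batch_assignment or {}
    batches = np.array([batch_assignment.get(s, "B0") for s in pop.sample_ids])

    if model.depth_distribution != "poisson":
        raise ValueError(f"unknown depth distribution {model.depth_distribution!r}")
    depth = rng.poisson(model.depth_mean, size=(n, L)).astype(np.int64)
    for batch in pd.unique(batches):
        p_drop = model.batch_dropout.get(batch, 0.0)
        if p_drop > 0:
            dropped = rng.random(L) < p_drop
            depth[np.ix_(batches == batch, dropped)] = 0

    eps = model.sequencing_error
    p_alt = (pop.dosages / PLOIDY) * (1.0 - eps) + (1.0 - pop.dosages / PLOIDY) * eps
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    locus_ids = [f"1:{k + 1}:A:C" for k in range(L)]
    return AlleleDepthMatrix(list(pop.sample_ids), locus_ids,
                             ref.astype(np.int64), alt.astype(np.int64))


def hwe_dosages(af, n: int, seed: int = 0) -> np.ndarray:
    """Random-union tetraploid dosages: Binomial(4, p) per individual x locus.

    This is the equilibrium dosage distribution under random mating without
    double reduction (mean 4p, variance 4p(1-p)).
    """
    rng = np.random.default_rng(seed)
    af = np.asarray(af, dtype=float)
    return rng.binomial(PLOIDY, af, size=(n, af.size)).astype(np.uint8)


def truncation_select(pop: SimulatedPopulation, scores, n_keep: int,
                      highest: bool = True, label: str | None = None) -> SimulatedPopulation:
    """Keep the n_keep individuals with the highest (or lowest) scores.

    Emulates a selected breeding panel: candidates are ranked on a trait
    score and only the tail is retained.
    """
    scores = np.asarray(pd.Series(scores).reindex(pop.sample_ids)
                        if not isinstance(scores, np.ndarray) else scores, dtype=float)
    if scores.size != pop.n:
        raise ValueError("scores must align with the population")
    if not 1 <= n_keep <= pop.n:
        raise ValueError("n_keep out of range")
    order = np.argsort(scores)
    idx = order[-n_keep:] if highest else order[:n_keep]
    return pop.subset(np.sort(idx), label=label)


def concat_populations(pops: list[SimulatedPopulation]) -> SimulatedPopulation:
    """Stack populations sharing one locus set; sample ids must be unique."""
    ids = [s for p in pops for s in p.sample_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids across populations")
    dosages = np.vstack([p.dosages for p in pops])
    ped = pd.concat([p.pedigree for p in pops])
    return SimulatedPopulation(ids, dosages, ped, population_label="combined")


def with_duplicates(pop: SimulatedPopulation, ids: list[str],
                    suffix: str = "_dup") -> SimulatedPopulation:
    """Append genetic copies of the given individuals under new sample ids.

    Used to emulate varieties genotyped independently in two library
    batches: the copies share dosages but receive independent sequencing
    draws downstream.
    """
    idx = [pop.sample_ids.index(s) for s in ids]
    new_ids = pop.sample_ids + [s + suffix for s in ids]
    dosages = np.vstack([pop.dosages, pop.dosages[idx]])
    extra = pop.pedigree.loc[ids].set_axis([s + suffix for s in ids])
    ped = pd.concat([pop.pedigree, extra])
    return SimulatedPopulation(new_ids, dosages, ped, pop.population_label)


def simulate_study(
    n_loci: int = 20_000,
    n_founders: int = 18,
    maspot_size: int = 755,
    dk_size: int = 80,
    uk_size: int = 290,
    n_uk_founders: int = 12,
    uk_founder_overlap: int = 2,
    n_qtl: int = 200,
    heritability: float = 0.5,
    selection_fraction: float = 0.5,
    n_shared_duplicates: int = 5,
    gbs_model: GBSModel | None = None,
    seed: int = 0,
) -> dict:
    """Emulate the three-panel study design end to end.

    Builds a large unselected full-diallel population ("MASPOT"-like), a
    small selected panel from the same founder pool ("DK"-like) and a larger
    selected panel from a mostly distinct founder pool ("UK"-like), records
    multi-year/multi-location phenotypes for one additive trait, and
    sequences everything with one GBS library batch per panel (plus
    duplicate genotyping of a few shared varieties in both test panels).

    Returns a dict with keys ``founders``, ``populations`` (dict of label ->
    SimulatedPopulation), ``combined`` (all panels stacked, duplicates
    included), ``records`` (phenotype table), ``true_bv`` (Series),
    ``depths`` (AlleleDepthMatrix), ``batches`` (sample id -> batch) and
    ``duplicate_pairs`` (list of (dk_id, uk_id) for shared varieties).
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    total_founders = n_founders + n_uk_founders - uk_founder_overlap
    founders = simulate_founders(total_founders, n_loci, seed=seeds[0])
    f_maspot = founders.subset(np.arange(n_founders))
    f_uk = founders.subset(np.arange(n_founders - uk_founder_overlap, total_founders))

    n_crosses = n_founders * (n_founders - 1) // 2
    per_cross = int(np.ceil(maspot_size / n_crosses))
    maspot = cross_diallel(f_maspot, per_cross, seed=seeds[1], label="M")
    maspot = maspot.subset(np.arange(maspot_size), label="MASPOT")

    # Selected panels: oversample offspring, keep the best on a pilot trait.
    n_dk_cand = int(np.ceil(dk_size / selection_fraction))
    per_cross_dk = int(np.ceil(n_dk_cand / n_crosses))
    dk_cand = cross_diallel(f_maspot, per_cross_dk, seed=seeds[2], label="K")
    pilot_arch = TraitArchitecture(n_qtl=n_qtl, heritability=heritability)
    _, dk_bv = simulate_phenotypes(dk_cand, pilot_arch, seed=seeds[2])
    dk = truncation_select(dk_cand, dk_bv.to_numpy(), n_dk_cand // 2, label="DK")
    dk = dk.subset(np.arange(dk_size), label="DK")

    n_uk_crosses = n_uk_founders * (n_uk_founders - 1) // 2
    n_uk_cand = int(np.ceil(uk_size / selection_fraction))
    per_cross_uk = int(np.ceil(n_uk_cand / n_uk_crosses))
    uk_cand = cross_diallel(f_uk, per_cross_uk, seed=seeds[3], label="U")
    _, uk_bv = simulate_phenotypes(uk_cand, pilot_arch, seed=seeds[3])
    uk = truncation_select(uk_cand, uk_bv.to_numpy(), n_uk_cand // 2, label="UK")
    uk = uk.subset(np.arange(uk_size), label="UK")

    combined = concat_populations([maspot, dk, uk])

    # Shared varieties genotyped in both test-panel batches.
    duplicate_pairs = []
    if n_shared_duplicates > 0:
        shared = dk.sample_ids[:n_shared_duplicates]
        combined = with_duplicates(combined, shared, suffix="_uklib")
        duplicate_pairs = [(s, s + "_uklib") for s in shared]

    arch = TraitArchitecture(
        n_qtl=n_qtl, heritability=heritability,
        year_effects={"2012": -0.5, "2013": 0.0, "2014": 0.4},
        location_effects={"Vandel": 0.0, "Cambridge": 0.8, "York": -0.3},
    )
    # UK trials are crossed over sites x years so that year and location
    # effects stay separately estimable in the joint adjustment model
    env = {"MASPOT": [("2013", "Vandel"), ("2014", "Vandel")],
           "DK": [("2013", "Vandel"), ("2014", "Vandel")],
           "UK": [("2012", "Cambridge"), ("2012", "York"),
                  ("2013", "Cambridge"), ("2013", "York")]}
    rows = []
    for label, pop in (("MASPOT", maspot), ("DK", dk), ("UK", uk)):
        for year, loc in env[label]:
            rows.append(pd.DataFrame({"genotype_id": pop.sample_ids,
                                      "year": year, "location": loc}))
    design = pd.concat(rows, ignore_index=True)
    no_dup = concat_populations([maspot, dk, uk])
    pop_of = {s: lab for lab, p in (("MASPOT", maspot), ("DK", dk), ("UK", uk))
              for s in p.sample_ids}
    records, true_bv = simulate_phenotypes(no_dup, arch, design=design,
                                           seed=seeds[4], trait="dry_matter",
                                           calibration_groups=pop_of)

    batches = {}
    for s in maspot.sample_ids:
        batches[s] = "lib_maspot"
    for s in dk.sample_ids:
        batches[s] = "lib_dk"
    for s in uk.sample_ids:
        batches[s] = "lib_uk"
    for _, dup in duplicate_pairs:
        batches[dup] = "lib_uk"

    gbs = gbs_model or GBSModel(batch_dropout={"lib_maspot": 0.10,
                                               "lib_dk": 0.15,
                                               "lib_uk": 0.20})
    depths = simulate_gbs(combined, gbs, batch_assignment=batches, seed=seeds[5])

    return {
        "founders": founders,
        "populations": {"MASPOT": maspot, "DK": dk, "UK": uk},
        "combined": combined,
        "records": records,
        "true_bv": true_bv,
        "depths": depths,
        "batches": batches,
        "duplicate_pairs": duplicate_pairs,
    }
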