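"""Tetraploid-scaled genomic relationship matrix and PCA diagnostics.

The marker score is the allele-frequency genotype X_ik in [0, 1].  Columns
are centred at the locus mean p_k, rows are inflated by the VanRaden
missing-data weight w_i, missing cells are set to exactly zero (mean
imputation after centring), and the cross-product is globally scaled:

    Z_ik = (X_ik - p_k) * w_i
    G    = Z Z' / (0.25 * sum_k p_k (1 - p_k))

Under random-union equilibrium the allele-frequency genotype has variance
p(1-p)/4 per locus, so 0.25 * sum p(1-p) equals the expected average
diagonal of Z Z' — the 0.25 carries the tetraploid adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencyMatrix

__all__ = [
    "CenteredGenotypeMatrix",
    "GenomicRelationshipMatrix",
    "PCAResult",
    "locus_means",
    "missingness_weights",
    "center_genotypes",
    "build_grm",
    "grm_from_af",
    "pca",
]


@dataclass
class CenteredGenotypeMatrix:
    """Centred, missingness-weighted marker scores; missing cells are 0."""

    sample_ids: list[str]
    locus_ids: list[str]
    Z: np.ndarray
    locus_means: np.ndarray       # p_k
    sample_weights: np.ndarray    # w_i

    @property
    def scaling_denominator(self) -> float:
        """0.25 * sum_k p_k (1 - p_k), the global tetraploid scaling."""
        p = self.locus_means
        return float(0.25 * np.sum(p * (1.0 - p)))


@dataclass
class GenomicRelationshipMatrix:
    """Symmetric individuals x individuals relationship matrix."""

    sample_ids: list[str]
    matrix: np.ndarray
    scaling_denominator: float

    def __post_init__(self):
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("G must be square over sample_ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("G must be symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, ids: list[str]) -> "GenomicRelationshipMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in ids])
        return GenomicRelationshipMatrix(list(ids), self.matrix[np.ix_(idx, idx)],
                                         self.scaling_denominator)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path) -> "GenomicRelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(float), np.nan)


@dataclass
class PCAResult:
    """Leading principal-component scores of the relationship matrix."""

    sample_ids: list[str]
    scores: np.ndarray                # n x n_components
    variance_proportion: np.ndarray   # per retained component


def locus_means(af: AlleleFrequencyMatrix) -> np.ndarray:
    """Mean allele frequency p_k per locus, over non-missing cells only."""
    n_obs = (~af.missing).sum(axis=0)
    if np.any(n_obs == 0):
        bad = [af.locus_ids[i] for i in np.flatnonzero(n_obs == 0)[:5]]
        raise ValueError(f"loci with no observed cells: {bad}")
    with np.errstate(invalid="ignore"):
        return np.nanmean(af.af, axis=0)


def missingness_weights(af: AlleleFrequencyMatrix, p: np.ndarray) -> np.ndarray:
    """VanRaden missing-data correction w_i per sample.

    w_i = sum_k p_k(1-p_k) over all loci / the same sum over the loci
    observed in sample i; w_i = 1 for complete samples and grows with the
    heterozygosity that the sample's missing loci would have contributed.
    """
    het = p * (1.0 - p)
    total = float(het.sum())
    observed = (~af.missing) @ het
    if np.any(observed <= 0):
        bad = [af.sample_ids[i] for i in np.flatnonzero(observed <= 0)[:5]]
        raise ValueError(f"samples with no informative observed loci: {bad}")
    return total / observed


def center_genotypes(af: AlleleFrequencyMatrix, p: np.ndarray | None = None,
                     w: np.ndarray | None = None) -> CenteredGenotypeMatrix:
    """Z_ik = (X_ik - p_k) * w_i, with missing cells set to exactly zero."""
    if p is None:
        p = locus_means(af)
    if w is None:
        w = missingness_weights(af, p)
    if p.size != af.n_loci or w.size != af.n_samples:
        raise ValueError("p/w dimensions inconsistent with the AF matrix")
    dt = af.af.dtype if np.issubdtype(af.af.dtype, np.floating) else np.float64
    Z = (af.af - p[None, :].astype(dt)) * w[:, None].astype(dt)
    Z[af.missing] = 0.0
    return CenteredGenotypeMatrix(list(af.sample_ids), list(af.locus_ids),
                                  Z, np.asarray(p, float), np.asarray(w, float))


def build_grm(Z: CenteredGenotypeMatrix) -> GenomicRelationshipMatrix:
    """G = Z Z' / (0.25 * sum p_k (1 - p_k)), individuals x individuals."""
    if len(Z.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    denom = Z.scaling_denominator
    if denom <= 0:
        raise ValueError("scaling denominator is zero: no polymorphic loci")
    G = np.asarray((Z.Z @ Z.Z.T), dtype=np.float64) / denom
    G = 0.5 * (G + G.T)
    return GenomicRelationshipMatrix(list(Z.sample_ids), G, denom)


def grm_from_af(af: AlleleFrequencyMatrix) -> GenomicRelationshipMatrix:
    """Convenience chain: locus means -> weights -> centring -> G."""
    return build_grm(center_genotypes(af))


def pca(G: GenomicRelationshipMatrix, n_components: int = 3,
        center: bool = True) -> PCAResult:
    """Principal components of the relationship matrix.

    Treats G as an observations x variables data matrix (rows = samples),
    optionally column-centres it, and takes the SVD — the convention of
    standard PCA tooling applied to a relationship matrix.
    """
    if not 1 <= n_components <= G.n:
        raise ValueError("n_components out of range")
    A = G.matrix - G.matrix.mean(axis=0, keepdims=True) if center else G.matrix
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    var = s**2 / max(G.n - 1, 1)
    total = var.sum()
    prop = var / total if total > 0 else np.zeros_like(var)
    # sign convention: largest-magnitude loading of each component positive
    scores = U * s
    for j in range(n_components):
        k = np.argmax(np.abs(U[:, j]))
        if U[k, j] < 0:
            scores[:, j] = -scores[:, j]
    return PCAResult(list(G.sample_ids), scores[:, :n_components],
                     prop[:n_components])
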