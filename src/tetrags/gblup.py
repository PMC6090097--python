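"""GBLUP: breeding-value prediction from a genomic relationship matrix.

Model: y = 1 mu + g + e with g ~ N(0, G sigma2_g), e ~ N(0, I sigma2_e).
Two solvers are provided.  The REML path profiles the restricted likelihood
over the variance ratio on the eigenstructure of the phenotyped block of G
and is fully deterministic.  The Gibbs path is a conjugate sampler over
(mu, g, sigma2_g, sigma2_e) with scaled-inverse-chi-square variance priors,
mirroring the Bayesian machinery commonly used for whole-genome regression;
posterior means are reported.  Both paths return GEBVs for every individual
in G, phenotyped or not, through the joint mixed-model equations.

A marker-effect ridge solver (SNP-BLUP) is included: with G = Z Z' / c the
two parameterisations are algebraically identical at shrinkage lambda =
c * sigma2_e / sigma2_g, which makes it an independent oracle for the GBLUP
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mixed import profile_reml
from .grm import CenteredGenotypeMatrix, GenomicRelationshipMatrix

__all__ = ["SolverConfig", "GBLUPFit", "fit_gblup", "predict_unphenotyped", "snp_blup"]

# A smallest eigenvalue below -_PSD_HARD * eigmax means G is genuinely not
# PSD; anything in (-_PSD_HARD, _PSD_SOFT) * eigmax is numerical round-off
# (single-precision cross-products land here) and is repaired by a logged
# diagonal jitter.
_PSD_HARD = 1e-5
_PSD_SOFT = 1e-8
_JITTER = 1e-8


@dataclass
class SolverConfig:
    """Solver choice and sampler settings.

    ``var_ratio`` fixes delta = sigma2_e/sigma2_g instead of estimating it
    (REML path only); used for the SNP-BLUP equivalence.  Gibbs priors are
    scaled-inverse-chi-square with ``prior_df`` degrees of freedom and scales
    set so the prior mode splits the phenotypic variance by
    ``prior_genetic_split``.
    """

    method: str = "REML"           # "REML" or "Gibbs"
    n_iter: int = 12_000
    burn_in: int = 2_000
    prior_df: float = 5.0
    prior_genetic_split: float = 0.5
    seed: int = 0
    var_ratio: float | None = None

    def __post_init__(self):
        if self.method not in ("REML", "Gibbs"):
            raise ValueError("method must be 'REML' or 'Gibbs'")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")


@dataclass
class GBLUPFit:
    """One fitted GBLUP model: variance components, intercept and GEBVs."""

    mu: float
    sigma2_g: float
    sigma2_e: float
    gebv: pd.Series                # indexed by every id in G
    solver: str
    train_ids: list[str] = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return float(self.sigma2_g / tot) if tot > 0 else 0.0

    def to_json(self) -> str:
        import json
        return json.dumps({"mu": self.mu, "sigma2_g": self.sigma2_g,
                           "sigma2_e": self.sigma2_e, "h2": self.h2,
                           "solver": self.solver, "n_train": len(self.train_ids),
                           "settings": self.settings}, indent=2)


def _check_psd(G: np.ndarray) -> np.ndarray:
    """Validate PSD-ness; jitter the diagonal when borderline."""
    ev = np.linalg.eigvalsh(G)
    emax = float(ev[-1]) if ev[-1] > 0 else 1.0
    if ev[0] < -_PSD_HARD * emax:
        raise ValueError(f"G is not positive semi-definite (eigmin={ev[0]:.3e})")
    if ev[0] < _PSD_SOFT * emax:
        bump = max(0.0, -float(ev[0])) + _JITTER * emax
        return G + bump * np.eye(G.shape[0])
    return G


def _as_series(y, G: GenomicRelationshipMatrix) -> pd.Series:
    if not isinstance(y, pd.Series):
        raise TypeError("y must be a pandas Series indexed by sample id")
    unknown = set(y.index) - set(G.sample_ids)
    if unknown:
        raise ValueError(f"phenotyped ids absent from G: {sorted(unknown)[:3]}")
    if y.index.has_duplicates:
        raise ValueError("duplicate ids in y")
    return y.astype(float)


def fit_gblup(y: pd.Series, G: GenomicRelationshipMatrix,
              config: SolverConfig | None = None) -> GBLUPFit:
    """Fit GBLUP and return GEBVs for every individual in G.

    ``y`` holds adjusted phenotypes for a subset of G's individuals
    (practically one wants >= 10; two is the hard minimum).  Individuals
    of G without a phenotype are predicted through the joint equations —
    their records are simply missing, no phenotype of theirs enters the fit.
    """
    config = config or SolverConfig()
    y = _as_series(y, G)
    if y.size < 2:
        raise ValueError("need at least 2 phenotyped individuals")
    pos = {s: i for i, s in enumerate(G.sample_ids)}
    t_idx = np.array([pos[s] for s in y.index])
    Gm = _check_psd(G.matrix)
    Gtt = Gm[np.ix_(t_idx, t_idx)]
    yv = y.to_numpy()

    if config.method == "REML":
        fit = profile_reml(yv, np.ones((yv.size, 1)), Gtt, delta=config.var_ratio)
        mu = float(fit.beta[0])
        if fit.sigma2_g == 0.0 or not np.isfinite(fit.delta):
            gebv = np.zeros(G.n)
        else:
            A = Gtt + fit.delta * np.eye(yv.size)
            resid_sol = np.linalg.solve(A, yv - mu)
            gebv = Gm[:, t_idx] @ resid_sol
        return GBLUPFit(mu=mu, sigma2_g=fit.sigma2_g, sigma2_e=fit.sigma2_e,
                        gebv=pd.Series(gebv, index=list(G.sample_ids)),
                        solver="REML", train_ids=list(y.index),
                        settings={"var_ratio": config.var_ratio})
    return _gibbs(yv, t_idx, Gm, list(G.sample_ids), list(y.index), config)


def _sample_scaled_inv_chi2(rng, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


def _gibbs(y: np.ndarray, t_idx: np.ndarray, Gm: np.ndarray,
           all_ids: list[str], train_ids: list[str],
           config: SolverConfig) -> GBLUPFit:
    """Conjugate Gibbs sampler in the eigenbasis of G.

    g = W alpha with W = U sqrt(D) from the eigendecomposition of the full
    G, so alpha ~ N(0, sigma2_g I).  When every individual is phenotyped
    W'W is diagonal and each alpha component updates in O(1); otherwise the
    alpha block is sampled jointly via a Cholesky solve.
    """
    rng = np.random.default_rng(config.seed)
    n = y.size
    d, U = np.linalg.eigh(Gm)
    keep = d > max(1e-12, 1e-10 * d.max())
    d, U = d[keep], U[:, keep]
    W_all = U * np.sqrt(d)
    W = W_all[t_idx]
    r = d.size
    diagonal = (len(all_ids) == n) and np.array_equal(np.sort(t_idx), np.arange(n))

    vy = float(np.var(y))
    if vy == 0:
        vy = 1.0
    df0 = config.prior_df
    s_g = config.prior_genetic_split * vy * (df0 + 2.0) / df0
    s_e = (1.0 - config.prior_genetic_split) * vy * (df0 + 2.0) / df0

    mu = float(y.mean())
    sigma2_g = config.prior_genetic_split * vy
    sigma2_e = (1.0 - config.prior_genetic_split) * vy
    alpha = np.zeros(r)

    if diagonal:
        Wty = W.T @ y
        Wt1 = W.T @ np.ones(n)
    n_kept = config.n_iter - config.burn_in
    # GEBVs accumulate the conditional mean of alpha (Rao-Blackwellised
    # posterior mean: lower Monte-Carlo variance than averaging the draws)
    alpha_mean_sum = np.zeros(r)
    mu_sum = 0.0
    s2g_sum = 0.0
    s2e_sum = 0.0

    for it in range(config.n_iter):
        # alpha | .
        if diagonal:
            prec = d / sigma2_e + 1.0 / sigma2_g
            mean = (Wty - mu * Wt1) / sigma2_e / prec
            alpha = mean + rng.standard_normal(r) / np.sqrt(prec)
        else:
            C = (W.T @ W) / sigma2_e + np.eye(r) / sigma2_g
            L = np.linalg.cholesky(C)
            rhs = W.T @ (y - mu) / sigma2_e
            mean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
            z = rng.standard_normal(r)
            alpha = mean + np.linalg.solve(L.T, z)
        g_train = W @ alpha
        # mu | .  (flat prior)
        resid0 = y - g_train
        mu = float(rng.normal(resid0.mean(), np.sqrt(sigma2_e / n)))
        # variances | .
        e = resid0 - mu
        sigma2_e = _sample_scaled_inv_chi2(
            rng, df0 + n, (df0 * s_e + float(e @ e)) / (df0 + n))
        sigma2_g = _sample_scaled_inv_chi2(
            rng, df0 + r, (df0 * s_g + float(alpha @ alpha)) / (df0 + r))
        if not (np.isfinite(sigma2_e) and np.isfinite(sigma2_g)):
            raise RuntimeError(f"Gibbs sampler diverged at iteration {it}")
        if it >= config.burn_in:
            alpha_mean_sum += mean
            mu_sum += mu
            s2g_sum += sigma2_g
            s2e_sum += sigma2_e

    gebv = W_all @ (alpha_mean_sum / n_kept)
    return GBLUPFit(mu=mu_sum / n_kept, sigma2_g=s2g_sum / n_kept,
                    sigma2_e=s2e_sum / n_kept,
                    gebv=pd.Series(gebv, index=all_ids), solver="Gibbs",
                    train_ids=train_ids,
                    settings={"n_iter": config.n_iter, "burn_in": config.burn_in,
                              "seed": config.seed})


def predict_unphenotyped(y_train: pd.Series, G: GenomicRelationshipMatrix,
                         test_ids: list[str],
                         config: SolverConfig | None = None) -> pd.Series:
    """GEBVs for unphenotyped individuals from a training-set fit.

    ``test_ids`` must be disjoint from the training ids; no test phenotype
    enters the fit (the fit never sees one).
    """
    overlap = set(y_train.index) & set(test_ids)
    if overlap:
        raise ValueError(f"train and test ids overlap: {sorted(overlap)[:3]}")
    unknown = set(test_ids) - set(G.sample_ids)
    if unknown:
        raise ValueError(f"test ids absent from G: {sorted(unknown)[:3]}")
    fit = fit_gblup(y_train, G, config)
    return fit.gebv.loc[list(test_ids)]


def snp_blup(y: pd.Series, Z: CenteredGenotypeMatrix, lam: float):
    """Ridge regression on centred marker scores (SNP-BLUP).

    Solves marker effects b = Z_t'(Z_t Z_t' + lam I)^-1 (y - mu_hat) with
    mu_hat the GLS intercept under the same covariance, and returns
    ``(effects, gebv)`` where gebv = Z b covers every sample in Z.  With
    G = Z Z' / c this equals the REML-path GBLUP GEBVs at fixed variance
    ratio delta = lam / c.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    ids = list(Z.sample_ids)
    pos = {s: i for i, s in enumerate(ids)}
    t_idx = np.array([pos[s] for s in y.index])
    Zt = Z.Z[t_idx]
    K = Zt @ Zt.T
    A = K + lam * np.eye(Zt.shape[0])
    if lam == 0.0 and np.linalg.matrix_rank(A) < A.shape[0]:
        raise ValueError("singular system with lam=0")
    yv = y.to_numpy(float)
    ones = np.ones(yv.size)
    Ainv1 = np.linalg.solve(A, ones)
    Ainvy = np.linalg.solve(A, yv)
    mu = float(ones @ Ainvy / (ones @ Ainv1))
    b = Zt.T @ np.linalg.solve(A, yv - mu)
    gebv = pd.Series(Z.Z @ b, index=ids)
    effects = pd.Series(b, index=list(Z.locus_ids))
    return effects, gebv
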