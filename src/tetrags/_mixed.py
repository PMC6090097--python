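"""Profile-REML machinery for single-random-effect mixed models.

Both the environmental phenotype adjustment (genotype as the random effect,
covariance sigma2_g * ZZ') and GBLUP (breeding values with covariance
sigma2_g * G) are instances of

    y = X beta + u + e,   u ~ N(0, sigma2_g * K),   e ~ N(0, sigma2_e * I)

with a single relative variance to estimate.  The restricted likelihood is
profiled over the ratio delta = sigma2_e / sigma2_g on the eigenstructure of
K projected onto the orthogonal complement of the fixed-effect design, which
makes the optimisation exactly one-dimensional and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["MixedModelFit", "profile_reml"]

# delta is searched on a log10 grid first, then refined by bounded Brent
# between the grid neighbours of the best point.
_LOG10_DELTA_GRID = np.linspace(-6.0, 6.0, 61)


@dataclass
class MixedModelFit:
    """Result of a profile-REML fit of a one-random-effect mixed model."""

    beta: np.ndarray          # fixed-effect estimates (GLS at the REML optimum)
    sigma2_g: float           # random-effect variance component
    sigma2_e: float           # residual variance component
    delta: float              # sigma2_e / sigma2_g at the optimum (inf if sigma2_g = 0)
    reml_loglik: float        # restricted log-likelihood at the optimum (up to a constant)

    @property
    def heritability(self) -> float:
        """sigma2_g / (sigma2_g + sigma2_e); 0 for a degenerate fit."""
        tot = self.sigma2_g + self.sigma2_e
        return float(self.sigma2_g / tot) if tot > 0 else 0.0


def _restricted_components(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """Rotate y into the error contrasts of X and diagonalise K there.

    Returns (xi, eta): eigenvalues of Q2' K Q2 and the rotated data
    eta = U' Q2' y, such that eta_s ~ N(0, sigma2_g * (xi_s + delta))
    independently.  The likelihood of eta is exactly the restricted
    likelihood of y.
    """
    n, q = X.shape
    Qfull, R = np.linalg.qr(X, mode="complete")
    if np.min(np.abs(np.diag(R[:q, :q]))) < 1e-10 * max(1.0, np.abs(R).max()):
        raise ValueError("fixed-effect design matrix is rank deficient")
    Q2 = Qfull[:, q:]
    M = Q2.T @ K @ Q2
    M = 0.5 * (M + M.T)
    xi, U = np.linalg.eigh(M)
    xi = np.clip(xi, 0.0, None)
    eta = U.T @ (Q2.T @ y)
    return xi, eta


def profile_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    *,
    delta: float | None = None,
) -> MixedModelFit:
    """Fit ``y = X beta + u + e`` with ``Var(u) = sigma2_g K`` by REML.

    Parameters
    ----------
    y
        Response vector, length n.
    X
        Fixed-effect design, n x q, full column rank.
    K
        Symmetric PSD covariance structure of the random effect, n x n.
    delta
        If given, the variance ratio sigma2_e/sigma2_g is held fixed at this
        value and only sigma2_g and beta are estimated (used for the
        SNP-BLUP equivalence path).

    Notes
    -----
    The GLS fixed effects are computed at the optimal ratio from the full
    (untransformed) model, so ``beta`` is the familiar
    ``(X'V^-1 X)^-1 X'V^-1 y``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y have inconsistent lengths")
    if K.shape != (n, n):
        raise ValueError("K must be n x n")

    xi, eta = _restricted_components(y, X, K)
    m = eta.size
    ss_eta = float(eta @ eta)

    # Degenerate data: y lies (numerically) in the column space of X.
    scale = max(1.0, float(y @ y))
    if ss_eta < 1e-14 * scale:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return MixedModelFit(beta=beta, sigma2_g=0.0, sigma2_e=0.0,
                             delta=np.inf, reml_loglik=np.inf)

    def negloglik(log10_delta: float) -> float:
        d = 10.0 ** log10_delta
        denom = xi + d
        s2g = float(np.sum(eta**2 / denom)) / m
        return 0.5 * (m * np.log(2.0 * np.pi * s2g) + float(np.sum(np.log(denom))) + m)

    if delta is None:
        grid_vals = np.array([negloglik(ld) for ld in _LOG10_DELTA_GRID])
        i = int(np.argmin(grid_vals))
        lo = _LOG10_DELTA_GRID[max(i - 1, 0)]
        hi = _LOG10_DELTA_GRID[min(i + 1, len(_LOG10_DELTA_GRID) - 1)]
        if lo < hi:
            res = minimize_scalar(negloglik, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-10})
            log10_delta = float(res.x)
            if negloglik(log10_delta) > grid_vals[i]:
                log10_delta = float(_LOG10_DELTA_GRID[i])
        else:  # pragma: no cover - single-point grid
            log10_delta = float(_LOG10_DELTA_GRID[i])
        delta_hat = 10.0 ** log10_delta
    else:
        if delta <= 0:
            raise ValueError("delta must be positive")
        delta_hat = float(delta)

    denom = xi + delta_hat
    sigma2_g = float(np.sum(eta**2 / denom)) / m
    sigma2_e = delta_hat * sigma2_g
    loglik = -negloglik(np.log10(delta_hat))

    # GLS fixed effects at the optimum; V is proportional to K + delta I.
    A = K + delta_hat * np.eye(n)
    AinvX = np.linalg.solve(A, X)
    Ainvy = np.linalg.solve(A, y)
    beta = np.linalg.solve(X.T @ AinvX, X.T @ Ainvy)

    return MixedModelFit(beta=beta, sigma2_g=sigma2_g, sigma2_e=sigma2_e,
                         delta=delta_hat, reml_loglik=loglik)
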