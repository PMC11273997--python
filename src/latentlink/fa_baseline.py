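"""Linear maximum-likelihood factor analysis baseline.

Fits the common-factor model x = tau + Lambda xi + eps by ML (EM, via
scikit-learn's ``FactorAnalysis``) on the covariance metric, so that on
linear simulated data the unstandardized loadings are directly comparable
to the generating Lambda.  Factor scores are Bartlett (maximum-likelihood)
estimates; regression (Thomson) scores are available behind a flag.
Reconstruction is the linear map ``intercepts + scores @ loadings.T``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.decomposition import FactorAnalysis
from sklearn.exceptions import ConvergenceWarning

from .alignment import procrustes_align

__all__ = ["FactorSolution", "fit_fa", "estimate_scores", "reconstruct"]


@dataclass(frozen=True)
class FactorSolution:
    """Result of a linear FA fit.

    Loadings and communalities are reported on both conventions: the
    covariance (unstandardized) metric, on which loadings of linear
    simulated items estimate the generating loading directly, and the
    correlation metric, on which communalities are bounded by 1.
    """

    loadings: np.ndarray  # (items, factors), covariance metric
    noise_variance: np.ndarray  # (items,) residual variances psi
    intercepts: np.ndarray  # (items,) item means
    item_variances: np.ndarray  # (items,) sample variances
    n_factors: int
    converged: bool
    heywood: bool
    n_iter: int
    est_scores: np.ndarray | None = None  # (subjects, factors)
    reconstructed: np.ndarray | None = None  # (subjects, items)
    score_method: str = "bartlett"
    alignment: np.ndarray | None = None  # orthogonal rotation applied to columns

    @property
    def communalities(self) -> np.ndarray:
        """Covariance-metric communalities, sum_k lambda_jk^2."""
        return np.sum(self.loadings**2, axis=1)

    @property
    def standardized_loadings(self) -> np.ndarray:
        return self.loadings / np.sqrt(self.item_variances[:, None])

    @property
    def communalities_correlation(self) -> np.ndarray:
        """Correlation-metric communalities, in [0, 1] barring Heywood cases."""
        return self.communalities / self.item_variances


def fit_fa(
    responses: np.ndarray,
    n_factors: int = 1,
    *,
    reference_loadings: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> FactorSolution:
    """ML factor extraction on the covariance metric.

    For ``n_factors > 1`` the rotational indeterminacy is resolved by
    aligning loading columns to ``reference_loadings`` (greedy matching on
    absolute correlation, then sign-fixing); without a reference the
    unrotated ML solution is returned.  Non-convergence of EM is flagged on
    the solution, and Heywood-type boundary solutions (residual variance
    driven to the floor) are reported, never silently clipped.
    """
    x = np.asarray(responses, dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than items ({p})")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")

    item_var = x.var(axis=0)
    s_cov = np.cov(x.T)
    eigvals = np.linalg.eigvalsh(s_cov)
    if eigvals[-(n_factors + 1)] < 1e-12 * max(eigvals[-1], 1.0):
        # data are (numerically) exactly rank-q: EM degenerates, but the ML
        # solution is the truncated eigendecomposition with zero residuals
        w, v = np.linalg.eigh(s_cov)
        top = np.argsort(w)[::-1][:n_factors]
        loadings = v[:, top] * np.sqrt(np.maximum(w[top], 0.0))
        psi = np.maximum(np.diag(s_cov) - np.sum(loadings**2, axis=1), 0.0)
        converged = True
        n_iter = 0
    else:
        fa = FactorAnalysis(n_components=n_factors, tol=tol, max_iter=max_iter)
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                fa.fit(x)
            except ConvergenceWarning:
                converged = False
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    fa = FactorAnalysis(
                        n_components=n_factors, tol=tol, max_iter=max_iter
                    ).fit(x)
        loadings = fa.components_.T.copy()  # (p, q)
        psi = fa.noise_variance_.copy()
        n_iter = int(getattr(fa, "n_iter_", 0))
    heywood = bool(np.any(psi <= 1e-8 * np.maximum(item_var, 1.0)))

    alignment = None
    if reference_loadings is not None:
        # ML loadings are identified only up to rotation; rotate onto the
        # generating structure (sign flip in the one-factor case)
        loadings, rot = procrustes_align(loadings, np.asarray(reference_loadings))
        alignment = rot

    return FactorSolution(
        loadings=loadings,
        noise_variance=psi,
        intercepts=x.mean(axis=0),
        item_variances=item_var,
        n_factors=n_factors,
        converged=converged,
        heywood=heywood,
        n_iter=n_iter,
        alignment=alignment,
    )


def estimate_scores(
    solution: FactorSolution,
    responses: np.ndarray,
    method: str = "bartlett",
) -> FactorSolution:
    """Estimate factor scores; returns a solution with ``est_scores`` filled.

    ``bartlett`` (default) gives the maximum-likelihood, conditionally
    unbiased scores (Lambda' Psi^-1 Lambda)^-1 Lambda' Psi^-1 (x - mu);
    ``regression`` gives the Thomson posterior-mean scores.
    """
    x = np.asarray(responses, dtype=float)
    lam = solution.loadings
    psi = solution.noise_variance
    bad = ~np.isfinite(psi) | (psi < 0)
    if np.any(bad):
        names = ", ".join(f"item_{j+1}" for j in np.flatnonzero(bad))
        raise ValueError(f"degenerate residual variances for {names}")
    xc = x - solution.intercepts
    # guard against exact zeros from boundary solutions
    psi_safe = np.maximum(psi, 1e-12)
    lam_w = lam / psi_safe[:, None]  # Psi^-1 Lambda
    m = lam.T @ lam_w  # Lambda' Psi^-1 Lambda
    if np.linalg.cond(m) > 1e12:
        raise ValueError(
            "singular information matrix; items with near-zero loadings: "
            + ", ".join(
                f"item_{j+1}" for j in np.flatnonzero(np.all(np.abs(lam) < 1e-8, axis=1))
            )
        )
    if method == "bartlett":
        scores = xc @ lam_w @ np.linalg.inv(m)
    elif method == "regression":
        scores = xc @ lam_w @ np.linalg.inv(np.eye(solution.n_factors) + m)
    else:
        raise ValueError(f"unknown score method {method!r}")
    return replace(solution, est_scores=scores, score_method=method)


def reconstruct(solution: FactorSolution) -> np.ndarray:
    """Linear reconstruction ``intercepts + est_scores @ loadings.T``."""
    if solution.est_scores is None:
        raise ValueError("estimate scores before reconstructing")
    return solution.intercepts + solution.est_scores @ solution.loadings.T
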