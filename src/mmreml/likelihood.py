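"""Restricted likelihood, projection matrix, gradient and GLS fixed effects.

With ``Sigma_gamma = sum_k gamma_k V_k`` the restricted log-likelihood (up to
an additive constant) is

    L_R(gamma) = -1/2 [ log|X' Sigma^-1 X| + log|Sigma| + y' P y ]

where the projection ``P = Sigma^-1 - Sigma^-1 X (X' Sigma^-1 X)^-1 X' Sigma^-1``
annihilates span(X).  No error-contrast basis M is ever constructed: the value
does not depend on its choice.  All Sigma solves go through Cholesky; a
non-positive pivot is reported as a non-PD covariance at the offending gamma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .model import VCModel

__all__ = [
    "ProjectionCache",
    "projection_matrix",
    "projection_apply",
    "restricted_loglik",
    "reml_gradient",
    "gls_beta",
    "profiled_sigma_ref",
]


class NotPositiveDefiniteError(ValueError):
    """Sigma_gamma (or a required block) failed its Cholesky factorization."""


@dataclass
class ProjectionCache:
    """Cholesky-backed cache of the projection at a fixed gamma."""

    gamma: np.ndarray
    sigma_cho: tuple  # cho_factor of Sigma
    W: np.ndarray  # Sigma^-1 X, n x p
    A_cho: tuple  # cho_factor of A = X' Sigma^-1 X
    logdet_sigma: float
    logdet_xtsx: float
    sigma_inv_y: np.ndarray
    P_y: np.ndarray
    P: Optional[np.ndarray] = None  # dense projection, built on demand

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Matrix-free product ``P v``."""
        v = np.asarray(v, dtype=float)
        siv = cho_solve(self.sigma_cho, v)
        return siv - self.W @ cho_solve(self.A_cho, self.W.T @ v)

    def dense(self) -> np.ndarray:
        if self.P is None:
            n = self.W.shape[0]
            sigma_inv = cho_solve(self.sigma_cho, np.eye(n))
            P = sigma_inv - self.W @ cho_solve(self.A_cho, self.W.T)
            self.P = 0.5 * (P + P.T)
        return self.P


def _chol_logdet(mat: np.ndarray, what: str, gamma: np.ndarray) -> tuple:
    try:
        c, low = cho_factor(mat, lower=True)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(
            f"{what} is not positive definite at gamma={np.asarray(gamma).tolist()}"
        ) from exc
    d = np.diag(c)
    if np.any(d <= 0):
        raise NotPositiveDefiniteError(
            f"{what} is not positive definite at gamma={np.asarray(gamma).tolist()}"
        )
    return (c, low), 2.0 * float(np.sum(np.log(d)))


def projection_matrix(model: VCModel, gamma: np.ndarray) -> ProjectionCache:
    """Factor Sigma_gamma and cache everything needed for L_R and its gradient."""
    gamma = np.asarray(gamma, dtype=float)
    sigma = model.sigma(gamma)
    sigma_cho, logdet_sigma = _chol_logdet(sigma, "Sigma_gamma", gamma)
    W = cho_solve(sigma_cho, model.X)
    A = model.X.T @ W
    A = 0.5 * (A + A.T)
    A_cho, logdet_xtsx = _chol_logdet(A, "X' Sigma^-1 X", gamma)
    sigma_inv_y = cho_solve(sigma_cho, model.y)
    P_y = sigma_inv_y - W @ cho_solve(A_cho, W.T @ model.y)
    return ProjectionCache(
        gamma=gamma,
        sigma_cho=sigma_cho,
        W=W,
        A_cho=A_cho,
        logdet_sigma=logdet_sigma,
        logdet_xtsx=logdet_xtsx,
        sigma_inv_y=sigma_inv_y,
        P_y=P_y,
    )


def projection_apply(model: VCModel, gamma: np.ndarray, vector: np.ndarray) -> np.ndarray:
    """Matrix-free ``P_gamma v``."""
    return projection_matrix(model, gamma).apply(vector)


def restricted_loglik(
    model: VCModel, gamma: np.ndarray, cache: Optional[ProjectionCache] = None
) -> float:
    if cache is None:
        cache = projection_matrix(model, gamma)
    quad = float(model.y @ cache.P_y)
    return -0.5 * (cache.logdet_xtsx + cache.logdet_sigma + quad)


def reml_gradient(
    model: VCModel, gamma: np.ndarray, cache: Optional[ProjectionCache] = None
) -> np.ndarray:
    """dL_R/dsigma_k^2 = -1/2 [ tr(P V_k) - y' P V_k P y ]."""
    if cache is None:
        cache = projection_matrix(model, gamma)
    traces = trace_p_components(model, cache)
    Py = cache.P_y
    quads = np.einsum("kij,i,j->k", model.V_stack, Py, Py)
    return -0.5 * (traces - quads)


DENSE_P_CAP = 5000


def trace_p_components(model: VCModel, cache: ProjectionCache) -> np.ndarray:
    """tr(P V_k) for every component.

    Below ``DENSE_P_CAP`` observations the symmetric dense projection is
    materialized once (an n x n backsolve reused across components); above it
    the identical values come from the accumulation
    tr(P V_k) = tr(Sigma^-1 V_k) - tr((X'S^-1X)^-1 X'S^-1 V_k S^-1 X),
    which never forms P.
    """
    if model.n <= DENSE_P_CAP:
        P = cache.dense()
        return np.einsum("ij,kij->k", P, model.V_stack)
    n = model.n
    sigma_inv = cho_solve(cache.sigma_cho, np.eye(n))
    out = np.empty(model.K)
    for k, V in enumerate(model.V_stack):
        WtVW = cache.W.T @ V @ cache.W
        out[k] = float(np.sum(sigma_inv * V)) - float(
            np.trace(cho_solve(cache.A_cho, WtVW))
        )
    return out


def gls_beta(
    model: VCModel, gamma: np.ndarray, cache: Optional[ProjectionCache] = None
) -> tuple[np.ndarray, np.ndarray]:
    """GLS fixed effects: beta = (X'S^-1X)^-1 X'S^-1 y, cov = (X'S^-1X)^-1."""
    if cache is None:
        cache = projection_matrix(model, gamma)
    p = model.p
    beta_cov = cho_solve(cache.A_cho, np.eye(p))
    beta_cov = 0.5 * (beta_cov + beta_cov.T)
    beta = cho_solve(cache.A_cho, model.X.T @ cache.sigma_inv_y)
    return beta, beta_cov


def profiled_sigma_ref(model: VCModel, delta: np.ndarray) -> float:
    """Closed-form reference variance at fixed ratios delta.

    With delta_k = sigma_k^2 / sigma_K^2 (K the reference component) and
    Sigma_delta = sum_{k<K} delta_k V_k + V_K, the profiled estimate is
    sigma_K^2(delta) = y' P_delta y / m.
    """
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    K = model.K
    if delta.shape != (K - 1,):
        raise ValueError(f"delta must have length {K - 1}")
    ref = model.residual_index
    Vref = model.components[ref].V
    try:
        cho_factor(Vref, lower=True)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(
            f"reference component {model.components[ref].name!r} is singular; "
            "profiling is unavailable — use the un-profiled (MM) path"
        ) from None
    gamma_delta = np.empty(K)
    others = [k for k in range(K) if k != ref]
    gamma_delta[others] = delta
    gamma_delta[ref] = 1.0
    cache = projection_matrix(model, gamma_delta)
    return float(model.y @ cache.P_y) / model.m
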