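"""Newton / Fisher-scoring / Average-Information ReML in the ratio
parameterization, and delta-method standard errors for the variances.

The model is reparameterized as (delta, sigma_ref^2) with
delta_k = sigma_k^2 / sigma_ref^2 and Sigma_delta = sum delta_k V_k + V_ref,
so P_delta = sigma_ref^2 P_gamma.  The reference variance is profiled out,
sigma_ref^2(delta) = y' P_delta y / m, and Newton-type updates are applied to
delta only, with the Average-Information matrix

    AI_kk' = y'P V_k P V_k' P y / (2 sigma_ref^2)
    AI_kR  = y'P V_k P y / (2 sigma_ref^4)     (trace-free approximation)
    AI_RR  = y'P y / (2 sigma_ref^6)

as the curvature (the negated average of the observed and expected Hessians,
the off-diagonal reference block up to the stated trace approximation).
Standard errors come from the inverse AI at the optimum mapped back to the
variance scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor

from .likelihood import (
    NotPositiveDefiniteError,
    gls_beta,
    projection_matrix,
    restricted_loglik,
)
from .model import FitResult, VCModel

__all__ = [
    "InformationMatrices",
    "gradient_delta",
    "hessian_delta",
    "expected_hessian",
    "ai_matrix",
    "information_matrices",
    "fit_ai",
    "variance_se",
]


@dataclass
class InformationMatrices:
    gradient: np.ndarray
    hessian: np.ndarray
    expected_hessian: np.ndarray
    ai: np.ndarray


def _delta_order(model: VCModel) -> list[int]:
    """Component indices in (delta_1..delta_{K-1}, reference) order."""
    ref = model.residual_index
    return [k for k in range(model.K) if k != ref] + [ref]


def _gamma_from_delta(model: VCModel, delta: np.ndarray, sigma_ref2: float) -> np.ndarray:
    ref = model.residual_index
    gamma = np.empty(model.K)
    others = [k for k in range(model.K) if k != ref]
    gamma[others] = np.asarray(delta, dtype=float) * sigma_ref2
    gamma[ref] = sigma_ref2
    return gamma


def _delta_quantities(model: VCModel, delta: np.ndarray):
    """Dense P_delta and the traces/quadratic forms all blocks need."""
    ref = model.residual_index
    others = [k for k in range(model.K) if k != ref]
    gamma_delta = np.empty(model.K)
    gamma_delta[others] = delta
    gamma_delta[ref] = 1.0
    cache = projection_matrix(model, gamma_delta)
    P = cache.dense()
    Py = cache.P_y
    V = [model.V_stack[k] for k in others]
    PV = [P @ Vk for Vk in V]
    VPy = [Vk @ Py for Vk in V]
    return cache, P, Py, V, PV, VPy


def information_matrices(
    model: VCModel, delta: np.ndarray, sigma_ref2: float
) -> InformationMatrices:
    """Gradient, Hessian, expected Hessian and AI matrix at (delta, sigma_ref^2).

    Index order: the K-1 ratio components (model order, reference skipped)
    followed by the reference variance.
    """
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    K = model.K
    m = model.m
    s2 = float(sigma_ref2)
    cache, P, Py, V, PV, VPy = _delta_quantities(model, delta)
    yPy = float(model.y @ Py)
    nd = K - 1

    tr_PV = np.array([np.trace(M) for M in PV])
    quad = np.array([float(Py @ v) for v in VPy])  # y'P V_k P y
    PVPy = [P @ v for v in VPy]

    grad = np.empty(K)
    grad[:nd] = -0.5 * (tr_PV - quad / s2)
    grad[nd] = -0.5 * (m / s2 - yPy / s2**2)

    H = np.empty((K, K))
    EH = np.empty((K, K))
    AI = np.empty((K, K))
    for i in range(nd):
        for j in range(i, nd):
            tr_ij = float(np.sum(PV[i] * PV[j].T))  # tr(P V_i P V_j)
            q_ij = float(VPy[i] @ PVPy[j])  # y'P V_i P V_j P y
            H[i, j] = H[j, i] = 0.5 * tr_ij - q_ij / s2
            EH[i, j] = EH[j, i] = -0.5 * tr_ij
            AI[i, j] = AI[j, i] = q_ij / (2.0 * s2)
    for i in range(nd):
        H[i, nd] = H[nd, i] = -0.5 * quad[i] / s2**2
        EH[i, nd] = EH[nd, i] = -0.5 * tr_PV[i] / s2
        AI[i, nd] = AI[nd, i] = quad[i] / (2.0 * s2**2)
    H[nd, nd] = 0.5 * m / s2**2 - yPy / s2**3
    EH[nd, nd] = -0.5 * m / s2**2
    AI[nd, nd] = yPy / (2.0 * s2**3)
    return InformationMatrices(gradient=grad, hessian=H, expected_hessian=EH, ai=AI)


def gradient_delta(model: VCModel, delta: np.ndarray, sigma_ref2: float) -> np.ndarray:
    return information_matrices(model, delta, sigma_ref2).gradient


def hessian_delta(model: VCModel, delta: np.ndarray, sigma_ref2: float) -> np.ndarray:
    return information_matrices(model, delta, sigma_ref2).hessian


def expected_hessian(model: VCModel, delta: np.ndarray, sigma_ref2: float) -> np.ndarray:
    return information_matrices(model, delta, sigma_ref2).expected_hessian


def ai_matrix(model: VCModel, delta: np.ndarray, sigma_ref2: float) -> np.ndarray:
    return information_matrices(model, delta, sigma_ref2).ai


def _profiled_curvature(curv: np.ndarray, nd: int) -> np.ndarray:
    """Schur complement removing the profiled reference coordinate."""
    A = curv[:nd, :nd]
    b = curv[:nd, nd]
    d = curv[nd, nd]
    if d <= 0:
        return A
    return A - np.outer(b, b) / d


def _profiled(model: VCModel, delta: np.ndarray) -> tuple[float, float]:
    """(sigma_ref^2(delta), L_R at the profiled point)."""
    ref = model.residual_index
    others = [k for k in range(model.K) if k != ref]
    gamma_delta = np.empty(model.K)
    gamma_delta[others] = delta
    gamma_delta[ref] = 1.0
    cache = projection_matrix(model, gamma_delta)
    s2 = float(model.y @ cache.P_y) / model.m
    gamma = _gamma_from_delta(model, delta, s2)
    return s2, restricted_loglik(model, gamma)


def fit_ai(
    model: VCModel,
    init="auto",
    tol: float = 1e-5,
    max_iter: int = 200,
    max_halvings: int = 20,
) -> FitResult:
    """AI-ReML with profiling of the reference variance and step-halving.

    Requires the reference component to be positive definite (profiling);
    heterogeneous-error models with singular components must use ``fit_mm``.
    """
    from .mm import default_init

    ref = model.residual_index
    try:
        cho_factor(model.components[ref].V, lower=True)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(
            f"reference component {model.components[ref].name!r} is singular; "
            "AI-ReML profiling unavailable — use fit_mm"
        ) from None

    if isinstance(init, str) and init == "auto":
        gamma0 = default_init(model)
    else:
        gamma0 = np.asarray(init, dtype=float)
    others = [k for k in range(model.K) if k != ref]
    delta = gamma0[others] / gamma0[ref]
    warns: list[str] = []
    s2, loglik = _profiled(model, delta)
    gamma = _gamma_from_delta(model, delta, s2)
    history = [loglik]
    converged = False
    it = 0
    nd = model.K - 1
    frozen_d = np.zeros(nd, dtype=bool)
    for it in range(1, max_iter + 1):
        if model.K == 1:
            converged = True
            break
        # ratios that have decayed to numerical zero leave the Newton system
        frozen_d |= delta < 1e-12
        delta = np.where(frozen_d, 0.0, delta)
        active = np.flatnonzero(~frozen_d)
        if active.size == 0:
            converged = True
            gamma = _gamma_from_delta(model, delta, s2)
            break
        info = information_matrices(model, delta, s2)
        grad_d = info.gradient[:nd][active]

        def _direction(curv):
            full = np.zeros(nd)
            full[active] = np.linalg.solve(curv[np.ix_(active, active)], grad_d)
            return full

        # profiling: the curvature of delta -> L_R(delta, s2_hat(delta)) is the
        # Schur complement of the reference entry, not the raw delta block
        ai_blk = _profiled_curvature(info.ai, nd)
        fisher_blk = _profiled_curvature(-info.expected_hessian, nd)
        cap = 5.0 * max(1.0, float(np.abs(delta).max()))

        # directions in decreasing order of ambition: AI, damped AI, Fisher
        # scoring; each clipped to a trust region around delta
        candidates = []
        for mat in (ai_blk,
                    ai_blk + 0.1 * np.diag(np.diag(ai_blk)) + 1e-8 * np.eye(nd),
                    fisher_blk):
            try:
                d = _direction(mat)
            except np.linalg.LinAlgError:
                continue
            if not np.all(np.isfinite(d)):
                continue
            big = float(np.abs(d).max())
            if big > cap:
                d = d * (cap / big)
            candidates.append(d)
        if not candidates:
            raise np.linalg.LinAlgError(
                "both the AI and expected-information matrices are singular"
            )

        accepted = False
        boundary_move = False
        tiny = 1e-8 * max(1.0, float(delta.max(initial=0.0)))
        for step in candidates:
            for _ in range(max_halvings + 1):
                cand = delta + step
                # a ratio pushed past zero is clamped onto a geometric path to
                # the boundary (or straight to it once negligible) instead of
                # crippling the whole Newton step
                neg = cand <= 0
                cand[neg] = np.where(delta[neg] < tiny, 0.0, delta[neg] * 0.1)
                try:
                    s2_new, ll_new = _profiled(model, cand)
                    if ll_new >= loglik - 1e-12:
                        accepted = True
                        boundary_move = bool(np.any(neg))
                        break
                except NotPositiveDefiniteError:
                    pass
                step = 0.5 * step
            if accepted:
                break
        if not accepted:
            warns.append(f"iteration {it}: no improving step found; stopping")
            break
        gamma_new = _gamma_from_delta(model, cand, s2_new)
        step_norm = float(np.abs(gamma_new - gamma).max())
        gain = ll_new - loglik
        delta, s2, loglik, gamma = cand, s2_new, ll_new, gamma_new
        history.append(loglik)
        # while a coordinate is being pushed onto the boundary the Newton step
        # for the remaining coordinates is not yet trustworthy
        if step_norm < tol and gain < tol and not boundary_move:
            converged = True
            break
    if not converged:
        msg = f"AI-ReML did not converge in {max_iter} iterations"
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)

    cache = projection_matrix(model, gamma)
    beta_hat, beta_cov = gls_beta(model, gamma, cache)
    try:
        gamma_se = variance_se(model, gamma)
    except Exception as exc:
        gamma_se = None
        warns.append(f"standard errors unavailable: {exc}")
    return FitResult(
        gamma_hat=gamma,
        beta_hat=beta_hat,
        beta_cov=beta_cov,
        loglik=loglik,
        converged=converged,
        n_iterations=it,
        solver_tag="ai",
        gamma_se=gamma_se,
        component_names=model.component_names,
        warnings=warns,
        diagnostics={"loglik_history": history, "m": model.m},
    )


def variance_se(model: VCModel, gamma_hat: np.ndarray) -> np.ndarray:
    """Standard errors of the variance estimates from the inverse AI matrix.

    The AI matrix lives on the (delta, sigma_ref^2) scale; its inverse is
    mapped to the variance scale by the Jacobian of
    gamma_k = delta_k sigma_ref^2 (k != ref), gamma_ref = sigma_ref^2.
    """
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    ref = model.residual_index
    s2 = float(gamma_hat[ref])
    if s2 <= 0:
        raise ValueError("reference variance estimate is not positive")
    others = [k for k in range(model.K) if k != ref]
    delta = gamma_hat[others] / s2
    info = information_matrices(model, delta, s2)
    try:
        cov_theta = np.linalg.inv(info.ai)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("AI matrix at the optimum is singular") from None
    K = model.K
    nd = K - 1
    J = np.zeros((K, K))  # rows: gamma in (others..., ref) order; cols: (delta..., s2)
    for i in range(nd):
        J[i, i] = s2
        J[i, nd] = delta[i]
    J[nd, nd] = 1.0
    cov_gamma = J @ cov_theta @ J.T
    var = np.diag(cov_gamma)
    if np.any(var < 0):
        raise ValueError("negative variance of a variance estimate (AI not PD)")
    se = np.empty(K)
    se[others] = np.sqrt(var[:nd])
    se[ref] = np.sqrt(var[nd])
    return se
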