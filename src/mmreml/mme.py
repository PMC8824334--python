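"""Henderson mixed-model-equation rewrite of the MM update.

For Model y = X beta + sum_{k != ref} Z_k u_k + e with u_k ~ N(0, sigma_k^2 R_k)
and e ~ N(0, sigma_ref^2 V_ref), the coefficient matrix of the MME at ratios
delta_k = sigma_k^2 / sigma_ref^2 is

    C = [ X'V_ref^-1 X   X'V_ref^-1 Z            ]
        [ Z'V_ref^-1 X   Z'V_ref^-1 Z + G_delta^-1 ]

with G_delta = blockdiag(delta_k R_k).  Solving C (beta, u) = (X'V_ref^-1 y,
Z'V_ref^-1 y) yields every quantity the MM update needs without ever forming
the n x n projection:

    Z'P_delta y = G^-1 u,   Z'P_delta Z = G^-1 - G^-1 [C^-1]_uu G^-1,
    P_delta y = V_ref^-1 e,  tr(P_delta V_ref) = m - tr(Z'SZ [C^-1]_uu)

where e = y - X beta - Z u and S = V_ref^-1 - V_ref^-1 X (X'V_ref^-1 X)^-1
X'V_ref^-1 is constant across iterations.  Worth it when the total latent
dimension sum n_k + p is small relative to n; requires every R_k and V_ref
to be invertible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .model import VCModel

__all__ = [
    "MMEFactors",
    "build_mme",
    "mme_identities",
    "trace_p_vk",
    "mm_step_via_mme",
    "select_strategy",
    "mme_applicable",
]


@dataclass
class MMEFactors:
    C: np.ndarray
    beta_hat: np.ndarray
    u_hat: np.ndarray
    e_hat: np.ndarray
    Cinv_uu: np.ndarray
    S: np.ndarray
    G_inv: np.ndarray
    Z: np.ndarray
    Vref_inv: np.ndarray
    blocks: list[slice]  # per-component slices into the u vector
    delta: np.ndarray
    logdet_Vref: float = 0.0
    logdet_G: float = 0.0
    logdet_C: float = 0.0
    logdet_Q: float = 0.0  # lower-right block Z'V^-1 Z + G^-1


def _component_ZR(model: VCModel, k: int) -> tuple[np.ndarray, np.ndarray]:
    comp = model.components[k]
    n = model.n
    Z = comp.Z if comp.Z is not None else np.eye(n)
    R = comp.R if comp.R is not None else np.eye(comp.n_levels)
    return Z, R


def mme_applicable(model: VCModel) -> bool:
    """All non-reference R_k and the reference V must be invertible."""
    ref = model.residual_index
    try:
        cho_factor(model.components[ref].V, lower=True)
        for k in range(model.K):
            if k == ref:
                continue
            _, R = _component_ZR(model, k)
            cho_factor(R, lower=True)
    except np.linalg.LinAlgError:
        return False
    return True


def build_mme(model: VCModel, delta: np.ndarray) -> MMEFactors:
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    ref = model.residual_index
    others = [k for k in range(model.K) if k != ref]
    if delta.shape != (len(others),):
        raise ValueError(f"delta must have length {len(others)}")
    try:
        Vref_cho = cho_factor(model.components[ref].V, lower=True)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "reference component is singular; use the direct path"
        ) from None
    n = model.n
    Vref_inv = cho_solve(Vref_cho, np.eye(n))
    logdet_Vref = 2.0 * float(np.sum(np.log(np.diag(Vref_cho[0]))))
    Zs, Ginv_blocks, blocks = [], [], []
    logdet_G = 0.0
    off = 0
    for dk, k in zip(delta, others):
        Z, R = _component_ZR(model, k)
        try:
            R_cho = cho_factor(R, lower=True)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"correlation of component {model.components[k].name!r} is "
                "singular; use the direct path"
            ) from None
        Zs.append(Z)
        Ginv_blocks.append(cho_solve(R_cho, np.eye(R.shape[0])) / dk)
        logdet_G += Z.shape[1] * np.log(dk) + 2.0 * float(np.sum(np.log(np.diag(R_cho[0]))))
        blocks.append(slice(off, off + Z.shape[1]))
        off += Z.shape[1]
    Z = np.hstack(Zs) if Zs else np.zeros((n, 0))
    q = Z.shape[1]
    G_inv = np.zeros((q, q))
    for b, gb in zip(blocks, Ginv_blocks):
        G_inv[b, b] = gb

    X = model.X
    VinvX = Vref_inv @ X
    VinvZ = Vref_inv @ Z
    p = model.p
    C = np.empty((p + q, p + q))
    C[:p, :p] = X.T @ VinvX
    C[:p, p:] = X.T @ VinvZ
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Z.T @ VinvZ + G_inv
    C = 0.5 * (C + C.T)
    rhs = np.concatenate([VinvX.T @ model.y, VinvZ.T @ model.y])
    Cinv = np.linalg.inv(C)
    sol = Cinv @ rhs
    beta_hat, u_hat = sol[:p], sol[p:]
    e_hat = model.y - X @ beta_hat - Z @ u_hat
    XtVinvX_inv = np.linalg.inv(C[:p, :p])
    S = Vref_inv - VinvX @ XtVinvX_inv @ VinvX.T
    sign_c, logdet_C = np.linalg.slogdet(C)
    sign_q, logdet_Q = np.linalg.slogdet(C[p:, p:]) if q else (1.0, 0.0)
    if sign_c <= 0 or sign_q <= 0:
        raise np.linalg.LinAlgError("MME coefficient matrix is not positive definite")
    return MMEFactors(
        C=C,
        beta_hat=beta_hat,
        u_hat=u_hat,
        e_hat=e_hat,
        Cinv_uu=Cinv[p:, p:],
        S=0.5 * (S + S.T),
        G_inv=G_inv,
        Z=Z,
        Vref_inv=Vref_inv,
        blocks=blocks,
        delta=delta,
        logdet_Vref=logdet_Vref,
        logdet_G=logdet_G,
        logdet_C=logdet_C,
        logdet_Q=logdet_Q,
    )


def restricted_loglik_mme(model: VCModel, gamma: np.ndarray, factors: MMEFactors) -> float:
    """L_R evaluated from the MME factorization (same constant convention as
    the direct evaluation): with sigma_ref^2 = s2,

      log|Sigma_gamma|        = n log s2 + log|V_ref| + log|G_delta| + log|Q|
      log|X'Sigma_gamma^-1 X| = -p log s2 + log|C| - log|Q|
      y'P_gamma y             = y'V_ref^-1 e_hat / s2 .
    """
    ref = model.residual_index
    s2 = float(np.asarray(gamma, dtype=float)[ref])
    Py_delta = factors.Vref_inv @ factors.e_hat
    quad = float(model.y @ Py_delta) / s2
    logdet_sigma = model.n * np.log(s2) + factors.logdet_Vref + factors.logdet_G + factors.logdet_Q
    logdet_xtsx = -model.p * np.log(s2) + factors.logdet_C - factors.logdet_Q
    return -0.5 * (logdet_xtsx + logdet_sigma + quad)


def mme_identities(factors: MMEFactors) -> dict[str, np.ndarray]:
    """The projection quantities recovered from the MME solution."""
    ZtPy = factors.G_inv @ factors.u_hat
    ZtPZ = factors.G_inv - factors.G_inv @ factors.Cinv_uu @ factors.G_inv
    Py = factors.Vref_inv @ factors.e_hat
    return {"ZtPy": ZtPy, "ZtPZ": ZtPZ, "Py": Py}


def trace_p_vk(factors: MMEFactors, m: int) -> float:
    """tr(P_delta V_ref) = m - tr(Z'SZ [C^-1]_uu) — S never needs updating."""
    if factors.Z.shape[1] == 0:
        return float(m)
    ZtSZ = factors.Z.T @ factors.S @ factors.Z
    return float(m - np.sum(ZtSZ * factors.Cinv_uu.T))


def mm_step_via_mme(
    model: VCModel, gamma_t: np.ndarray, factors: Optional[MMEFactors] = None
) -> np.ndarray:
    """The MM multiplicative update computed through the MME.

    Numerically equal to the direct ``mm_step`` (same sqrt fixed-point form),
    evaluated in the delta parameterization: for k != ref the numerator is
    [y'P Z_k] R_k [Z_k'P y] and the denominator sigma_ref^2 tr(Z_k'P Z_k R_k);
    for the reference, e'V_ref^-1 e over sigma_ref^2 tr(P V_ref).
    """
    gamma_t = np.asarray(gamma_t, dtype=float)
    ref = model.residual_index
    others = [k for k in range(model.K) if k != ref]
    s2 = float(gamma_t[ref])
    delta = gamma_t[others] / s2
    if factors is None:
        factors = build_mme(model, delta)
    ids = mme_identities(factors)
    gamma_next = gamma_t.copy()
    ZtPZ = ids["ZtPZ"]
    for b, k in zip(factors.blocks, others):
        _, R = _component_ZR(model, k)
        t_k = ids["ZtPy"][b]
        num = float(t_k @ R @ t_k)
        denom = s2 * float(np.sum(ZtPZ[b, b] * R.T))
        if denom <= 0:
            gamma_next[k] = 0.0
            continue
        gamma_next[k] = gamma_t[k] * np.sqrt(num / denom)
    num_ref = float(factors.e_hat @ ids["Py"])  # e' V_ref^-1 e
    denom_ref = s2 * trace_p_vk(factors, model.m)
    gamma_next[ref] = s2 * np.sqrt(num_ref / denom_ref)
    return gamma_next


def select_strategy(model: VCModel) -> str:
    """Pick 'mme' when its per-iteration flop proxy undercuts the direct path.

    Proxy: (sum n_k + p)^3 + sum n_k^2 * n  vs  n^3 + K n^2, requiring MME
    applicability (all R_k and V_ref invertible).
    """
    ref = model.residual_index
    others = [k for k in range(model.K) if k != ref]
    n, p, K = model.n, model.p, model.K
    nks = [model.components[k].n_levels for k in others]
    q = sum(nks)
    mme_cost = (q + p) ** 3 + sum(nk**2 for nk in nks) * n
    direct_cost = n**3 + K * n**2
    if mme_cost < direct_cost and mme_applicable(model):
        return "mme"
    return "direct"
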