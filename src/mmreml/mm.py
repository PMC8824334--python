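"""ReML estimation by Min-Max (MM) iteration with SQUAREM acceleration.

At the current variance vector gamma_t the objective f = -L_R is dominated by
a separable surrogate (equality at gamma_t):

    g(gamma) = 1/2 sum_k [ sigma_k^2 tr(P_t V_k)
                           + (sigma_k^4(t)/sigma_k^2) y'P_t V_k P_t y ]
               + 1/2 (log|X'Sigma_t^-1 X| + log|Sigma_t|) - m/2 .

The surrogate separates over components; setting its gradient to zero gives
the multiplicative update

    sigma_k^2(t+1) = sigma_k^2(t) * sqrt( y'P_t V_k P_t y / tr(P_t V_k) ),

which preserves positivity and never decreases L_R.  Convergence uses both an
infinity-norm parameter criterion and an objective-gain criterion with the
same tolerance (default 1e-5).  Every third iteration a squared-extrapolation
(SQUAREM) proposal is tried and accepted only if it keeps all variances
positive and improves the objective.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .likelihood import (
    ProjectionCache,
    gls_beta,
    projection_matrix,
    restricted_loglik,
    trace_p_components,
)
from .model import FitResult, VCModel

__all__ = ["surrogate", "mm_step", "squarem_step", "fit_mm"]

_FREEZE_PATIENCE = 3


def _mm_quantities(model: VCModel, gamma_t: np.ndarray) -> tuple[ProjectionCache, np.ndarray, np.ndarray]:
    cache = projection_matrix(model, gamma_t)
    traces = trace_p_components(model, cache)
    Py = cache.P_y
    quads = np.einsum("kij,i,j->k", model.V_stack, Py, Py)
    return cache, traces, quads


def surrogate(model: VCModel, gamma_t: np.ndarray, gamma: np.ndarray) -> float:
    """Evaluate the MM surrogate g^(t+1)(gamma) anchored at gamma_t.

    Dominates -L_R everywhere and touches it at gamma_t.  Has a pole at
    sigma_k^2 = 0, so gamma must be strictly positive.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("surrogate requires strictly positive gamma (pole at 0)")
    gamma_t = np.asarray(gamma_t, dtype=float)
    cache, traces, quads = _mm_quantities(model, gamma_t)
    lin = float(gamma @ traces)
    frac = float(np.sum(gamma_t**2 / gamma * quads))
    const = 0.5 * (cache.logdet_xtsx + cache.logdet_sigma) - 0.5 * model.m
    return 0.5 * (lin + frac) + const


def mm_step(
    model: VCModel,
    gamma_t: np.ndarray,
    cache: Optional[ProjectionCache] = None,
    frozen: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One MM update.  Components with tr(P V_k) ~ 0 (fully confounded with
    the fixed effects) are frozen at zero rather than divided by zero."""
    gamma_t = np.asarray(gamma_t, dtype=float)
    if cache is None:
        cache = projection_matrix(model, gamma_t)
    traces = trace_p_components(model, cache)
    Py = cache.P_y
    quads = np.einsum("kij,i,j->k", model.V_stack, Py, Py)
    gamma_next = gamma_t.copy()
    scale = np.abs(traces).max()
    active = traces > 1e-12 * max(scale, 1.0)
    if frozen is not None:
        active &= ~frozen
    gamma_next[active] = gamma_t[active] * np.sqrt(quads[active] / traces[active])
    gamma_next[~active & (traces <= 1e-12 * max(scale, 1.0))] = 0.0
    return gamma_next


def squarem_step(
    theta_t2: np.ndarray,
    theta_t1: np.ndarray,
    theta_t: np.ndarray,
    objective,
) -> np.ndarray:
    """Squared-extrapolation proposal from three consecutive MM iterates.

    With r = theta(t-1)-theta(t-2) and v the second difference
    theta(t)-2 theta(t-1)+theta(t-2), the steplength alpha = -|r|_2/|v|_2
    gives the proposal theta(t-2) - 2 alpha r + alpha^2 v; it is accepted
    only if entrywise positive and it strictly decreases the objective
    f = -L_R, else theta_t is returned unchanged.
    """
    r = theta_t1 - theta_t2
    v = theta_t - 2.0 * theta_t1 + theta_t2  # second difference of the iterates
    nv = float(np.linalg.norm(v))
    if nv == 0.0:
        return theta_t
    alpha = -float(np.linalg.norm(r)) / nv
    proposal = theta_t2 - 2.0 * alpha * r + alpha**2 * v
    if np.any(proposal <= 0):
        return theta_t
    try:
        if objective(proposal) < objective(theta_t):
            return proposal
    except Exception:
        return theta_t
    return theta_t


def default_init(model: VCModel) -> np.ndarray:
    """Equal split of the OLS residual variance across components."""
    y, X = model.y, model.X
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    var = float(resid @ resid) / max(model.m, 1)
    if var <= 0:
        var = max(float(np.var(y)), 1e-8)
    return np.full(model.K, var / model.K)


def fit_mm(
    model: VCModel,
    init="auto",
    tol: float = 1e-5,
    max_iter: int = 1000,
    accelerate: bool = True,
    use_mme: str = "auto",
    compute_se: bool = True,
) -> FitResult:
    """ReML fit by MM iteration.

    Stops when BOTH |gamma_t - gamma_{t-1}|_inf < tol and the objective gain
    f(gamma_{t-1}) - f(gamma_t) < tol hold.  ``use_mme`` selects the Henderson
    mixed-model-equation rewrite of the update ("auto" applies a flop-count
    rule; the iterate sequence is identical either way).
    """
    from .mme import (
        build_mme,
        mme_applicable,
        mm_step_via_mme,
        restricted_loglik_mme,
        select_strategy,
    )

    if isinstance(init, str) and init == "auto":
        gamma = default_init(model)
    else:
        gamma = np.asarray(init, dtype=float).copy()
        if np.any(gamma <= 0):
            raise ValueError("initial variances must be strictly positive")

    if use_mme == "auto":
        strategy = select_strategy(model)
    elif use_mme == "on":
        if not mme_applicable(model):
            raise ValueError("MME path requested but some R_k or V_K is singular")
        strategy = "mme"
    elif use_mme == "off":
        strategy = "direct"
    else:
        raise ValueError("use_mme must be 'auto', 'on' or 'off'")

    floor = 1e-10 * float(np.sum(gamma))
    frozen = np.zeros(model.K, dtype=bool)
    below = np.zeros(model.K, dtype=int)
    warns: list[str] = []
    ref = model.residual_index
    others = [k for k in range(model.K) if k != ref]
    n_obj_evals = 0

    def objective(g):
        nonlocal n_obj_evals
        n_obj_evals += 1
        if strategy == "mme":
            f = build_mme(model, g[others] / g[ref])
            return -restricted_loglik_mme(model, g, f)
        return -restricted_loglik(model, g)

    def step_and_loglik(g):
        """(next iterate, L_R at g) from one factorization of Sigma at g."""
        if strategy == "mme":
            f = build_mme(model, g[others] / g[ref])
            return (
                mm_step_via_mme(model, g, factors=f),
                restricted_loglik_mme(model, g, f),
            )
        cache = projection_matrix(model, g)
        return mm_step(model, g, cache=cache), restricted_loglik(model, g, cache)

    history: list[float] = []
    recent: list[np.ndarray] = [gamma.copy()]
    converged = False
    loglik = -np.inf
    step_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        gamma_new, loglik_here = step_and_loglik(gamma)
        if not np.isfinite(loglik_here):
            raise FloatingPointError(f"non-finite likelihood at iteration {it}")
        history.append(loglik_here)
        gain = loglik_here - loglik
        loglik = loglik_here
        if step_norm < tol and gain < tol:
            converged = True
            break
        gamma_new = np.where(frozen, gamma, gamma_new)
        if strategy == "mme":
            # the MME rewrite needs strictly positive ratios; an exact zero
            # (fully confounded component) continues from the boundary floor
            gamma_new = np.where(gamma_new <= 0, floor, gamma_new)

        # geometric decay never reaches 0: freeze persistent near-zero components
        below = np.where(gamma_new < floor, below + 1, 0)
        newly = (below >= _FREEZE_PATIENCE) & ~frozen
        if np.any(newly):
            frozen |= newly
            gamma_new[newly] = floor
            for k in np.flatnonzero(newly):
                warns.append(
                    f"component {model.component_names[k]!r} frozen at the "
                    f"boundary floor {floor:.3e}"
                )

        recent.append(gamma_new.copy())
        if len(recent) > 3:
            recent.pop(0)
        if accelerate and len(recent) == 3 and it % 3 == 0:
            prop = squarem_step(recent[0], recent[1], recent[2], objective)
            if prop is not recent[2]:
                gamma_new = np.where(frozen, gamma_new, prop)
                recent = [gamma_new.copy()]

        active = ~frozen
        step_norm = float(np.abs(gamma_new - gamma)[active].max()) if active.any() else 0.0
        gamma = gamma_new

    if not converged:
        msg = f"MM did not converge in {max_iter} iterations (last step {step_norm:.2e})"
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)

    cache = projection_matrix(model, gamma)
    beta_hat, beta_cov = gls_beta(model, gamma, cache)
    gamma_se = None
    if compute_se:
        from .ai import variance_se

        try:
            gamma_se = variance_se(model, gamma)
        except Exception as exc:  # singular AI, boundary estimate, ...
            warns.append(f"standard errors unavailable: {exc}")
    tag = "mm+mme" if strategy == "mme" else "mm"
    return FitResult(
        gamma_hat=gamma,
        beta_hat=beta_hat,
        beta_cov=beta_cov,
        loglik=loglik,
        converged=converged,
        n_iterations=it,
        solver_tag=tag,
        gamma_se=gamma_se,
        component_names=model.component_names,
        frozen=frozen,
        warnings=warns,
        diagnostics={"loglik_history": history, "objective_evals": n_obj_evals,
                     "m": model.m},
    )
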