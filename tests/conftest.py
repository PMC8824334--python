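import numpy as np
import pytest

from mmreml import Component, build_model, simulate_phenotype


def random_instance(seed, n=30, K=3, p=2, gamma_true=None, factored=True,
                    interior=False):
    """A small seeded variance-component model with simulated phenotype.

    Components are mutually well separated: a dense correlation with a widely
    spread spectrum (kinship-like), a grouped (factored) random effect, an
    AR(1)-type correlation, and an identity error term last.
    """
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(p - 1)])
    comps = [] if K == 1 else [Component("kinship", R=_dense_corr(rng, n))]
    if K >= 3 and factored:
        q = max(4, n // 6)
        Z = np.zeros((n, q))
        Z[np.arange(n), rng.integers(0, q, n)] = 1.0
        comps.append(Component("group", Z=Z))
    while len(comps) < K - 1:
        comps.append(Component(f"ar{len(comps)}", R=_ar1_corr(n, 0.6)))
    comps.append(Component("error"))
    if gamma_true is None:
        if interior:
            # strong, clearly separated signals: every solver should land at
            # the same interior optimum
            gamma_true = np.concatenate([rng.uniform(0.5, 1.5, K - 1), [1.0]])
        else:
            gamma_true = rng.uniform(0.3, 1.5, K)
    gamma_true = np.asarray(gamma_true, dtype=float)
    y = simulate_phenotype((X, comps), gamma_true, beta=rng.normal(0, 1, p), seed=rng)
    return build_model(y, X, comps), gamma_true


def _dense_corr(rng, n):
    A = rng.standard_normal((n, n + 5))
    S = A @ A.T / (n + 5)
    d = 1.0 / np.sqrt(np.diag(S))
    return S * d[:, None] * d[None, :]


def _ar1_corr(n, rho):
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def nm_oracle(model, restarts=5, seed=0):
    """Derivative-free direct maximizer of the restricted likelihood.

    Restarted Nelder-Mead on log-variances; independent of every iterative
    solver in the package.
    """
    from scipy.optimize import minimize

    from mmreml import restricted_loglik

    rng = np.random.default_rng(seed)
    K = model.K
    starts = [np.zeros(K)] + [rng.normal(0, 1, K) for _ in range(restarts - 1)]
    best = None
    for x0 in starts:
        res = minimize(
            lambda lg: -restricted_loglik(model, np.exp(lg)),
            x0,
            method="Nelder-Mead",
            options=dict(xatol=1e-11, fatol=1e-13, maxiter=5000, maxfev=8000),
        )
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(best.x), -best.fun


def rel_diff(a, b, scale):
    """Componentwise relative difference between variance estimates.

    Components that both routes place at the zero boundary (below one part
    per million of the phenotypic variance ``scale``) are counted as in
    agreement: the multiplicative MM iterate stops a few multiples of its
    step tolerance above an exact zero, so the residual magnitude there is
    solver round-off, not a substantive difference.  All other components
    are compared on the usual relative scale.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    out = np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-300)
    boundary = (np.abs(a) < 1e-6 * scale) & (np.abs(b) < 1e-6 * scale)
    out[boundary] = 0.0
    return out


@pytest.fixture
def small_model():
    model, gamma_true = random_instance(42, n=30, K=3)
    return model


@pytest.fixture
def two_vc_model():
    model, _ = random_instance(7, n=40, K=2)
    return model
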