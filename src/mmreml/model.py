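"""Variance-component mixed model containers and validation.

The model is ``Y ~ N(X beta, sum_k sigma_k^2 V_k)`` with known correlation
structures ``V_k``.  Each component may be given either directly as an n x n
matrix ``V_k`` or in factored form ``V_k = Z_k R_k Z_k^T`` with an incidence
matrix ``Z_k`` (n x n_k) and a correlation matrix ``R_k`` (n_k x n_k), the
form used by designs with replicated or grouped observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Component",
    "VCModel",
    "VarianceState",
    "FitResult",
    "build_model",
    "hybrid_phi",
]

_SYM_TOL = 1e-10
_PSD_TOL = 1e-8


@dataclass
class Component:
    """One variance component: ``V = Z R Z^T``.

    ``Z`` omitted means identity incidence (n_k = n); ``R`` omitted means
    identity correlation.  ``V`` is cached at construction.
    """

    name: str
    Z: Optional[np.ndarray] = None
    R: Optional[np.ndarray] = None
    V: np.ndarray = field(init=False, repr=False)
    n_levels: int = field(init=False)

    def materialize(self, n: int) -> None:
        Z, R = self.Z, self.R
        if Z is not None:
            Z = np.asarray(Z, dtype=float)
            if Z.shape[0] != n:
                raise ValueError(
                    f"component {self.name!r}: incidence has {Z.shape[0]} rows, "
                    f"expected {n}"
                )
            self.Z = Z
            n_k = Z.shape[1]
        else:
            n_k = n
        if R is not None:
            R = np.asarray(R, dtype=float)
            if R.shape != (n_k, n_k):
                raise ValueError(
                    f"component {self.name!r}: correlation is {R.shape}, "
                    f"expected ({n_k}, {n_k})"
                )
            if not np.allclose(R, R.T, atol=_SYM_TOL * max(1.0, np.abs(R).max())):
                raise ValueError(f"component {self.name!r}: correlation matrix not symmetric")
            R = 0.5 * (R + R.T)
            self.R = R
        self.n_levels = n_k
        if Z is None and R is None:
            V = np.eye(n)
        elif Z is None:
            V = R.copy()
        elif R is None:
            V = Z @ Z.T
        else:
            V = Z @ R @ Z.T
        V = 0.5 * (V + V.T)
        norm = np.abs(V).max()
        if norm > 0:
            w_min = np.linalg.eigvalsh(V)[0]
            if w_min < -_PSD_TOL * norm:
                raise ValueError(
                    f"component {self.name!r}: V not positive semidefinite "
                    f"(min eigenvalue {w_min:.3e})"
                )
        self.V = V

    @property
    def is_factored(self) -> bool:
        return self.Z is not None


@dataclass
class VCModel:
    """Observations, fixed-effect design and K variance components."""

    y: np.ndarray
    X: np.ndarray
    components: list[Component]
    residual_index: int = -1

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y have inconsistent numbers of rows")
        if self.residual_index < 0:
            self.residual_index += len(self.components)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        """Residual degrees of freedom, rank of any error-contrast basis."""
        return self.n - self.p

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def V_stack(self) -> np.ndarray:
        """K x n x n array of component covariance structures."""
        if not hasattr(self, "_V_stack"):
            self._V_stack = np.stack([c.V for c in self.components])
        return self._V_stack

    def sigma(self, gamma: np.ndarray) -> np.ndarray:
        """Covariance ``Sigma_gamma = sum_k gamma_k V_k``."""
        gamma = np.asarray(gamma, dtype=float)
        if gamma.shape != (self.K,):
            raise ValueError(f"gamma must have length {self.K}")
        return np.einsum("k,kij->ij", gamma, self.V_stack)

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]


@dataclass
class VarianceState:
    gamma: np.ndarray
    loglik: float
    iteration: int = 0
    last_step_norm: float = np.inf
    last_loglik_gain: float = np.inf


@dataclass
class FitResult:
    """Converged variance estimates with GLS fixed effects."""

    gamma_hat: np.ndarray
    beta_hat: np.ndarray
    beta_cov: np.ndarray
    loglik: float
    converged: bool
    n_iterations: int
    solver_tag: str
    gamma_se: Optional[np.ndarray] = None
    component_names: Optional[list[str]] = None
    frozen: Optional[np.ndarray] = None
    warnings: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def build_model(
    y: np.ndarray,
    X: np.ndarray,
    components: Sequence[Component],
    residual_index: int = -1,
) -> VCModel:
    """Validate and assemble a variance-component model.

    Raises ``ValueError`` on rank-deficient ``X`` (naming the collinear
    columns), non-symmetric correlation matrices, or dimension mismatches.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and y.shape[0] != 1:
        X = X.T
    n = y.shape[0]
    if X.shape[0] != n:
        raise ValueError(f"X has {X.shape[0]} rows but y has {n} entries")
    if X.shape[1] > n:
        raise ValueError("more fixed-effect columns than observations")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(
            f"fixed-effect design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}"
        )
    if n - X.shape[1] <= 0:
        raise ValueError("no residual degrees of freedom (n - p <= 0)")
    if len(components) < 1:
        raise ValueError("at least one variance component is required")
    comps = list(components)
    for comp in comps:
        comp.materialize(n)
        diag = np.diag(comp.V)
        if comp.R is not None and diag.max() > 0:
            rdiag = np.diag(comp.R)
            if np.abs(rdiag - 1.0).max() > 0.3:
                warnings.warn(
                    f"component {comp.name!r}: correlation diagonal departs from 1 "
                    f"(max |diag-1| = {np.abs(rdiag - 1.0).max():.2f}); variances are "
                    "interpreted on that scale",
                    stacklevel=2,
                )
    return VCModel(y=y, X=X, components=comps, residual_index=residual_index)


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Indices of columns linearly dependent on their predecessors (QR pivots)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int((d > tol).sum())
    return sorted(int(j) for j in piv[rank:])


def hybrid_phi(
    K_F: np.ndarray,
    K_D: np.ndarray,
    crosses: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Double-relatedness matrix between hybrids of a factorial design.

    For hybrids h = (f, d) and h' = (f', d'),
    ``Phi[h, h'] = K_F[f, f'] * K_D[d, d']`` — the entrywise (Schur) product
    of the parental kinships under the cross mapping, hence PSD whenever
    both parental kinships are.
    """
    K_F = np.asarray(K_F, dtype=float)
    K_D = np.asarray(K_D, dtype=float)
    f_idx = np.array([c[0] for c in crosses], dtype=int)
    d_idx = np.array([c[1] for c in crosses], dtype=int)
    if f_idx.size and (f_idx.min() < 0 or f_idx.max() >= K_F.shape[0]):
        raise ValueError("cross references an unknown flint parent index")
    if d_idx.size and (d_idx.min() < 0 or d_idx.max() >= K_D.shape[0]):
        raise ValueError("cross references an unknown dent parent index")
    phi = K_F[np.ix_(f_idx, f_idx)] * K_D[np.ix_(d_idx, d_idx)]
    return 0.5 * (phi + phi.T)
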