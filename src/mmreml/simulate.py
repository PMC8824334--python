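"""Synthetic designs for variance-component analysis and GWAS.

Three study designs are generated, mirroring common maize quantitative
genetics layouts:

* a panel of inbred lines with a marker-derived kinship (2-component GWAS
  models),
* an incomplete factorial crossing design between two heterotic groups
  (flint x dent hybrids; 4 components: flint, dent, their interaction
  through the double-relatedness matrix, error),
* a multi-trial hybrid experiment with per-trial genotype-by-environment
  interaction, row and column effects, and either a common or trial-specific
  error variance.

Genotypes are i.i.d. biallelic dosages (no linkage-disequilibrium model);
kinships are VanRaden-type centered cross-products.  Every generator is
deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cholesky

from .model import Component, VCModel, build_model, hybrid_phi

__all__ = [
    "SimulationSpec",
    "simulate_genotypes",
    "kinship_from_markers",
    "simulate_phenotype",
    "factorial_design",
    "multi_trial_design",
]


@dataclass
class SimulationSpec:
    """Parameters of a synthetic study."""

    n_lines: int = 300
    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    # factorial design
    n_flint: int = 30
    n_dent: int = 40
    n_hybrids: int = 400
    # multi-trial layout
    n_trials: int = 3
    obs_per_trial: int = 200
    n_rows: int = 10
    n_cols: int = 20
    trial_specific_error: bool = False
    # generative parameters
    gamma: Optional[dict[str, float]] = None
    beta: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie in (0, 0.5]")
        for name in ("n_lines", "n_markers", "n_flint", "n_dent", "n_hybrids",
                     "n_trials", "obs_per_trial", "n_rows", "n_cols"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gamma is not None:
            g = np.array(list(self.gamma.values()), dtype=float)
            if np.any(g < 0) or g.sum() <= 0:
                raise ValueError("gamma entries must be >= 0 with a positive sum")


def simulate_genotypes(
    n: int,
    L: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """n x L additive dosages in {0,1,2}, allele frequency uniform in maf_range."""
    rng = np.random.default_rng(rng)
    freq = rng.uniform(*maf_range, size=L)
    return rng.binomial(2, freq[None, :], size=(n, L)).astype(float)


def kinship_from_markers(dosages: np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    K = W W' / (sum_l 2 f_l (1 - f_l)) with W the dosages centered at 2 f_l,
    f_l the empirical allele frequency.  Monomorphic markers carry no
    information and are dropped; all-monomorphic input is an error.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2 or dosages.shape[1] < 2:
        raise ValueError("need a 2-D dosage matrix with at least 2 markers")
    freq = dosages.mean(axis=0) / 2.0
    poly = np.ptp(dosages, axis=0) > 0
    if not np.any(poly):
        raise ValueError("all markers are monomorphic; kinship undefined")
    W = dosages[:, poly] - 2.0 * freq[poly]
    denom = float(np.sum(2.0 * freq[poly] * (1.0 - freq[poly])))
    K = W @ W.T / denom
    return 0.5 * (K + K.T)


def _psd_factor(V: np.ndarray) -> np.ndarray:
    """A factor F with F F' = V, valid for singular PSD V."""
    try:
        return cholesky(V, lower=True)
    except np.linalg.LinAlgError:
        w, Q = np.linalg.eigh(V)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("component structure is not positive semidefinite")
        w = np.clip(w, 0.0, None)
        return Q * np.sqrt(w)[None, :]


def simulate_phenotype(
    model_structure: tuple[np.ndarray, Sequence[Component]],
    gamma: np.ndarray,
    beta: Optional[np.ndarray] = None,
    seed: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw y = X beta + sum_k F_k z_k with F_k F_k' = sigma_k^2 V_k.

    Factored components are sampled on their latent scale (u_k ~ N(0,
    sigma_k^2 R_k), contribution Z_k u_k), which keeps the cost at the level
    dimension.  ``beta=None`` (or an empty X) gives the null-mean case.
    """
    X, components = model_structure
    rng = np.random.default_rng(seed)
    gamma = np.asarray(gamma, dtype=float)
    if len(gamma) != len(components):
        raise ValueError("gamma and component list lengths differ")
    n = X.shape[0]
    y = np.zeros(n)
    if beta is not None:
        y += X @ np.asarray(beta, dtype=float)
    for g, comp in zip(gamma, components):
        if g == 0:
            continue
        if comp.R is not None:
            F = _psd_factor(np.asarray(comp.R, dtype=float))
            u = np.sqrt(g) * (F @ rng.standard_normal(F.shape[1]))
            y += comp.Z @ u if comp.Z is not None else u
        elif comp.Z is not None:
            u = np.sqrt(g) * rng.standard_normal(comp.Z.shape[1])
            y += comp.Z @ u
        else:
            y += np.sqrt(g) * rng.standard_normal(n)
    return y


def factorial_design(spec: SimulationSpec) -> dict:
    """Incomplete factorial crossing design between two heterotic groups.

    Returns incidences Z_F, Z_D (one-hot hybrid -> parent maps), parental
    kinships K_F, K_D, the double-relatedness matrix Phi, the cross list and
    the 4 model components (flint, dent, interaction, error).
    """
    rng = np.random.default_rng(spec.seed)
    n_F, n_D, n_H = spec.n_flint, spec.n_dent, spec.n_hybrids
    if n_H > n_F * n_D:
        raise ValueError(
            f"requested {n_H} hybrids but the full factorial has only {n_F * n_D} crosses"
        )
    geno_F = simulate_genotypes(n_F, spec.n_markers, spec.maf_range, rng)
    geno_D = simulate_genotypes(n_D, spec.n_markers, spec.maf_range, rng)
    K_F = kinship_from_markers(geno_F)
    K_D = kinship_from_markers(geno_D)
    all_crosses = [(f, d) for f in range(n_F) for d in range(n_D)]
    pick = rng.choice(len(all_crosses), size=n_H, replace=False)
    crosses = [all_crosses[i] for i in sorted(pick)]
    Z_F = np.zeros((n_H, n_F))
    Z_D = np.zeros((n_H, n_D))
    for h, (f, d) in enumerate(crosses):
        Z_F[h, f] = 1.0
        Z_D[h, d] = 1.0
    phi = hybrid_phi(K_F, K_D, crosses)
    components = [
        Component("flint", Z=Z_F, R=K_F),
        Component("dent", Z=Z_D, R=K_D),
        Component("interaction", R=phi),
        Component("error"),
    ]
    return {
        "components": components,
        "crosses": crosses,
        "K_F": K_F,
        "K_D": K_D,
        "phi": phi,
        "Z_F": Z_F,
        "Z_D": Z_D,
        "n": n_H,
    }


def multi_trial_design(spec: SimulationSpec) -> dict:
    """Multi-trial hybrid experiment with per-trial G x E interactions.

    Components: 3 main genetic effects (flint, dent, hybrid interaction),
    then per trial k a flint x trial, dent x trial, hybrid x trial, row and
    column effect (identity correlations for rows/columns), and finally one
    common error or N_T trial-specific error indicators.  With N_T trials
    the inventory is 3 + 5 N_T + 1 components for a common error variance
    and 3 + 5 N_T + N_T otherwise (44 vs 51 at N_T = 8).
    """
    rng = np.random.default_rng(spec.seed)
    base = factorial_design(spec)
    n_H = spec.n_hybrids
    N_T = spec.n_trials
    n_obs = spec.obs_per_trial
    if n_obs <= 0:
        raise ValueError("each trial needs at least one observation")
    n = N_T * n_obs

    hybrid_of = np.empty(n, dtype=int)
    trial_of = np.empty(n, dtype=int)
    row_of = np.empty(n, dtype=int)
    col_of = np.empty(n, dtype=int)
    for t in range(N_T):
        sl = slice(t * n_obs, (t + 1) * n_obs)
        hybrid_of[sl] = rng.choice(n_H, size=n_obs, replace=n_obs > n_H)
        trial_of[sl] = t
        slots = rng.choice(spec.n_rows * spec.n_cols, size=n_obs, replace=n_obs > spec.n_rows * spec.n_cols)
        row_of[sl] = slots // spec.n_cols
        col_of[sl] = slots % spec.n_cols

    def one_hot(idx: np.ndarray, width: int) -> np.ndarray:
        Z = np.zeros((len(idx), width))
        Z[np.arange(len(idx)), idx] = 1.0
        return Z

    Z_H = one_hot(hybrid_of, n_H)
    Z_F = Z_H @ base["Z_F"]
    Z_D = Z_H @ base["Z_D"]
    components = [
        Component("flint", Z=Z_F, R=base["K_F"]),
        Component("dent", Z=Z_D, R=base["K_D"]),
        Component("hybrid", Z=Z_H, R=base["phi"]),
    ]
    for t in range(N_T):
        in_t = (trial_of == t).astype(float)[:, None]
        components.append(Component(f"flint_x_trial{t + 1}", Z=Z_F * in_t, R=base["K_F"]))
        components.append(Component(f"dent_x_trial{t + 1}", Z=Z_D * in_t, R=base["K_D"]))
        components.append(Component(f"hybrid_x_trial{t + 1}", Z=Z_H * in_t, R=base["phi"]))
        components.append(Component(f"row_trial{t + 1}", Z=one_hot(row_of, spec.n_rows) * in_t))
        components.append(Component(f"col_trial{t + 1}", Z=one_hot(col_of, spec.n_cols) * in_t))
    if spec.trial_specific_error:
        for t in range(N_T):
            in_t = trial_of == t
            components.append(Component(f"error_trial{t + 1}", R=np.diag(in_t.astype(float))))
    else:
        components.append(Component("error"))
    return {
        "components": components,
        "n": n,
        "trial_of": trial_of,
        "hybrid_of": hybrid_of,
        "row_of": row_of,
        "col_of": col_of,
        "factorial": base,
    }
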