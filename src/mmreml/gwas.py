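"""Per-marker association scanning with Wald tests.

For each polymorphic marker the additive dosage (and optionally a
heterozygote-indicator dominance column) enters the fixed part of a
variance-component mixed model.  The null beta_marker = 0 is assessed with a
Wald statistic W = b' cov(b)^-1 b against a chi-square with as many degrees
of freedom as tested marker effects.  Exact mode refits the variance
components for every marker (warm-started); approximate mode estimates them
once in the base model and only re-solves the GLS per marker (the EMMAX-style
shortcut, whose p-values are close but not identical to exact ones).  LOCO
mode rebuilds the kinship for each chromosome from the markers of all other
chromosomes.  Multiple testing is handled by a Bonferroni correction at the
effective number of tests (eigenvalue-based, simpleM with a 99.5% cutoff).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .likelihood import projection_matrix
from .mm import fit_mm
from .model import Component, FitResult, build_model
from .simulate import kinship_from_markers
from .twovc import fit_two_vc_mm, spectral_cache

__all__ = [
    "wald_test",
    "run_gwas",
    "gao_meff",
    "declare_significant",
    "bic",
]


def wald_test(fit: FitResult, tested_indices: Sequence[int]) -> tuple[float, int, float]:
    """(statistic, df, p) for H0: beta_T = 0 on the tested coefficient block."""
    idx = list(tested_indices)
    beta = np.asarray(fit.beta_hat)[idx]
    cov = np.asarray(fit.beta_cov)[np.ix_(idx, idx)]
    df = len(idx)
    try:
        c = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError:
        return np.nan, df, np.nan
    stat = float(beta @ cho_solve(c, beta))
    p = float(stats.chi2.sf(stat, df))
    return stat, df, max(p, np.finfo(float).tiny)


def _prepare_markers(genotypes) -> tuple[np.ndarray, list[str]]:
    if isinstance(genotypes, pd.DataFrame):
        return genotypes.to_numpy(dtype=float), [str(c) for c in genotypes.columns]
    G = np.asarray(genotypes, dtype=float)
    return G, [f"m{j}" for j in range(G.shape[1])]


def _impute_missing(G: np.ndarray) -> np.ndarray:
    if not np.isnan(G).any():
        return G
    warnings.warn("missing dosages mean-imputed per marker", stacklevel=3)
    G = G.copy()
    means = np.nanmean(G, axis=0)
    nan_r, nan_c = np.where(np.isnan(G))
    G[nan_r, nan_c] = means[nan_c]
    return G


def _fixed_gamma_record(y, X_full, components, gamma, tested):
    """GLS + Wald at frozen variance components (approximate mode)."""
    model = build_model(y, X_full, [Component(c.name, Z=c.Z, R=c.R) for c in components])
    cache = projection_matrix(model, gamma)
    A_inv = cho_solve(cache.A_cho, np.eye(model.p))
    beta = A_inv @ (model.X.T @ cache.sigma_inv_y)
    fit = FitResult(
        gamma_hat=np.asarray(gamma, dtype=float),
        beta_hat=beta,
        beta_cov=0.5 * (A_inv + A_inv.T),
        loglik=np.nan,
        converged=True,
        n_iterations=0,
        solver_tag="gls-fixed-gamma",
    )
    return fit, wald_test(fit, tested)


def run_gwas(
    pheno: np.ndarray,
    covariates: Optional[np.ndarray],
    genotypes,
    components: Sequence[Component],
    mode: str = "exact",
    loco: bool = False,
    dominance: bool = False,
    chromosomes: Optional[Sequence] = None,
    kinship_component: int = 0,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Scan every polymorphic marker and return one Wald record per marker.

    ``components`` lists the random structure (residual last).  With K=2 the
    shared-spectral fast path is used; otherwise each marker model is fitted
    with the general MM solver.  ``loco`` replaces the correlation of
    ``kinship_component`` with a kinship estimated from all chromosomes except
    the tested one (requires ``chromosomes``).
    """
    if mode not in {"exact", "approximate"}:
        raise ValueError("mode must be 'exact' or 'approximate'")
    y = np.asarray(pheno, dtype=float).ravel()
    n = y.shape[0]
    X_base = (
        np.ones((n, 1))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    G, names = _prepare_markers(genotypes)
    G = _impute_missing(G)
    L = G.shape[1]
    chrom = np.asarray(chromosomes) if chromosomes is not None else np.zeros(L, dtype=int)
    if loco and chromosomes is None:
        raise ValueError("loco requires a chromosome assignment per marker")

    records = []
    p0 = X_base.shape[1]
    for ch in np.unique(chrom):
        in_ch = chrom == ch
        comps = list(components)
        if loco:
            keep = ~in_ch
            if keep.sum() < 2:
                raise ValueError(f"chromosome {ch}: too few off-chromosome markers for LOCO")
            K_loco = kinship_from_markers(G[:, keep])
            base_c = comps[kinship_component]
            comps[kinship_component] = Component(base_c.name, Z=base_c.Z, R=K_loco)
        records.extend(
            _scan_chromosome(
                y, X_base, G[:, in_ch], [names[j] for j in np.flatnonzero(in_ch)],
                ch, comps, mode, dominance, p0, tol,
            )
        )
    df = pd.DataFrame.from_records(
        records,
        columns=[
            "marker_id", "chromosome", "beta_add", "se_add", "beta_dom",
            "wald_stat", "df", "p_value", "mode", "skipped_reason",
        ],
    )
    return df


def _scan_chromosome(y, X_base, G, names, ch, components, mode, dominance, p0, tol):
    base_model = build_model(y, X_base, [Component(c.name, Z=c.Z, R=c.R) for c in components])
    K = base_model.K
    use_fast = K == 2 and not dominance
    records = []
    if use_fast:
        try:
            cache = spectral_cache(base_model)
        except np.linalg.LinAlgError:
            use_fast = False
    base_fit = (
        fit_two_vc_mm(cache, tol=tol) if use_fast else fit_mm(base_model, tol=tol, compute_se=False)
    )
    warm = base_fit.gamma_hat

    for j in range(G.shape[1]):
        x = G[:, j]
        rec = {
            "marker_id": names[j], "chromosome": ch, "beta_add": np.nan,
            "se_add": np.nan, "beta_dom": np.nan, "wald_stat": np.nan,
            "df": 0, "p_value": np.nan, "mode": mode, "skipped_reason": "",
        }
        if np.ptp(x) == 0:
            rec["skipped_reason"] = "monomorphic"
            records.append(rec)
            continue
        cols = [x]
        if dominance:
            cols.append((x == 1).astype(float))
        X_full = np.column_stack([X_base] + cols)
        tested = list(range(p0, p0 + len(cols)))
        if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
            rec["skipped_reason"] = "collinear with covariates"
            records.append(rec)
            continue
        if mode == "approximate":
            fit, (stat, df, p) = _fixed_gamma_record(y, X_full, components, warm, tested)
        elif use_fast:
            Xj = np.column_stack([cache.X_tilde_base, cache.Lambda @ X_full[:, p0:]])
            d0 = base_fit.diagnostics["delta"]
            fit = fit_two_vc_mm(cache, Xj, init_delta=max(d0, 1e-8), tol=tol)
            stat, df, p = wald_test(fit, tested)
        else:
            marker_model = build_model(
                y, X_full, [Component(c.name, Z=c.Z, R=c.R) for c in components]
            )
            fit = fit_mm(marker_model, init=np.maximum(warm, 1e-8 * warm.sum()),
                         tol=tol, compute_se=False)
            stat, df, p = wald_test(fit, tested)
        rec.update(
            beta_add=float(fit.beta_hat[p0]),
            se_add=float(np.sqrt(max(fit.beta_cov[p0, p0], 0.0))),
            beta_dom=float(fit.beta_hat[p0 + 1]) if dominance else np.nan,
            wald_stat=stat, df=df, p_value=p,
        )
        records.append(rec)
    return records


def gao_meff(genotypes, chromosomes: Optional[Sequence] = None, cutoff: float = 0.995) -> int:
    """Effective number of tests (simpleM): per chromosome, the smallest
    number of leading eigenvalues of the marker correlation matrix whose sum
    reaches ``cutoff`` of the total, summed over chromosomes."""
    G, _ = _prepare_markers(genotypes)
    G = _impute_missing(G)
    poly = np.ptp(G, axis=0) > 0
    G = G[:, poly]
    L = G.shape[1]
    if L < 2:
        raise ValueError("need at least 2 polymorphic markers")
    chrom = (
        np.zeros(L, dtype=int)
        if chromosomes is None
        else np.asarray(chromosomes)[poly]
    )
    meff = 0
    for ch in np.unique(chrom):
        block = G[:, chrom == ch]
        corr = np.corrcoef(block, rowvar=False)
        corr = np.atleast_2d(corr)
        w = np.linalg.eigvalsh(corr)[::-1]
        w = np.clip(w, 0.0, None)
        cum = np.cumsum(w) / w.sum()
        meff += int(np.searchsorted(cum, cutoff) + 1)
    return meff


def declare_significant(records: pd.DataFrame, meff: int, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni at the effective number of tests: keep p <= alpha / meff."""
    if len(records) == 0:
        return records
    return records[records["p_value"] <= alpha / meff]


def bic(fit: FitResult, n_params_override: Optional[int] = None) -> float:
    """BIC = -2 L_R + q log(m), with m = n - p the residual degrees of
    freedom (the ReML sample size) and q the number of free variance
    parameters.  Uses the same additive-constant convention as the fitted
    restricted log-likelihood, so only differences between fits on the same
    data are meaningful."""
    if not fit.converged:
        warnings.warn("BIC computed from an unconverged fit", stacklevel=2)
    m = fit.diagnostics.get("m")
    if m is None:
        raise ValueError("fit does not record m (residual degrees of freedom)")
    q = n_params_override if n_params_override is not None else len(fit.gamma_hat)
    return float(-2.0 * fit.loglik + q * np.log(m))
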