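"""Readers and writers for phenotype, kinship and genotype tables.

All tables are TSV/CSV (delimiter sniffed from the extension, tab default).
The row order of the phenotype file defines the observation coordinate
system; kinships and genotypes are reindexed to it by string identifier.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .model import Component, FitResult, VCModel, build_model

__all__ = [
    "ModelConfig",
    "read_phenotypes",
    "read_kinship",
    "read_genotypes",
    "assemble_model",
    "write_fit_results",
    "write_gwas_results",
]

_PLINK_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype/covariate table with an ``id`` column (first column if unnamed)."""
    df = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
    if "id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "id"})
    df["id"] = df["id"].astype(str)
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        import logging

        logging.getLogger(__name__).info(
            "dropping %d rows with missing values", n_missing
        )
        df = df.dropna()
    return df.reset_index(drop=True)


def read_kinship(path) -> pd.DataFrame:
    """Square labeled kinship/correlation matrix."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"kinship in {path} is not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError(f"kinship in {path} has mismatched row/column labels")
    return df


def read_genotypes(path, dialect: str = "auto") -> pd.DataFrame:
    """Dosage matrix, rows = individuals (index ``id``), columns = markers.

    Understands plain matrices (first column = id) and the PLINK ``.raw``
    additive dialect (whitespace-separated, FID/IID/... metadata columns).
    """
    path = str(path)
    if dialect == "auto":
        with open(path) as fh:
            header = fh.readline().split()
        dialect = "raw" if header[:2] == ["FID", "IID"] or "IID" in header[:6] else "plain"
    if dialect == "raw":
        df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
        idx = df["IID"].astype(str)
        df = df.drop(columns=[c for c in _PLINK_RAW_META if c in df.columns])
        df.index = idx
    elif dialect == "plain":
        df = pd.read_csv(path, sep=_sep(path), index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    bad = df.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    nan_new = bad.isna() & ~df.isna()
    if nan_new.any().any():
        r, c = np.argwhere(nan_new.to_numpy())[0]
        raise ValueError(
            f"non-numeric dosage at row {df.index[r]!r}, marker {df.columns[c]!r}"
        )
    return bad


@dataclass
class ModelConfig:
    """Declarative model description loaded from YAML/JSON."""

    trait: str
    fixed: list[str] = field(default_factory=list)
    components: list[dict] = field(default_factory=list)
    solver: str = "mm"
    tol: float = 1e-5
    max_iter: int = 1000
    accelerate: bool = True
    mme: str = "auto"

    @classmethod
    def load(cls, path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        names = [c["name"] for c in cfg.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        base = Path(path).parent
        for c in cfg.components:
            kin = c.get("kinship")
            if kin and not (base / kin).exists():
                raise FileNotFoundError(f"kinship file {kin} (component {c['name']})")
        return cfg


def _incidence(ids: pd.Series, levels: list[str]) -> np.ndarray:
    pos = {lv: i for i, lv in enumerate(levels)}
    missing = sorted(set(ids) - set(levels))
    if missing:
        raise ValueError(f"ids absent from the kinship/level set: {missing[:10]}")
    Z = np.zeros((len(ids), len(levels)))
    for r, ident in enumerate(ids):
        Z[r, pos[ident]] = 1.0
    return Z


def assemble_model(pheno: pd.DataFrame, config: ModelConfig, base_dir=".") -> VCModel:
    """Build a VCModel from a phenotype table and a declarative config.

    Each configured component has a ``name`` and either a ``kinship`` file
    (with an optional ``factor`` column in the phenotype table mapping rows
    to kinship levels; default ``id``) or ``identity: true`` on a factor.
    A trailing identity error component is appended if none is declared.
    """
    base_dir = Path(base_dir)
    y = pheno[config.trait].to_numpy(dtype=float)
    n = len(pheno)
    X_cols = [np.ones(n)]
    for c in config.fixed:
        col = pheno[c]
        if col.dtype == object:
            X_cols.extend(pd.get_dummies(col, drop_first=True).to_numpy(dtype=float).T)
        else:
            X_cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(X_cols)
    comps = []
    for c in config.components:
        factor = c.get("factor", "id")
        ids = pheno[factor].astype(str)
        if c.get("kinship"):
            kin = read_kinship(base_dir / c["kinship"])
            levels = list(kin.index)
            Z = _incidence(ids, levels)
            identity_map = len(levels) == n and (ids.to_numpy() == np.array(levels)).all()
            comps.append(
                Component(c["name"], Z=None if identity_map else Z, R=kin.to_numpy())
            )
        else:
            levels = sorted(ids.unique())
            comps.append(Component(c["name"], Z=_incidence(ids, levels)))
    if not comps or comps[-1].Z is not None or comps[-1].R is not None:
        comps.append(Component("error"))
    return build_model(y, X, comps)


def _metadata(extra: dict) -> dict:
    import mmreml

    return {
        "package": "mmreml",
        "version": getattr(mmreml, "__version__", "unknown"),
        "python": platform.python_version(),
        "numpy": np.__version__,
        **extra,
    }


def write_fit_results(fit: FitResult, prefix: str, extra_meta: Optional[dict] = None) -> None:
    """PREFIX.variances.tsv, PREFIX.fixed.tsv and a PREFIX.meta.json sidecar."""
    prefix = str(prefix)
    names = fit.component_names or [f"vc{k + 1}" for k in range(len(fit.gamma_hat))]
    se = fit.gamma_se if fit.gamma_se is not None else [np.nan] * len(names)
    pd.DataFrame(
        {"component": names, "estimate": fit.gamma_hat, "se": se}
    ).to_csv(prefix + ".variances.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "coefficient": [f"b{j}" for j in range(len(fit.beta_hat))],
            "estimate": fit.beta_hat,
            "se": np.sqrt(np.clip(np.diag(fit.beta_cov), 0, None)),
        }
    ).to_csv(prefix + ".fixed.tsv", sep="\t", index=False)
    meta = _metadata(
        {
            "solver_tag": fit.solver_tag,
            "converged": bool(fit.converged),
            "n_iterations": int(fit.n_iterations),
            "loglik": float(fit.loglik),
            "warnings": fit.warnings,
            **(extra_meta or {}),
        }
    )
    with open(prefix + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def write_gwas_results(table: pd.DataFrame, prefix: str, extra_meta: Optional[dict] = None) -> None:
    prefix = str(prefix)
    table.to_csv(prefix + ".gwas.tsv", sep="\t", index=False)
    with open(prefix + ".meta.json", "w") as fh:
        json.dump(_metadata(extra_meta or {}), fh, indent=2)
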