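"""Genotype means (BLUEs), variance components and covariance matrices.

Estimation is on the balanced two-way genotype x environment layout with
replicates, using closed-form method-of-moments (ANOVA / MANOVA mean squares
and mean cross-products).  For balanced data the genotype adjusted means
coincide with plain genotype means and the moment estimators with REML, so
the closed forms double as checkable references.

All covariance matrices are on the entry-mean basis: P is the covariance of
genotype means across the selected environments, C the genetic covariance
freed of G by environment and residual contamination,

    C_hat = (MCP_G - MCP_GE) / (r * e),      P_hat = MCP_G / (r * e),

with r replicates and e environments, so that diag(P) >= diag(C).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import KEY_COLUMNS, TrialData, psd_factor

__all__ = [
    "BlueTable",
    "VarianceComponents",
    "CovariancePair",
    "compute_blues",
    "variance_components",
    "broad_sense_heritability",
    "covariance_matrices",
    "ensure_psd",
]

logger = logging.getLogger(__name__)


@dataclass
class BlueTable:
    """Genotype adjusted means for one dataset (conventional/organic/combined)."""

    dataset_label: str
    values: pd.DataFrame  # genotype-indexed, one column per trait

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicated genotype ids in BLUE table")

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass
class VarianceComponents:
    trait: str
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    n_env: int
    n_rep: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class CovariancePair:
    """Genetic (C) and phenotypic (P) covariance matrices, entry-mean basis."""

    C: pd.DataFrame
    P: pd.DataFrame
    dataset_label: str
    basis: str = "entry-mean"

    def __post_init__(self) -> None:
        for name, M in (("C", self.C), ("P", self.P)):
            if not np.allclose(M.values, M.values.T, atol=1e-8):
                raise ValueError(f"{name} is not symmetric")
        if np.linalg.matrix_rank(self.P.values) < self.P.shape[0]:
            raise ValueError("P is singular; condition it with ensure_psd first")

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(self.C.columns)


def _subset_frame(trial: TrialData, subset: str) -> pd.DataFrame:
    df = trial.subset(subset)
    if df.empty:
        raise ValueError(f"subset {subset!r} selects no records")
    return df


def _is_balanced(df: pd.DataFrame, traits) -> bool:
    if df[list(traits)].isna().any().any():
        return False
    counts = df.groupby(["genotype", "environment"], sort=False).size()
    n_g = df["genotype"].nunique()
    n_e = df["environment"].nunique()
    return len(counts) == n_g * n_e and counts.nunique() == 1


def compute_blues(trial: TrialData, subset: str = "combined") -> BlueTable:
    """Genotype adjusted means from a two-way genotype + environment model.

    On complete balanced data this reduces exactly to the arithmetic mean of
    all plots of the genotype.  With missing plots the adjusted mean is the
    least-squares solution of the additive two-way model, evaluated as the
    genotype effect plus the average environment effect, which removes the
    bias from genotypes unevenly represented across environments.
    """
    df = _subset_frame(trial, subset)
    traits = list(trial.trait_names)
    df = df.dropna(subset=traits)
    if df.empty:
        raise ValueError("no complete records in subset")
    all_geno = trial.data["genotype"].unique()
    present = df["genotype"].unique()
    dropped = sorted(set(all_geno) - set(present))
    if dropped:
        logger.warning("genotypes with no records excluded from BLUEs: %s", dropped)

    if _is_balanced(df, traits):
        vals = df.groupby("genotype", sort=True)[traits].mean()
        return BlueTable(dataset_label=subset, values=vals)

    # min-norm least squares on genotype + environment dummy design
    geno = pd.Categorical(df["genotype"])
    env = pd.Categorical(df["environment"])
    n, g, e = len(df), len(geno.categories), len(env.categories)
    X = np.zeros((n, g + e))
    X[np.arange(n), geno.codes] = 1.0
    X[np.arange(n), g + env.codes] = 1.0
    Y = df[traits].to_numpy()
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    geno_eff, env_eff = beta[:g], beta[g:]
    blues = geno_eff + env_eff.mean(axis=0)
    vals = pd.DataFrame(blues, index=pd.Index(geno.categories, name="genotype"),
                        columns=traits).sort_index()
    return BlueTable(dataset_label=subset, values=vals)


def _anova_frames(df: pd.DataFrame, traits: list[str]):
    """Cell/genotype/environment mean decomposition for the balanced layout."""
    g = df["genotype"].nunique()
    e = df["environment"].nunique()
    r = len(df) // (g * e)
    cell = df.groupby(["genotype", "environment"], sort=True)[traits].mean()
    gm = df.groupby("genotype", sort=True)[traits].mean()
    em = df.groupby("environment", sort=True)[traits].mean()
    grand = df[traits].mean()
    return g, e, r, cell, gm, em, grand


def _require_balanced(df: pd.DataFrame, traits) -> None:
    if not _is_balanced(df, traits):
        raise ValueError(
            "unbalanced data: moment estimators need the complete balanced "
            "layout; impute via the two-way fit or drop incomplete genotypes"
        )


def variance_components(trial: TrialData, trait: str,
                        subset: str = "combined") -> VarianceComponents:
    """Method-of-moments components from the two-way ANOVA with replicates.

    sigma2_e = MS_error, sigma2_ge = (MS_GE - MS_error)/r,
    sigma2_g = (MS_G - MS_GE)/(r*e); negative estimates are truncated at
    zero and flagged.
    """
    if trait not in trial.trait_names:
        raise ValueError(f"unknown trait {trait!r}")
    df = _subset_frame(trial, subset)
    _require_balanced(df, [trait])
    g, e, r, cell, gm, em, grand = _anova_frames(df, [trait])

    y = df[trait].to_numpy()
    cell_for_row = cell[trait].loc[
        list(zip(df["genotype"], df["environment"]))
    ].to_numpy()
    ms_error = (
        float(((y - cell_for_row) ** 2).sum() / (g * e * (r - 1))) if r > 1 else 0.0
    )
    if r == 1:
        warnings.warn("single replicate: residual variance inestimable, set to 0")

    ms_g = r * e * float(((gm[trait] - grand[trait]) ** 2).sum()) / (g - 1)
    if e > 1:
        inter = (
            cell[trait]
            - gm[trait].reindex(cell.index.get_level_values(0)).to_numpy()
            - em[trait].reindex(cell.index.get_level_values(1)).to_numpy()
            + grand[trait]
        )
        ms_ge = r * float((inter**2).sum()) / ((g - 1) * (e - 1))
        s2_ge = (ms_ge - ms_error) / r
        s2_g = (ms_g - ms_ge) / (r * e)
    else:
        warnings.warn("single environment: G×E variance inestimable, set to 0")
        s2_ge = 0.0
        s2_g = (ms_g - ms_error) / r

    truncated = s2_g < 0 or s2_ge < 0
    if truncated:
        logger.warning(
            "negative component estimate truncated to 0 for trait %s "
            "(sigma2_g=%.4g, sigma2_ge=%.4g)", trait, s2_g, s2_ge
        )
    return VarianceComponents(
        trait=trait,
        sigma2_g=max(s2_g, 0.0),
        sigma2_ge=max(s2_ge, 0.0),
        sigma2_e=max(ms_error, 0.0),
        n_env=e,
        n_rep=r,
        truncated=truncated,
    )


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """Entry-mean H2 = s2_g / (s2_g + s2_ge/e + s2_e/(e*r)), in [0, 1]."""
    denom = vc.sigma2_g + vc.sigma2_ge / vc.n_env + vc.sigma2_e / (vc.n_env * vc.n_rep)
    if denom == 0.0:
        warnings.warn("all variance components zero; heritability defined as 0")
        return 0.0
    return vc.sigma2_g / denom


def _mcp(dev: np.ndarray, dof: int) -> np.ndarray:
    return dev.T @ dev / dof


def covariance_matrices(trial: TrialData, subset: str = "combined",
                        floor: float = 1e-8) -> CovariancePair:
    """Entry-mean genetic and phenotypic covariance matrices for a dataset.

    Multivariate analogue of :func:`variance_components` built from mean
    cross-product matrices; C_hat = (MCP_G - MCP_GE)/(r*e), P_hat =
    MCP_G/(r*e) (the covariance of genotype means).  Both are passed through
    :func:`ensure_psd`; a P that stays singular after conditioning is
    rejected.
    """
    traits = list(trial.trait_names)
    if len(traits) < 2:
        raise ValueError("need at least two traits for covariance matrices")
    df = _subset_frame(trial, subset)
    _require_balanced(df, traits)
    g, e, r, cell, gm, em, grand = _anova_frames(df, traits)
    if g < 2:
        raise ValueError("need at least two genotypes")

    dev_g = (gm - grand).to_numpy()
    mcp_g = _mcp(dev_g, g - 1) * r * e
    if e > 1:
        inter = (
            cell.to_numpy()
            - gm.reindex(cell.index.get_level_values(0)).to_numpy()
            - em.reindex(cell.index.get_level_values(1)).to_numpy()
            + grand.to_numpy()
        )
        mcp_ge = _mcp(inter, (g - 1) * (e - 1)) * r
    else:
        mcp_ge = np.zeros_like(mcp_g)

    C = ensure_psd((mcp_g - mcp_ge) / (r * e), floor=floor)
    P = ensure_psd(mcp_g / (r * e), floor=floor)
    if np.linalg.cond(P) > 1e12:
        raise ValueError("phenotypic matrix P singular after conditioning")
    idx = pd.Index(traits)
    return CovariancePair(
        C=pd.DataFrame(C, index=idx, columns=idx),
        P=pd.DataFrame(P, index=idx, columns=idx),
        dataset_label=subset,
    )


def ensure_psd(M: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues of a symmetric matrix at ``floor``.

    Returns the input unchanged (same object) when already well conditioned;
    otherwise reconstructs from the clipped spectrum, preserving the
    remaining eigenpairs, and logs the repair.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("ensure_psd needs a square matrix")
    if not np.allclose(M, M.T, atol=1e-8, rtol=1e-8):
        raise ValueError("ensure_psd needs a symmetric matrix")
    vals, vecs = np.linalg.eigh((M + M.T) / 2.0)
    if vals.min() >= floor:
        return M
    logger.warning("PSD repair: clipping eigenvalues below %.3g (min %.3g)",
                   floor, vals.min())
    out = (vecs * np.clip(vals, floor, None)) @ vecs.T
    return (out + out.T) / 2.0
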