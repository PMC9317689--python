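"""Synthetic multi-environment, multi-trait phenotype trials with known genetic truth.

The generator emulates a balanced spring-wheat variety trial: ``n_genotypes``
lines grown in several environments under one or more management systems
(e.g. conventional / organic site-years), ``n_rep`` replicate plots each.
The phenotype of genotype *i* in environment *j*, replicate *k* is the
vector sum

    y_ijk = mu + g_i + env_j + ge_ij + eps_ijk

where ``g_i ~ MVN(0, C_true)`` is the true genotypic value, ``env_j`` an
environment main effect, ``ge_ij ~ MVN(0, gxe_cov)`` a genotype-by-environment
deviation independent across environments, and ``eps_ijk ~ MVN(0, residual_cov)``
a plot residual.  The draws of ``g_i`` are retained as a truth table so that
realized genetic gains of any downstream selection can be measured exactly.

The layout is complete and balanced (every genotype in every environment and
replicate); unbalancedness is introduced only by explicitly masking plots
with :func:`mask_plots`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "KEY_COLUMNS",
    "SimulationSpec",
    "TrialData",
    "simulate_met",
    "default_wheat_spec",
    "implied_heritability",
    "mask_plots",
]

#: columns identifying one plot record, in canonical order
KEY_COLUMNS = ["genotype", "management", "environment", "replicate"]


def _as_square(M, t: int, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (t, t):
        raise ValueError(f"{name} must be {t}x{t}, got shape {M.shape}")
    return M


def psd_factor(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Return L with L @ L.T = M for a symmetric PSD matrix.

    Uses the eigendecomposition so that exactly-zero matrices factor to the
    zero matrix (degenerate no-noise simulations are then exact).  Raises
    ``ValueError`` naming the offending matrix if M is not symmetric PSD.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10, rtol=1e-8):
        raise ValueError(f"{name} is not symmetric")
    vals, vecs = np.linalg.eigh((M + M.T) / 2.0)
    tol = 1e-8 * max(1.0, float(np.abs(vals).max(initial=0.0)))
    if vals.min(initial=0.0) < -tol:
        raise ValueError(
            f"{name} is not positive semi-definite (min eigenvalue {vals.min():.3g})"
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated multi-environment trial.

    Covariance matrices are on the per-plot trait scale (trait units squared).
    ``env_effect_sd`` sets the spread of environment main effects per trait;
    these cancel from all genotype contrasts, so the scale is free.
    """

    n_genotypes: int
    trait_names: tuple[str, ...]
    trait_means: np.ndarray
    C_true: np.ndarray
    gxe_cov: np.ndarray
    residual_cov: np.ndarray
    n_env_per_management: dict[str, int]
    n_rep: int
    env_effect_sd: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        t = len(self.trait_names)
        if t < 1:
            raise ValueError("need at least one trait")
        if self.n_genotypes < 1 or self.n_rep < 1:
            raise ValueError("n_genotypes and n_rep must be positive")
        if not self.n_env_per_management or any(
            v < 1 for v in self.n_env_per_management.values()
        ):
            raise ValueError("every management must have at least one environment")
        object.__setattr__(self, "trait_means", np.asarray(self.trait_means, float))
        object.__setattr__(self, "env_effect_sd", np.asarray(self.env_effect_sd, float))
        if self.trait_means.shape != (t,) or self.env_effect_sd.shape != (t,):
            raise ValueError("trait_means and env_effect_sd must have length t")
        for name in ("C_true", "gxe_cov", "residual_cov"):
            M = _as_square(getattr(self, name), t, name)
            object.__setattr__(self, name, M)
            psd_factor(M, name)  # raises if not symmetric PSD

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_environments(self) -> int:
        return sum(self.n_env_per_management.values())

    def with_seed(self, seed: int) -> "SimulationSpec":
        return replace(self, seed=int(seed))


@dataclass
class TrialData:
    """Long-format plot records plus (for simulations) the genetic truth.

    ``data`` has columns ``genotype, management, environment, replicate`` and
    one column per trait.  ``truth`` is a genotype-indexed frame of the true
    genotypic values g_i (deviations plus trait means), present only for
    simulated data.
    """

    data: pd.DataFrame
    trait_names: tuple[str, ...]
    truth: pd.DataFrame | None = None
    env_effects: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in KEY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trial data lacks key columns {missing}")
        for trait in self.trait_names:
            if trait not in self.data.columns:
                raise ValueError(f"trial data lacks trait column {trait!r}")
        if self.data.duplicated(KEY_COLUMNS).any():
            raise ValueError("duplicate (genotype, environment, replicate) records")

    @property
    def genotypes(self) -> list:
        return sorted(self.data["genotype"].unique().tolist())

    @property
    def managements(self) -> list[str]:
        return sorted(self.data["management"].unique().tolist())

    def subset(self, label: str) -> pd.DataFrame:
        """Records for one management label, or all records for ``'combined'``."""
        if label == "combined":
            return self.data
        out = self.data[self.data["management"] == label]
        if out.empty:
            raise ValueError(f"no records for management {label!r}")
        return out


def simulate_met(spec: SimulationSpec) -> TrialData:
    """Simulate a balanced multi-environment trial under ``spec``.

    Draw order is fixed (genotypic values, environment effects, G×E, residuals)
    so the same seed reproduces the same data bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.n_traits
    n_g, n_rep = spec.n_genotypes, spec.n_rep

    Lg = psd_factor(spec.C_true, "C_true")
    Lge = psd_factor(spec.gxe_cov, "gxe_cov")
    Le = psd_factor(spec.residual_cov, "residual_cov")

    g_dev = rng.standard_normal((n_g, t)) @ Lg.T
    envs: list[tuple[str, str]] = []
    for mgmt, n_env in spec.n_env_per_management.items():
        envs.extend((mgmt, f"{mgmt}_{j + 1}") for j in range(n_env))
    n_env_total = len(envs)
    env_dev = rng.standard_normal((n_env_total, t)) * spec.env_effect_sd
    ge_dev = rng.standard_normal((n_g * n_env_total, t)) @ Lge.T
    eps = rng.standard_normal((n_g * n_env_total * n_rep, t)) @ Le.T

    genotype_ids = [f"G{i + 1:03d}" for i in range(n_g)]
    # genotype-major, environment, replicate ordering
    gi = np.repeat(np.arange(n_g), n_env_total * n_rep)
    ei = np.tile(np.repeat(np.arange(n_env_total), n_rep), n_g)
    ri = np.tile(np.arange(1, n_rep + 1), n_g * n_env_total)
    cell = gi * n_env_total + ei  # genotype x environment cell index

    values = spec.trait_means + g_dev[gi] + env_dev[ei] + ge_dev[cell] + eps

    data = pd.DataFrame(
        {
            "genotype": np.array(genotype_ids)[gi],
            "management": np.array([m for m, _ in envs])[ei],
            "environment": np.array([e for _, e in envs])[ei],
            "replicate": ri,
        }
    )
    for j, trait in enumerate(spec.trait_names):
        data[trait] = values[:, j]

    truth = pd.DataFrame(
        spec.trait_means + g_dev, index=pd.Index(genotype_ids, name="genotype"),
        columns=list(spec.trait_names),
    )
    env_effects = pd.DataFrame(
        env_dev, index=pd.Index([e for _, e in envs], name="environment"),
        columns=list(spec.trait_names),
    )
    return TrialData(data=data, trait_names=spec.trait_names, truth=truth,
                     env_effects=env_effects)


#: canonical trait order used by the wheat defaults
WHEAT_TRAITS = ("maturity", "height", "yield", "gpc")

# genetic correlations among (maturity d, height cm, yield t/ha, GPC %);
# yield rows carry the reported values, the rest are mild plausible choices
_WHEAT_GENETIC_CORR = np.array(
    [
        [1.00, 0.15, 0.50, -0.30],
        [0.15, 1.00, -0.47, 0.10],
        [0.50, -0.47, 1.00, -0.56],
        [-0.30, 0.10, -0.56, 1.00],
    ]
)
_WHEAT_GENETIC_SD = np.array([3.0, 7.0, 0.55, 1.25])
# G×E and residual variances as multiples of the genetic variance, per trait;
# tuned so entry-mean heritability per management lands in the 0.32-0.80 band
_WHEAT_GXE_RATIO = np.array([1.0, 1.5, 2.5, 0.8])
_WHEAT_RESID_RATIO = np.array([2.0, 3.0, 5.0, 1.6])


def default_wheat_spec(seed: int) -> SimulationSpec:
    """Spec emulating a 196-cultivar spring wheat panel.

    Four traits: days to maturity, plant height (cm), grain yield (t/ha) and
    grain protein content (%), grown at 5 conventionally and 4 organically
    managed environments with 2 replicates.  Grain yield is genetically
    negatively correlated with GPC (-0.56) and height (-0.47) and positively
    with maturity (0.50); trait means and spreads put simulated genotype
    means inside realistic agronomic ranges (maturity ~81-97 d, height
    ~71-107 cm, yield ~2.8-6.7 t/ha, GPC ~10.6-17.7 %).
    """
    sd = _WHEAT_GENETIC_SD
    C = _WHEAT_GENETIC_CORR * np.outer(sd, sd)
    gxe_sd = sd * np.sqrt(_WHEAT_GXE_RATIO)
    res_sd = sd * np.sqrt(_WHEAT_RESID_RATIO)
    return SimulationSpec(
        n_genotypes=196,
        trait_names=WHEAT_TRAITS,
        trait_means=np.array([89.0, 89.0, 4.8, 14.3]),
        C_true=C,
        gxe_cov=_WHEAT_GENETIC_CORR * np.outer(gxe_sd, gxe_sd),
        residual_cov=_WHEAT_GENETIC_CORR * np.outer(res_sd, res_sd),
        n_env_per_management={"conventional": 5, "organic": 4},
        n_rep=2,
        env_effect_sd=np.array([2.0, 5.0, 0.6, 0.8]),
        seed=int(seed),
    )


def implied_heritability(spec: SimulationSpec, management: str | None = None) -> np.ndarray:
    """Entry-mean broad-sense heritability implied by the spec's components.

    H2 = sigma2_g / (sigma2_g + sigma2_ge/e + sigma2_eps/(e*r)) per trait,
    with e the number of environments of ``management`` (all if None).
    """
    if management is None:
        e = spec.n_environments
    else:
        e = spec.n_env_per_management[management]
    vg = np.diag(spec.C_true)
    vge = np.diag(spec.gxe_cov)
    ve = np.diag(spec.residual_cov)
    denom = vg + vge / e + ve / (e * spec.n_rep)
    with np.errstate(invalid="ignore"):
        h2 = np.where(denom > 0, vg / np.where(denom > 0, denom, 1.0), 0.0)
    return h2


def mask_plots(trial: TrialData, fraction: float, seed: int) -> TrialData:
    """Drop a random fraction of plot records, producing unbalanced data.

    Missingness is represented by absent records (not NaN cells).  At least
    one record per genotype is always retained.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    data = trial.data
    drop = rng.random(len(data)) < fraction
    kept = data[~drop]
    lost = set(data["genotype"].unique()) - set(kept["genotype"].unique())
    if lost:  # guarantee every genotype keeps at least one plot
        first = data[data["genotype"].isin(lost)].groupby("genotype").head(1)
        kept = pd.concat([kept, first]).sort_index()
    return TrialData(data=kept.reset_index(drop=True), trait_names=trial.trait_names,
                     truth=trial.truth, env_effects=trial.env_effects)
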