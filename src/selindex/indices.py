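"""Smith linear phenotypic selection index (LPSI) and constrained variants.

Net genetic merit of line *i* is H_i = w'g_i with economic weights w and true
genotypic values g ~ MVN(0, C).  The LPSI is I_i = b'y_i on phenotypes
(here genotype BLUEs) with covariance P; the merit-optimal Smith coefficients
solve P b = C w, maximizing the correlation

    rho_HI = w'Cb / sqrt(w'Cw * b'Pb).

Selection of the top fraction p at standardized intensity k gives the
response and per-trait expected genetic gains

    R = k * sigma_H * rho_HI,        E = k * C b / sigma_I.

The constrained index (Kempthorne-Nordskog null restrictions, Mallard
predetermined proportional gains) projects the Smith coefficients:
b = K beta with K = I - Q, Q = P^-1 M (M' P^-1 M)^-1 M', M' = D' U' C
(null case D = U, so M' = U' C), which zeroes the expected gain of every
restricted trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

__all__ = [
    "EconomicWeights",
    "RestrictionSpec",
    "IndexModel",
    "IndexEvaluation",
    "net_merit_variance",
    "lpsi_coefficients",
    "mallard_D",
    "restricted_coefficients",
    "index_values",
    "selection_intensity",
    "evaluate_index",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EconomicWeights:
    """Per-trait economic weights w (merit units per trait unit)."""

    values: tuple[float, ...]
    trait_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.values, float)
        if not np.all(np.isfinite(w)):
            raise ValueError("economic weights must be finite")
        if not np.any(w != 0):
            raise ValueError("at least one economic weight must be nonzero")
        if self.trait_names is not None and len(self.trait_names) != len(w):
            raise ValueError("trait_names/weights length mismatch")
        object.__setattr__(self, "values", tuple(float(v) for v in w))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, float)


def _as_weights(w) -> np.ndarray:
    if isinstance(w, EconomicWeights):
        return w.as_array()
    return np.asarray(w, float)


@dataclass(frozen=True)
class RestrictionSpec:
    """Constraint set for the restricted index.

    ``restricted`` names the traits whose expected gain is constrained (each
    contributes one indicator row of U'); ``mode='null'`` forces their gains
    to zero, ``mode='proportional'`` forces them into the ratios of ``d``.
    An empty restriction reproduces the unrestricted LPSI.
    """

    restricted: tuple[str, ...] = ()
    mode: str = "null"
    d: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("null", "proportional"):
            raise ValueError("mode must be 'null' or 'proportional'")
        if len(set(self.restricted)) != len(self.restricted):
            raise ValueError("restricted traits must be distinct")
        if self.mode == "proportional":
            if self.d is None or len(self.d) != len(self.restricted):
                raise ValueError("proportional mode needs d of length r")
            if not all(np.isfinite(self.d)) or not any(v != 0 for v in self.d):
                raise ValueError("d must be finite and nonzero")
        elif self.d is not None:
            raise ValueError("d is only meaningful in proportional mode")
        object.__setattr__(self, "restricted", tuple(self.restricted))

    @property
    def n_restricted(self) -> int:
        return len(self.restricted)

    def u_transpose(self, trait_names) -> np.ndarray:
        """r x t indicator matrix U' (one 1 per row, marking the trait)."""
        trait_names = list(trait_names)
        if self.restricted and len(self.restricted) >= len(trait_names):
            raise ValueError("need fewer restrictions than traits (r < t)")
        U_t = np.zeros((len(self.restricted), len(trait_names)))
        for q, trait in enumerate(self.restricted):
            if trait not in trait_names:
                raise ValueError(f"restricted trait {trait!r} not among {trait_names}")
            U_t[q, trait_names.index(trait)] = 1.0
        return U_t

    @property
    def label(self) -> str:
        if not self.restricted:
            return "LPSI"
        if self.mode == "null":
            inner = ", ".join(f"{t}=0" for t in self.restricted)
        else:
            inner = ", ".join(f"{t}:{v:g}" for t, v in zip(self.restricted, self.d))
        return f"RLPSI({inner})"


@dataclass
class IndexModel:
    """Fitted index coefficients together with their provenance."""

    scenario: str
    b: np.ndarray
    trait_names: tuple[str, ...]
    C: np.ndarray
    P: np.ndarray
    w: np.ndarray
    restriction: RestrictionSpec | None = None

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, float)
        if not np.all(np.isfinite(self.b)):
            raise ValueError("index coefficients must be finite")


@dataclass
class IndexEvaluation:
    """Selection parameters of one (weights, scenario, dataset) cell."""

    scenario: str
    response: float
    expected_gain: pd.Series  # per trait, trait units
    rho_hi: float
    sigma_i: float
    sigma_h: float
    intensity: float
    scores: pd.Series | None = None  # per-genotype index values, if computed

    def __post_init__(self) -> None:
        if self.sigma_i < 0 or self.sigma_h < 0:
            raise ValueError("standard deviations must be non-negative")
        if abs(self.rho_hi) > 1 + 1e-9:
            raise ValueError("|rho_HI| must be <= 1")


def net_merit_variance(C, w) -> float:
    """Variance of the net genetic merit, sigma2_H = w'Cw."""
    C = np.asarray(C, float)
    w = _as_weights(w)
    if C.shape != (w.size, w.size):
        raise ValueError("dimension mismatch between C and w")
    return float(w @ C @ w)


def _solve_spd(P: np.ndarray, B: np.ndarray, allow_pinv: bool = False) -> np.ndarray:
    """Solve P X = B for symmetric positive definite P via Cholesky."""
    try:
        cho = scipy.linalg.cho_factor(P)
        return scipy.linalg.cho_solve(cho, B)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare path
        raise_err = exc
    except scipy.linalg.LinAlgError as exc:
        raise_err = exc
    if allow_pinv:
        logger.warning("P not positive definite; falling back to pseudo-inverse")
        return np.linalg.pinv(P) @ B
    raise np.linalg.LinAlgError(
        "P is not positive definite; condition it (ensure_psd) or pass "
        "allow_pinv=True"
    ) from raise_err


def lpsi_coefficients(P, C, w, allow_pinv: bool = False) -> np.ndarray:
    """Smith coefficients b solving P b = C w (maximize rho_HI)."""
    P = np.asarray(P, float)
    C = np.asarray(C, float)
    w = _as_weights(w)
    t = w.size
    if P.shape != (t, t) or C.shape != (t, t):
        raise ValueError("P, C and w have inconsistent dimensions")
    return _solve_spd(P, C @ w, allow_pinv=allow_pinv)


def mallard_D(d) -> np.ndarray:
    """Contrast matrix D' of predetermined proportional gains, (r-1) x r.

    Row q carries d_r in column q and -d_q in the last column, so that
    D'd = 0: selecting in the null space of D' forces the restricted gains
    into the ratios of d.  For r = 1 there is no ratio to enforce and the
    matrix is empty.
    """
    d = np.asarray(d, float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("d must be a nonempty vector")
    if not np.all(np.isfinite(d)) or np.all(d == 0):
        raise ValueError("d must be finite and nonzero")
    r = d.size
    if r == 1:
        return np.zeros((0, 1))
    D_t = np.zeros((r - 1, r))
    for q in range(r - 1):
        D_t[q, q] = d[r - 1]
        D_t[q, r - 1] = -d[q]
    return D_t


def restricted_coefficients(P, C, w,
                            restriction: RestrictionSpec | None = None,
                            trait_names=None,
                            allow_pinv: bool = False) -> IndexModel:
    """Constrained index coefficients b = K beta (null-restricted or Mallard).

    With no restriction the result is exactly the Smith LPSI (b = beta).
    Null mode zeroes the expected gain of each restricted trait (U'Cb = 0);
    proportional mode constrains the restricted gains to the ratios in d.
    """
    P = np.asarray(P, float)
    C = np.asarray(C, float)
    w = _as_weights(w)
    t = w.size
    if trait_names is None:
        trait_names = tuple(f"trait_{j + 1}" for j in range(t))
    trait_names = tuple(trait_names)
    beta = lpsi_coefficients(P, C, w, allow_pinv=allow_pinv)

    if restriction is None or restriction.n_restricted == 0:
        scenario = "LPSI"
        return IndexModel(scenario=scenario, b=beta, trait_names=trait_names,
                          C=C, P=P, w=w, restriction=restriction)

    U_t = restriction.u_transpose(trait_names)
    psi_t = U_t @ C  # r x t
    if restriction.mode == "null":
        M_t = psi_t
    else:
        M_t = mallard_D(restriction.d) @ psi_t
        if M_t.shape[0] == 0:
            # single proportional constraint fixes no direction: b = beta
            return IndexModel(scenario=restriction.label, b=beta,
                              trait_names=trait_names, C=C, P=P, w=w,
                              restriction=restriction)
    if np.linalg.matrix_rank(M_t) < M_t.shape[0]:
        raise ValueError("redundant restrictions: M is rank deficient")

    M = M_t.T  # t x m
    PinvM = _solve_spd(P, M, allow_pinv=allow_pinv)
    gram = M_t @ PinvM  # M' P^-1 M
    Q = PinvM @ np.linalg.solve(gram, M_t)
    K = np.eye(t) - Q
    b = K @ beta
    return IndexModel(scenario=restriction.label, b=b, trait_names=trait_names,
                      C=C, P=P, w=w, restriction=restriction)


def index_values(model: IndexModel, blues) -> pd.Series:
    """Per-genotype index scores I_i = b'y_i.

    ``blues`` is a BlueTable or a genotype-indexed DataFrame whose columns
    include the model's traits.
    """
    frame = blues.values if hasattr(blues, "dataset_label") else blues
    missing = [t for t in model.trait_names if t not in frame.columns]
    if missing:
        raise ValueError(f"BLUE table lacks trait columns {missing}")
    Y = frame[list(model.trait_names)].to_numpy()
    return pd.Series(Y @ model.b, index=frame.index, name="index")


def selection_intensity(p: float, n: int | None = None) -> float:
    """Standardized selection intensity for truncation at fraction p.

    Infinite-population value k = phi(z)/p with z the upper-p normal
    quantile.  When the finite number of candidates ``n`` is given, returns
    the expected mean of the top round(p*n) of n standard normal order
    statistics (Blom approximation), which is slightly smaller.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("selection fraction p must be in (0, 1)")
    if n is None:
        z = stats.norm.ppf(1.0 - p)
        return float(stats.norm.pdf(z) / p)
    if n < 1:
        raise ValueError("n must be positive")
    m = int(np.floor(p * n + 0.5))
    m = max(m, 1)
    ranks = np.arange(n - m + 1, n + 1)  # top m ranks
    expected = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return float(expected.mean())


def evaluate_index(model: IndexModel, k: float,
                   blues=None) -> IndexEvaluation:
    """Selection parameters R, E, rho_HI, sigma_I, sigma_H of a fitted index.

    R = k sigma_H rho_HI and E = k C b / sigma_I; for the unrestricted LPSI
    w'Cb = b'Pb so R reduces to k sigma_I.  If ``blues`` is given the
    per-genotype scores are attached.
    """
    b, C, P, w = model.b, model.C, model.P, model.w
    var_i = float(b @ P @ b)
    var_h = net_merit_variance(C, w)
    if var_i <= 0:
        raise ValueError("zero-variance index: b'Pb must be positive")
    if var_h <= 0:
        raise ValueError("zero-variance merit: w'Cw must be positive")
    sigma_i = float(np.sqrt(var_i))
    sigma_h = float(np.sqrt(var_h))
    rho = float(w @ C @ b) / (sigma_h * sigma_i)
    rho = float(np.clip(rho, -1.0, 1.0))
    gains = k * (C @ b) / sigma_i
    scores = index_values(model, blues) if blues is not None else None
    return IndexEvaluation(
        scenario=model.scenario,
        response=float(k * sigma_h * rho),
        expected_gain=pd.Series(gains, index=list(model.trait_names),
                                name="expected_gain"),
        rho_hi=rho,
        sigma_i=sigma_i,
        sigma_h=sigma_h,
        intensity=float(k),
        scores=scores,
    )
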