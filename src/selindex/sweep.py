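"""Economic-weight grid enumeration, evaluation, ANOVA comparison, shortlist.

The breeding question behind the sweep: economic weights w are fixed inputs
to the index, but their choice changes the selection parameters (per-trait
expected gains E, response R, correlation rho_HI) and the set of genotypes
selected.  The sweep evaluates every weight combination of a Cartesian grid
under each selection scenario, compares weight levels trait by trait with
one-way ANOVA, and shortlists the weights that jointly satisfy gain /
response / correlation criteria.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .indices import (
    RestrictionSpec,
    evaluate_index,
    restricted_coefficients,
)

__all__ = [
    "WeightGrid",
    "SelectionCriteria",
    "default_grid",
    "BEST_WHEAT_WEIGHTS",
    "evaluate_grid",
    "compare_weight_levels",
    "select_best_weights",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightGrid:
    """Ordered per-trait weight levels; combinations are their Cartesian product."""

    levels: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        clean = {}
        for trait, lv in self.levels.items():
            lv = tuple(float(v) for v in lv)
            if len(set(lv)) != len(lv):
                raise ValueError(f"duplicate weight levels for {trait!r}")
            if not lv:
                raise ValueError(f"empty level list for {trait!r}")
            clean[trait] = lv
        object.__setattr__(self, "levels", clean)

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(self.levels)

    def __len__(self) -> int:
        n = 1
        for lv in self.levels.values():
            n *= len(lv)
        return n

    def combinations(self) -> list[tuple[float, ...]]:
        return list(itertools.product(*self.levels.values()))

    def filtered(self, **subset) -> "WeightGrid":
        """Restrict some traits to subsets of their levels (order preserved)."""
        levels = dict(self.levels)
        for trait, keep in subset.items():
            keep = set(float(v) for v in np.atleast_1d(keep))
            levels[trait] = tuple(v for v in levels[trait] if v in keep)
        return WeightGrid(levels=levels)


def default_grid() -> WeightGrid:
    """The 2304-combination wheat grid.

    Maturity and height weights are negative (early, short plants wanted):
    {-1, -5, -10, -15} each.  Grain yield runs 1 then 10..150 by 10
    (16 levels), GPC 1 then 10..80 by 10 (9 levels): 4*4*16*9 = 2304.
    """
    return WeightGrid(levels={
        "maturity": (-1.0, -5.0, -10.0, -15.0),
        "height": (-1.0, -5.0, -10.0, -15.0),
        "yield": tuple([1.0] + [float(v) for v in range(10, 151, 10)]),
        "gpc": tuple([1.0] + [float(v) for v in range(10, 81, 10)]),
    })


#: the five shortlisted wheat weight vectors (maturity, height, yield, gpc)
BEST_WHEAT_WEIGHTS: tuple[tuple[float, ...], ...] = (
    (-1.0, -1.0, 120.0, 70.0),
    (-1.0, -1.0, 130.0, 70.0),
    (-1.0, -1.0, 150.0, 70.0),
    (-5.0, -1.0, 130.0, 70.0),
    (-5.0, -1.0, 150.0, 70.0),
)


def _scenario_list(scenarios) -> list[RestrictionSpec]:
    out = []
    for s in scenarios:
        if s is None or (isinstance(s, str) and s.upper() == "LPSI"):
            out.append(RestrictionSpec())
        elif isinstance(s, RestrictionSpec):
            out.append(s)
        else:
            raise ValueError(f"unrecognized scenario {s!r}")
    return out


def evaluate_grid(grid: WeightGrid, C, P, scenarios, k: float,
                  trait_names=None) -> pd.DataFrame:
    """One row of selection parameters per (weight combination, scenario).

    Columns: ``w_<trait>`` for each grid trait, ``scenario``, ``E_<trait>``,
    ``response``, ``rho``, ``ok``.  A cell whose index computation fails is
    kept with NaN parameters and ``ok=False`` so the sweep never aborts.
    """
    if len(grid) == 0:
        raise ValueError("empty weight grid")
    C = np.asarray(C, float)
    P = np.asarray(P, float)
    if trait_names is None:
        trait_names = grid.trait_names
    trait_names = tuple(trait_names)
    if C.shape != (len(trait_names),) * 2:
        raise ValueError("C dimension does not match trait count")
    scen = _scenario_list(scenarios)

    rows = []
    for combo in grid.combinations():
        w = np.asarray(combo, float)
        for restriction in scen:
            row = {f"w_{t}": v for t, v in zip(grid.trait_names, combo)}
            row["scenario"] = restriction.label
            try:
                model = restricted_coefficients(P, C, w, restriction,
                                                trait_names=trait_names)
                ev = evaluate_index(model, k)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("sweep cell failed for w=%s scenario=%s: %s",
                               combo, restriction.label, exc)
                for t in trait_names:
                    row[f"E_{t}"] = np.nan
                row.update(response=np.nan, rho=np.nan, ok=False)
                rows.append(row)
                continue
            for t in trait_names:
                row[f"E_{t}"] = float(ev.expected_gain[t])
            row.update(response=ev.response, rho=ev.rho_hi, ok=True)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class WeightAnova:
    """One-way ANOVA of a sweep response over one trait's weight levels."""

    factor: str
    response: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    level_means: pd.Series
    tukey: object | None = None

    def __str__(self) -> str:  # compact text report
        lines = [
            f"one-way ANOVA of {self.response} over levels of {self.factor}",
            f"F({self.df_between}, {self.df_within}) = {self.f_statistic:.4g}, "
            f"p = {self.p_value:.3g}",
            "level means:",
        ]
        lines += [f"  {lvl:>8}: {m:.4f}" for lvl, m in self.level_means.items()]
        return "\n".join(lines)


def compare_weight_levels(rows: pd.DataFrame, response: str, factor: str,
                          tukey: bool = False) -> WeightAnova:
    """Compare the levels of one trait's weight by one-way ANOVA.

    ``factor`` is a ``w_<trait>`` column, ``response`` any numeric sweep
    column (an ``E_<trait>``, ``response`` or ``rho``).  With all-identical
    responses across levels F is 0; with zero within-level variance F is
    reported as NaN (undefined).
    """
    for col in (response, factor):
        if col not in rows.columns:
            raise ValueError(f"column {col!r} not in sweep table")
    df = rows[[factor, response]].dropna()
    groups = [g[response].to_numpy() for _, g in df.groupby(factor, sort=True)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 levels with >= 2 rows each")
    level_means = df.groupby(factor, sort=True)[response].mean()
    n = len(df)
    k_lvl = len(groups)
    grand = df[response].mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k_lvl - 1, n - k_lvl
    if ss_within == 0.0:
        f_stat = 0.0 if ss_between == 0.0 else np.nan
        p = 1.0 if ss_between == 0.0 else np.nan
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    tukey_res = None
    if tukey:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tukey_res = pairwise_tukeyhsd(df[response], df[factor].astype(str))
    return WeightAnova(factor=factor, response=response,
                       f_statistic=float(f_stat), df_between=df_b,
                       df_within=df_w, p_value=float(p),
                       level_means=level_means, tukey=tukey_res)


@dataclass(frozen=True)
class SelectionCriteria:
    """Joint thresholds a sweep row must satisfy to be shortlisted.

    ``max_gain`` bounds undesired increases (e.g. maturity, height) from
    above; ``min_gain`` bounds desired gains (yield, GPC) from below;
    response and correlation have lower bounds.
    """

    max_gain: dict[str, float] = field(default_factory=dict)
    min_gain: dict[str, float] = field(default_factory=dict)
    min_response: float = -np.inf
    min_correlation: float = -np.inf

    def mask(self, rows: pd.DataFrame) -> pd.Series:
        ok = rows.get("ok", pd.Series(True, index=rows.index)).astype(bool)
        for trait, bound in self.max_gain.items():
            ok &= rows[f"E_{trait}"] <= bound
        for trait, bound in self.min_gain.items():
            ok &= rows[f"E_{trait}"] >= bound
        ok &= rows["response"] >= self.min_response
        ok &= rows["rho"] >= self.min_correlation
        return ok


def select_best_weights(rows: pd.DataFrame, criteria: SelectionCriteria,
                        top_n: int = 5, rank_trait: str = "yield") -> pd.DataFrame:
    """Filter sweep rows by ``criteria`` and rank the survivors.

    Ranking: target-trait expected gain descending, ties broken by rho_HI,
    then response (both descending), then lexicographic weight order, so the
    result is invariant to input row order.  Returns up to ``top_n`` rows.
    """
    if rows.empty:
        raise ValueError("empty sweep table")
    kept = rows[criteria.mask(rows)]
    if kept.empty:
        logger.warning("no sweep row satisfies the selection criteria")
        return kept
    weight_cols = sorted(c for c in rows.columns if c.startswith("w_"))
    ordered = kept.sort_values(
        by=[f"E_{rank_trait}", "rho", "response"] + weight_cols,
        ascending=[False, False, False] + [True] * len(weight_cols),
        kind="mergesort",
    )
    return ordered.head(top_n).reset_index(drop=True)
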