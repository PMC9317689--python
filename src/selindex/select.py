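"""Truncation selection of genotypes and cross-scenario consistency analysis.

Selection keeps the top fraction p of genotypes ranked on an index (or a
single trait); realized differentials compare the selected group's mean with
the population, either on phenotypic BLUEs or — for simulated data with a
truth table — on true genotypic values, giving the realized genetic gain to
set against the theoretical E.  Consistency analysis asks which genotypes
keep being selected across economic weights and selection scenarios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionSet",
    "ConsistencyReport",
    "round_half_up",
    "select_top_fraction",
    "single_trait_selection",
    "realized_differential",
    "overlap",
    "consistency_analysis",
]

logger = logging.getLogger(__name__)


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (19.6 -> 20, 2.5 -> 3)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SelectionSet:
    """Genotypes kept by one truncation selection, with its context."""

    genotypes: frozenset
    fraction: float
    dataset: str = ""
    scenario: str = ""
    weights: tuple[float, ...] = ()
    expanded: bool = False  # ties at the cut enlarged the set beyond round(p*n)

    def __len__(self) -> int:
        return len(self.genotypes)


def select_top_fraction(scores: pd.Series, p: float, direction: str = "max",
                        dataset: str = "", scenario: str = "",
                        weights: tuple[float, ...] = ()) -> SelectionSet:
    """Keep the top fraction p of genotypes by score.

    The target size is round-half-up(p*n); genotypes tied exactly with the
    cutoff score are all included (the set may exceed the target, logged).
    ``direction='min'`` selects the lowest scorers instead.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("selection fraction p must be in (0, 1)")
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    scores = scores.dropna()
    n = len(scores)
    if n == 0:
        raise ValueError("no finite scores to select from")
    m = round_half_up(p * n)
    if m < 1:
        logger.warning("p*n < 1; selecting a single genotype")
        m = 1
    ranked = scores.sort_values(ascending=(direction == "min"), kind="mergesort")
    cutoff = ranked.iloc[m - 1]
    if direction == "max":
        chosen = scores.index[scores >= cutoff]
    else:
        chosen = scores.index[scores <= cutoff]
    expanded = len(chosen) > m
    if expanded:
        logger.warning("tie at the truncation point: set expanded from %d to %d",
                       m, len(chosen))
    return SelectionSet(genotypes=frozenset(chosen), fraction=p, dataset=dataset,
                        scenario=scenario, weights=tuple(weights),
                        expanded=expanded)


def single_trait_selection(blues, trait: str, p: float,
                           direction: str = "max", dataset: str = "") -> SelectionSet:
    """Truncation selection on a single trait's BLUEs (baseline method)."""
    frame = blues.values if hasattr(blues, "dataset_label") else blues
    if trait not in frame.columns:
        raise ValueError(f"trait {trait!r} not in BLUE table")
    label = dataset or getattr(blues, "dataset_label", "")
    return select_top_fraction(frame[trait], p, direction=direction,
                               dataset=label, scenario=f"single:{trait}")


def realized_differential(selected: SelectionSet, table) -> pd.Series:
    """Mean(selected) - mean(population) per trait.

    On BLUEs this is the phenotypic selection differential; on a simulation
    truth table it is the realized genetic gain.  Rejects empty or full
    selections (no contrast to measure).
    """
    frame = table.values if hasattr(table, "dataset_label") else table
    ids = [g for g in frame.index if g in selected.genotypes]
    if not ids or len(ids) == len(frame):
        raise ValueError("selection must be a nonempty strict subset")
    return frame.loc[ids].mean() - frame.mean()


def overlap(a: SelectionSet, b: SelectionSet) -> int:
    """Number of genotypes common to two selections (symmetric)."""
    return len(a.genotypes & b.genotypes)


@dataclass
class ConsistencyReport:
    """Which genotypes persist across (scenario, weight, dataset) contexts."""

    membership: pd.DataFrame  # genotype x context (0/1)
    counts: pd.Series  # contexts per genotype
    consensus: frozenset
    union: frozenset
    min_weights: int
    min_scenarios: int


def consistency_analysis(sets: list[SelectionSet], min_weights: int,
                         min_scenarios: int) -> ConsistencyReport:
    """Consensus genotypes across economic weights and selection scenarios.

    A genotype is in the consensus when there are at least ``min_scenarios``
    scenarios in which it was selected under at least ``min_weights``
    distinct weight vectors (selection in any dataset counts).  Tightening
    either threshold can only shrink the consensus.
    """
    if not sets:
        raise ValueError("no selection sets given")
    universe = sorted(set().union(*(s.genotypes for s in sets)))
    contexts = []
    for s in sets:
        label = f"{s.dataset}|{s.scenario}|{','.join(f'{v:g}' for v in s.weights)}"
        contexts.append(label)
    if len(set(contexts)) != len(contexts):
        # identical contexts are merged by OR below
        logger.info("duplicate contexts merged in consistency analysis")
    membership = pd.DataFrame(0, index=pd.Index(universe, name="genotype"),
                              columns=pd.Index([], dtype=object))
    for s, label in zip(sets, contexts):
        col = membership.get(label, pd.Series(0, index=membership.index))
        col = col.copy()
        col.loc[list(s.genotypes)] = 1
        membership[label] = col

    counts = membership.sum(axis=1)

    # per (scenario, genotype): number of distinct weight vectors selecting it
    per_scenario: dict[str, dict] = {}
    for s in sets:
        d = per_scenario.setdefault(s.scenario, {})
        for g in s.genotypes:
            d.setdefault(g, set()).add(s.weights)
    consensus = frozenset(
        g for g in universe
        if sum(
            1 for d in per_scenario.values()
            if len(d.get(g, ())) >= min_weights
        ) >= min_scenarios
    )
    return ConsistencyReport(membership=membership, counts=counts,
                             consensus=consensus,
                             union=frozenset(universe),
                             min_weights=min_weights,
                             min_scenarios=min_scenarios)
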