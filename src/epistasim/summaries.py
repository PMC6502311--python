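"""Summary statistics over replicate divergence trajectories.

A trajectory table is a tidy frame with one row per replicate per
total substitution count ``n`` (including the ancestral ``n = 0``
row), holding ``replicate``, ``n``, ``n_A``, ``n_B``, ``w_H`` and the
mean epistatic coefficients among fixed pairs (``eps_within_A``,
``eps_within_B``, ``eps_between``).  All statistics here are plain
functions of that frame or of final population states, so they apply
equally to freshly simulated results and to tables reloaded from
disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

from epistasim.fitness import DominanceParams, effective_selection
from epistasim.network import EpistasisNetwork
from epistasim.simulate import PopulationState

__all__ = [
    "epistasis_components",
    "heterosis_frequency",
    "per_substitution_decline",
    "large_effect_fraction",
    "introgression_fraction",
    "band",
    "EpistasisComponents",
    "DeclineRates",
]


@dataclass(frozen=True)
class EpistasisComponents:
    """Mean epistasis among fixed pairs; NaN where no pair exists."""

    within_A: float
    within_B: float
    between: float


def epistasis_components(
    network: EpistasisNetwork,
    state_A: PopulationState | Iterable[str],
    state_B: PopulationState | Iterable[str],
) -> EpistasisComponents:
    """Mean epistatic coefficient over fixed pairs.

    Within-population means run over all unordered pairs of loci fixed
    in the same population, between-population means over all pairs
    with one locus from each; unstored pairs contribute coefficient 0.
    A component with no pairs is NaN.
    """
    A = list(state_A.fixed if isinstance(state_A, PopulationState) else state_A)
    B = list(state_B.fixed if isinstance(state_B, PopulationState) else state_B)

    def _within(loci: list[str]) -> float:
        if len(loci) < 2:
            return math.nan
        total = sum(network.epsilon_of(a, b) for a, b in combinations(loci, 2))
        return total / (len(loci) * (len(loci) - 1) / 2)

    if A and B:
        between = sum(network.epsilon_of(a, b) for a in A for b in B) / (
            len(A) * len(B)
        )
    else:
        between = math.nan
    return EpistasisComponents(
        within_A=_within(A), within_B=_within(B), between=between
    )


def heterosis_frequency(trajectories: pd.DataFrame, n_per_population: int) -> float:
    """Fraction of replicates with w_H strictly above 1 at equal depth.

    The queried state is ``n_A = n_B = n_per_population``; every
    replicate in the table must reach it.
    """
    at = trajectories[
        (trajectories["n_A"] == n_per_population)
        & (trajectories["n_B"] == n_per_population)
    ]
    reps = set(trajectories["replicate"].unique())
    missing = reps - set(at["replicate"].unique())
    if missing:
        raise ValueError(
            f"replicates never reach n_A = n_B = {n_per_population}: "
            f"{sorted(missing)[:10]}"
        )
    # a replicate can visit the queried depth only once
    return float((at["w_H"] > 1.0).mean())


@dataclass(frozen=True)
class DeclineRates:
    """Per-substitution proportional decline of relative hybrid fitness.

    ``geometric`` averages, over replicates, the compound rate
    ``1 - (w_final / w_0)^(1/n_final)``; ``arithmetic`` averages the
    per-step proportional changes ``-(w_next - w) / w`` directly.
    """

    geometric: float
    arithmetic: float


def per_substitution_decline(trajectories: pd.DataFrame) -> DeclineRates:
    """Mean proportional change of w_H per fixation (positive = decline)."""
    geo, arith = [], []
    for _, g in trajectories.groupby("replicate"):
        g = g.sort_values("n")
        w = g["w_H"].to_numpy()
        if len(w) < 2:
            raise ValueError("replicates need at least 2 trajectory rows")
        n_final = g["n"].iloc[-1] - g["n"].iloc[0]
        geo.append(1.0 - (w[-1] / w[0]) ** (1.0 / n_final))
        arith.append(float(np.mean(-(np.diff(w) / w[:-1]))))
    return DeclineRates(geometric=float(np.mean(geo)), arithmetic=float(np.mean(arith)))


def large_effect_fraction(
    trajectories: pd.DataFrame, threshold: float = 0.10
) -> float:
    """Fraction of replicates where any single fixation moves w_H by
    more than ``threshold`` proportionally."""
    hits = 0
    reps = 0
    for _, g in trajectories.groupby("replicate"):
        g = g.sort_values("n")
        w = g["w_H"].to_numpy()
        reps += 1
        rel = np.abs(np.diff(w)) / w[:-1]
        if np.any(rel > threshold):
            hits += 1
    if reps == 0:
        raise ValueError("empty trajectory table")
    return hits / reps


def introgression_fraction(
    network: EpistasisNetwork,
    state_A: PopulationState | Iterable[str],
    state_B: PopulationState | Iterable[str],
    dom: DominanceParams | None = None,
) -> tuple[float, float]:
    """Fraction of one population's substitutions positively selected in
    the other's background.

    Returns ``(A_in_B, B_in_A)``: for each locus fixed in A, the sign
    of its effective selection coefficient is evaluated against B's
    fixed set (and vice versa).  A positive fraction signals potential
    for adaptive introgression despite low hybrid fitness.
    """
    dom = dom or DominanceParams()
    A = list(state_A.fixed if isinstance(state_A, PopulationState) else state_A)
    B = list(state_B.fixed if isinstance(state_B, PopulationState) else state_B)
    if set(A) & set(B):
        raise ValueError("fixed sets must be disjoint")

    def _frac(sources: list[str], background: list[str]) -> float:
        if not sources:
            return math.nan
        positive = sum(
            1
            for locus in sources
            if effective_selection(network, locus, background, dom).sigma > 0
        )
        return positive / len(sources)

    return _frac(A, B), _frac(B, A)


def band(
    values: np.ndarray | pd.DataFrame,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-replicate percentile envelope.

    ``values`` has one row per replicate and one column per
    substitution count; returns the lower and upper percentile bounds
    (2.5th/97.5th at the default level) per column.  Requires at least
    20 replicates so the tails are represented at all.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < 20:
        raise ValueError(f"need >= 20 replicates, got {arr.shape[0]}")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    tail = 100.0 * (1.0 - level) / 2.0
    lower = np.percentile(arr, tail, axis=0)
    upper = np.percentile(arr, 100.0 - tail, axis=0)
    return lower, upper
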