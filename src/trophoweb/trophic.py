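"""Trophic-level estimation on the directed (unsymmetrized) web.

Basal nodes — producers, cyanobacteria, detritus, and any node without diet
links — sit at TL = 1.  A consumer's level is one plus the weighted mean of
its prey's levels; on a binary web every prey gets an equal diet share, so
the levels solve the linear system

    TL_i = 1 + (1/k_i) * sum_{j in prey(i)} TL_j

which is solved exactly (dense LU), handling omnivory loops among consumers
without iteration.  A flow-weighted variant (diet shares proportional to
prey biomass) is available but unused for binary analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import BASAL_CATEGORIES, FoodWeb, FoodWebError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrophicLevels:
    """Solved trophic levels plus the basal set fixed at TL = 1."""

    levels: Mapping[str, float]
    basal: frozenset[str]

    def __getitem__(self, name: str) -> float:
        return self.levels[name]

    def as_series(self, ndigits: int = 2) -> pd.Series:
        return pd.Series({n: round(v, ndigits) for n, v in sorted(self.levels.items())},
                         name="TL")


def identify_basal(web: FoodWeb) -> frozenset[str]:
    """Nodes fixed at TL = 1.

    Basal-category nodes (producer, cyanobacteria, detritus) are basal even
    when they receive donor links (e.g. inputs into detritus); those links
    are excluded from the TL system.  An animal with no prey is a dangling
    consumer: warned about, and treated as basal so the system stays
    solvable.
    """
    if not web.directed:
        raise FoodWebError("basal identification requires the directed web")
    basal = set()
    for n in web.nodes:
        if web.category(n) in BASAL_CATEGORIES:
            basal.add(n)
        elif web.graph.in_degree(n) == 0:
            logger.warning("WARN: animal node %r has no prey; treated as basal", n)
            basal.add(n)
    return frozenset(basal)


def trophic_levels(web: FoodWeb, weighted_by_biomass: bool = False) -> TrophicLevels:
    """Solve the diet-weighted linear system for all nodes.

    With ``weighted_by_biomass`` the diet shares of a consumer are
    proportional to prey biomasses instead of uniform.  Cannibalistic
    self-loops are excluded from diet shares.  Raises on a diet cycle with
    no basal input (singular system), naming the nodes involved.
    """
    if not web.directed:
        raise FoodWebError("trophic levels are computed on the directed web")
    names = web.nodes
    index = {n: i for i, n in enumerate(names)}
    basal = identify_basal(web)

    n = len(names)
    a = np.zeros((n, n))
    b = np.ones(n)
    for node in names:
        i = index[node]
        a[i, i] = 1.0
        if node in basal:
            continue  # fixed TL = 1
        prey = [p for p in web.prey_of(node) if p != node]
        if weighted_by_biomass:
            masses = np.array([web.biomass(p) or 0.0 for p in prey], dtype=float)
            if masses.sum() <= 0:
                raise FoodWebError(f"consumer {node!r}: no positive prey biomass for weighting")
            shares = masses / masses.sum()
        else:
            shares = np.full(len(prey), 1.0 / len(prey))
        for p, s in zip(prey, shares):
            a[i, index[p]] -= s

    try:
        x = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        cycle = _find_unsupported_cycle(web, basal)
        raise FoodWebError(
            f"trophic-level system is singular; diet cycle without basal input: {cycle}"
        ) from exc

    residual = np.max(np.abs(a @ x - b))
    if residual > 1e-10:
        raise FoodWebError(f"trophic-level solve residual too large: {residual:.2e}")
    return TrophicLevels(dict(zip(names, x.tolist())), basal)


def _find_unsupported_cycle(web: FoodWeb, basal: frozenset[str]) -> list[str]:
    """Consumers that cannot reach a basal node backwards through diet links."""
    import networkx as nx

    reachable = set(basal)
    frontier = list(basal)
    while frontier:
        node = frontier.pop()
        for succ in web.graph.successors(node):
            if succ not in reachable:
                reachable.add(succ)
                frontier.append(succ)
    return sorted(set(web.nodes) - reachable) or sorted(
        n for n in web.nodes if n not in basal and nx.has_path(web.graph, n, n)
    )


def trophic_levels_fixed_point(
    web: FoodWeb, tol: float = 1e-10, max_iter: int = 100_000
) -> TrophicLevels:
    """Fixed-point iteration TL <- 1 + Q.TL; converges to the linear solve.

    Exposed mainly as an internal cross-check for webs with omnivory loops.
    """
    names = web.nodes
    basal = identify_basal(web)
    levels = {n: 1.0 for n in names}
    for _ in range(max_iter):
        delta = 0.0
        new = {}
        for node in names:
            if node in basal:
                new[node] = 1.0
                continue
            prey = [p for p in web.prey_of(node) if p != node]
            value = 1.0 + sum(levels[p] for p in prey) / len(prey)
            delta = max(delta, abs(value - levels[node]))
            new[node] = value
        levels = new
        if delta < tol:
            break
    else:
        raise FoodWebError("fixed-point trophic-level iteration did not converge")
    return TrophicLevels(levels, basal)


def compare_to_reference(
    levels: TrophicLevels,
    reference: Mapping[str, tuple[float, float]],
    default_tolerance: float = 0.3,
) -> pd.DataFrame:
    """Flag computed levels against literature values with tolerances.

    ``reference`` maps node name to ``(TL, tolerance)``; a missing/None
    tolerance falls back to ``default_tolerance`` (the +/- 0.3 S.E. band
    conventional for literature trophic levels).
    """
    rows = []
    for node, entry in sorted(reference.items()):
        ref_tl, tol = entry
        if tol is None:
            tol = default_tolerance
        computed = levels.levels.get(node)
        within = computed is not None and abs(computed - ref_tl) <= tol
        rows.append(
            {
                "node": node,
                "computed_TL": None if computed is None else round(computed, 2),
                "reference_TL": ref_tl,
                "tolerance": tol,
                "within_range": bool(within),
            }
        )
    return pd.DataFrame(rows)
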