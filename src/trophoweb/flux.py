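"""Steady-state energy fluxes on the directed aggregated web.

The model balances each consumer's energy budget at steady state: the
efficiency-weighted inflow from its prey covers its metabolic loss plus its
outflow to predators.  Per-prey assimilation efficiencies ``e_i`` depend on
the prey's category (animal 0.906, producer/cyanobacteria 0.545, detritus
0.158); feeding preferences ``W[i,j]`` are scaled by prey biomass; metabolic
loss is the allometric per-gram rate ``x = a * M^b`` times total biomass.
Basal nodes (producers, cyanobacteria, detritus) act as unlimited sources:
placeholder biomass 1 and metabolic rate 0.

Writing ``G_j`` for the total consumption of consumer ``j``, the balance

    G_j * sum_i W[i,j] e_i  =  X_j + sum_k W[j,k] G_k

is linear in the ``G`` vector and solved exactly; individual fluxes are
``F[i,j] = W[i,j] * G_j``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import BASAL_CATEGORIES, FoodWeb, FoodWebError
from .trophic import TrophicLevels, identify_basal

logger = logging.getLogger(__name__)

#: Literature assimilation efficiencies by prey category.
DEFAULT_EFFICIENCIES: dict[str, float] = {
    "animal": 0.906,
    "producer": 0.545,
    "cyanobacteria": 0.545,
    "detritus": 0.158,
}


@dataclass(frozen=True)
class FluxParameters:
    """Configuration of the flux-balance solve.

    ``allometric_a`` and ``allometric_b`` give the per-gram metabolic rate
    x = a * M^b (M the mean body mass in grams); the defaults are the
    metabolic-theory values commonly used with this class of models.
    Preferences are biomass-scaled and efficiencies are applied per prey.
    """

    efficiencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFICIENCIES)
    )
    allometric_a: float = 0.71
    allometric_b: float = -0.25
    basal_biomass_placeholder: float = 1.0
    basal_metabolic_rate: float = 0.0

    def __post_init__(self) -> None:
        for cat, e in self.efficiencies.items():
            if not 0 < e <= 1:
                raise FoodWebError(f"efficiency for {cat!r} must be in (0, 1], got {e}")

    def efficiency_of(self, category: str) -> float:
        try:
            return self.efficiencies[category]
        except KeyError:
            raise FoodWebError(f"no assimilation efficiency for category {category!r}")


@dataclass(frozen=True)
class FluxMatrix:
    """Nonnegative prey x consumer flux matrix (kJ/m^2/day by convention).

    ``matrix`` rows are prey, columns consumers, nodes alphabetical;
    ``F[i,j] > 0`` only where the edge i -> j exists.
    """

    matrix: pd.DataFrame

    @property
    def nodes(self) -> list[str]:
        return list(self.matrix.index)

    def flux(self, prey: str, predator: str) -> float:
        return float(self.matrix.loc[prey, predator])

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"prey": i, "predator": j, "flux": float(self.matrix.loc[i, j])}
            for i in self.matrix.index
            for j in self.matrix.columns
            if self.matrix.loc[i, j] > 0
        ]
        return pd.DataFrame(rows, columns=["prey", "predator", "flux"])


def prepare_flux_web(
    web: FoodWeb, params: FluxParameters | None = None
) -> tuple[FoodWeb, dict[str, float]]:
    """Restrict the web to nodes with flux data and resolve biomasses.

    Non-basal nodes missing biomass or body mass cannot enter the budget
    and are excluded with a logged warning; basal nodes always stay, with
    the placeholder biomass.  Returns the restricted web and the biomass
    map used for preference weighting.
    """
    params = params or FluxParameters()
    basal = identify_basal(web)
    keep, dropped = [], []
    for n in web.nodes:
        attrs = web.attributes(n)
        if n in basal or (attrs.biomass is not None and attrs.body_mass is not None):
            keep.append(n)
        else:
            dropped.append(n)
    if dropped:
        logger.warning("WARN: nodes without biomass/body-mass data omitted from fluxes: %s",
                       dropped)
    sub = web.subweb(keep, label=f"{web.label} (flux)" if web.label else "flux")
    biomass = {
        n: params.basal_biomass_placeholder if n in basal else float(web.attributes(n).biomass)
        for n in keep
    }
    return sub, biomass


def metabolic_losses(
    web: FoodWeb, params: FluxParameters | None = None
) -> dict[str, float]:
    """Whole-node metabolic loss X_j = a * M_j^b * B_j; 0 for basal nodes."""
    params = params or FluxParameters()
    basal = identify_basal(web)
    losses = {}
    for n in web.nodes:
        if n in basal:
            losses[n] = params.basal_metabolic_rate
            continue
        attrs = web.attributes(n)
        if attrs.biomass is None or attrs.body_mass is None:
            raise FoodWebError(
                f"non-basal node {n!r} lacks biomass/body mass; "
                "run prepare_flux_web first"
            )
        losses[n] = params.allometric_a * attrs.body_mass ** params.allometric_b * attrs.biomass
    return losses


def preference_matrix(web: FoodWeb, biomass: Mapping[str, float]) -> pd.DataFrame:
    """Biomass-scaled feeding preferences W[i,j] = B_i / sum_{k in prey(j)} B_k.

    Columns (consumers with at least one prey) sum to 1 over their prey.
    """
    names = web.nodes
    w = pd.DataFrame(0.0, index=names, columns=names)
    for consumer in names:
        prey = [p for p in web.prey_of(consumer) if p != consumer]
        if not prey:
            continue
        total = sum(biomass[p] for p in prey)
        if total <= 0:
            raise FoodWebError(f"consumer {consumer!r}: prey biomasses sum to zero")
        for p in prey:
            w.loc[p, consumer] = biomass[p] / total
    return w


def solve_fluxes(
    web: FoodWeb,
    preferences: pd.DataFrame,
    losses: Mapping[str, float],
    params: FluxParameters | None = None,
) -> FluxMatrix:
    """Exact linear solve of the per-prey-efficiency flux balance.

    Raises on a solved flux below -1e-9 (infeasible parameterization);
    roundoff negatives in (-1e-9, 0) are clipped to zero.
    """
    params = params or FluxParameters()
    names = web.nodes
    basal = identify_basal(web)
    consumers = [n for n in names if n not in basal]
    idx = {n: i for i, n in enumerate(consumers)}

    eff = {n: params.efficiency_of(web.category(n)) for n in names}
    m = len(consumers)
    a = np.zeros((m, m))
    b = np.zeros(m)
    for j in consumers:
        jj = idx[j]
        gain = sum(preferences.loc[i, j] * eff[i] for i in web.prey_of(j) if i != j)
        if gain <= 0:
            raise FoodWebError(f"consumer {j!r} has no assimilable inflow")
        a[jj, jj] += gain
        b[jj] = losses[j]
        for k in web.predators_of(j):
            if k in idx:
                a[jj, idx[k]] -= preferences.loc[j, k]

    g = np.linalg.solve(a, b) if m else np.zeros(0)

    matrix = pd.DataFrame(0.0, index=names, columns=names)
    for j in consumers:
        total = g[idx[j]]
        if total < -1e-9:
            raise FoodWebError(
                f"infeasible flux parameterization: consumption of {j!r} solved to {total:.3e}"
            )
        total = max(total, 0.0)
        for i in web.prey_of(j):
            if i == j:
                continue
            value = preferences.loc[i, j] * total
            matrix.loc[i, j] = max(value, 0.0)
    return FluxMatrix(matrix)


def compute_fluxes(
    web: FoodWeb, params: FluxParameters | None = None
) -> tuple[FluxMatrix, FoodWeb]:
    """Convenience pipeline: restrict, weight, lose, solve.

    Returns the flux matrix and the restricted web it was solved on.
    """
    params = params or FluxParameters()
    sub, biomass = prepare_flux_web(web, params)
    w = preference_matrix(sub, biomass)
    x = metabolic_losses(sub, params)
    return solve_fluxes(sub, w, x, params), sub


def balance_residuals(
    fluxes: FluxMatrix, web: FoodWeb, losses: Mapping[str, float],
    params: FluxParameters | None = None,
) -> dict[str, float]:
    """Conservation residual e-inflow - X - outflow at every non-basal node."""
    params = params or FluxParameters()
    basal = identify_basal(web)
    eff = {n: params.efficiency_of(web.category(n)) for n in web.nodes}
    out = {}
    f = fluxes.matrix
    for j in web.nodes:
        if j in basal:
            continue
        inflow = sum(eff[i] * f.loc[i, j] for i in web.prey_of(j))
        outflow = sum(f.loc[j, k] for k in web.predators_of(j))
        out[j] = inflow - losses[j] - outflow
    return out


def flux_matrix_log10(
    fluxes: FluxMatrix, levels: TrophicLevels | None = None
) -> pd.DataFrame:
    """Entrywise log10 display matrix; structural zeros become NaN.

    With trophic levels supplied, rows and columns are arranged by
    ascending TL (ties alphabetical), the conventional layout for weighted
    interaction matrices.
    """
    m = fluxes.matrix
    if levels is not None:
        order = sorted(m.index, key=lambda n: (levels.levels.get(n, math.inf), n))
        m = m.loc[order, order]
    with np.errstate(divide="ignore"):
        out = np.log10(m.to_numpy())
    out[~np.isfinite(out)] = np.nan
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def flux_summaries(fluxes: FluxMatrix) -> dict[str, float]:
    """Counts and Shannon diversity of the positive fluxes.

    H = -sum p ln p over fluxes normalized to proportions; H = 0 for a
    single flux, ln k for k equal fluxes.
    """
    values = fluxes.matrix.to_numpy().ravel()
    positive = values[values > 0]
    if positive.size == 0:
        raise FoodWebError("flux summaries undefined for an all-zero matrix")
    total = positive.sum()
    p = positive / total
    return {
        "n_fluxes": int(positive.size),
        "total_flux": float(total),
        "shannon_diversity": float(-(p * np.log(p)).sum()),
    }
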