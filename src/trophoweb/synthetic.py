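"""Synthetic food webs with the structural properties the analysis assumes.

Topology comes from the niche model: each species gets a niche value drawn
uniformly on [0, 1] and each consumer eats every species whose niche value
falls in a contiguous diet interval.  Interval widths are beta-distributed
and calibrated so the expected number of directed links equals the target
connectance times N(N-1); the species with the smallest niche value eats
nothing, guaranteeing at least one basal node.  Attributes emulate the
shape of lagoon functional-group data: basal nodes carry the placeholder
biomass 1 and a basal category; consumers are animals with lognormal
biomass and body mass.

Everything is reproducible from a single integer seed: topology and
attributes are drawn from named substreams of one seed sequence, so a web
and its attributes never depend on call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .core import FoodWeb, FoodWebError, NodeAttributes, check_connected

_TOPOLOGY_STREAM = 1
_ATTRIBUTE_STREAM = 2
_PERTURB_STREAM = 3

DEFAULT_BASAL_CATEGORIES: dict[str, float] = {
    "producer": 0.4,
    "cyanobacteria": 0.3,
    "detritus": 0.3,
}


@dataclass(frozen=True)
class SyntheticWebSpec:
    """Parameters of the generator.

    Defaults emulate the scale of the study system's aggregated webs:
    23 nodes at undirected density ~0.22, lognormal biomasses spanning
    roughly four orders of magnitude (grams), body masses centred at 1 g.
    """

    n_nodes: int = 23
    connectance: float = 0.217
    seed: int = 0
    n_basal_min: int = 1
    biomass_logmean: float = 2.0
    biomass_logsd: float = 1.5
    bodymass_logmean: float = 0.0
    bodymass_logsd: float = 2.0
    basal_categories: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASAL_CATEGORIES)
    )
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.connectance < 1:
            raise FoodWebError(f"connectance must be in (0, 1), got {self.connectance}")
        if self.n_basal_min < 1:
            raise FoodWebError("n_basal_min must be >= 1")
        if self.biomass_logsd < 0 or self.bodymass_logsd < 0:
            raise FoodWebError("lognormal sd parameters must be >= 0")
        if self.n_nodes < 1:
            raise FoodWebError("n_nodes must be >= 1")
        total = sum(self.basal_categories.values())
        if not total > 0:
            raise FoodWebError("basal_categories weights must sum to > 0")


@dataclass(frozen=True)
class Perturbation:
    """Disturbance applied to a baseline web.

    ``basal_replacement`` and ``consumer_turnover`` are fractions in [0, 1]
    of basal nodes / consumers whose identity (and niche position) is
    re-drawn in the perturbed web, emulating a basal regime switch (e.g.
    macrophytes replaced by cyanobacteria-like producers) plus consumer
    turnover.
    """

    basal_replacement: float = 0.0
    consumer_turnover: float = 0.0
    replacement_basal_category: str = "cyanobacteria"

    def __post_init__(self) -> None:
        for label, value in (
            ("basal_replacement", self.basal_replacement),
            ("consumer_turnover", self.consumer_turnover),
        ):
            if not 0.0 <= value <= 1.0:
                raise FoodWebError(f"{label} must be in [0, 1], got {value}")


def _interval_mean(spec: SyntheticWebSpec) -> float:
    """Mean diet-interval width making E[directed links] = C * N * (N-1).

    With the minimum-niche species fixed basal, the remaining N-1 consumers
    have expected interval width m * E[niche value | not the minimum]; the
    sum of non-minimum niche values has expectation N/2 - 1/(N+1).
    """
    n, c = spec.n_nodes, spec.connectance
    if n < 2:
        return 0.0
    consumers_mass = n / 2.0 - 1.0 / (n + 1.0)
    m = c * n / consumers_mass
    if not m < 1.0:
        raise FoodWebError(
            f"connectance {c} infeasible for {n} nodes (needs mean interval {m:.3f} >= 1)"
        )
    return m


def _draw_topology(
    rng: np.random.Generator, spec: SyntheticWebSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw niche values, diet-interval centres and widths for one attempt."""
    n = spec.n_nodes
    values = rng.uniform(size=n)
    m = _interval_mean(spec)
    if m > 0:
        beta_b = 1.0 / m - 1.0
        widths = values * rng.beta(1.0, beta_b, size=n)
    else:
        widths = np.zeros(n)
    widths[np.argmin(values)] = 0.0  # smallest niche value eats nothing
    # centre kept so the diet interval lies inside [0, 1]
    low = widths / 2.0
    high = np.minimum(values, 1.0 - widths / 2.0)
    centres = low + (high - low) * rng.uniform(size=n)
    return values, centres, widths


def _edges_from_intervals(
    names: list[str], values: np.ndarray, centres: np.ndarray, widths: np.ndarray
) -> set[tuple[str, str]]:
    edges = set()
    n = len(names)
    for i in range(n):
        if widths[i] <= 0:
            continue
        lo, hi = centres[i] - widths[i] / 2.0, centres[i] + widths[i] / 2.0
        for j in range(n):
            if j != i and lo <= values[j] <= hi:
                edges.add((names[j], names[i]))  # prey -> predator
    return edges


def _basal_names(names: list[str], edges: set[tuple[str, str]]) -> set[str]:
    eaten_by = {pred for _, pred in edges}
    return {n for n in names if n not in eaten_by}


def _topology_failure(
    names: list[str], edges: set[tuple[str, str]], spec: SyntheticWebSpec
) -> str | None:
    """Reason the drawn topology is unusable, or None when it is valid.

    A valid web is connected, has enough basal nodes, and supports every
    consumer from a basal node through diet links (otherwise the
    trophic-level and flux linear systems are singular).
    """
    basal = _basal_names(names, edges)
    if len(basal) < spec.n_basal_min:
        return f"only {len(basal)} basal nodes (need {spec.n_basal_min})"
    web = FoodWeb([_placeholder_attrs(n) for n in names], edges, directed=True)
    ok, components = check_connected(web)
    if not ok:
        return f"{len(components)} components"
    reachable = set(basal)
    frontier = list(basal)
    while frontier:
        node = frontier.pop()
        for succ in web.graph.successors(node):
            if succ not in reachable:
                reachable.add(succ)
                frontier.append(succ)
    unsupported = set(names) - reachable
    if unsupported:
        return f"consumers without basal support: {sorted(unsupported)}"
    return None


def _flux_failure(web: FoodWeb) -> str | None:
    """Reject webs whose default-parameter flux balance is infeasible.

    Tight mutual-feeding loops can demand more energy than assimilation can
    supply (negative solved consumption); such webs cannot pass the full
    analysis, so the generator resamples them.
    """
    from .flux import compute_fluxes

    try:
        compute_fluxes(web)
    except FoodWebError as exc:
        return f"flux balance infeasible: {exc}"
    return None


def _generate(spec: SyntheticWebSpec) -> tuple[FoodWeb, np.ndarray, np.ndarray, np.ndarray]:
    """Accepted web plus the niche configuration that produced it."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _TOPOLOGY_STREAM]))
    names = [f"s{i + 1:02d}" for i in range(spec.n_nodes)]
    if spec.n_nodes == 1:
        web = assign_attributes(
            FoodWeb([_placeholder_attrs(names[0])], [], directed=True, label="synthetic"),
            spec,
        )
        return web, np.zeros(1), np.zeros(1), np.zeros(1)
    last_failure = ""
    for _ in range(spec.max_retries):
        values, centres, widths = _draw_topology(rng, spec)
        edges = _edges_from_intervals(names, values, centres, widths)
        failure = _topology_failure(names, edges, spec)
        if failure is not None:
            last_failure = failure
            continue
        web = assign_attributes(
            FoodWeb([_placeholder_attrs(n) for n in names], edges,
                    directed=True, label="synthetic"),
            spec,
        )
        failure = _flux_failure(web)
        if failure is not None:
            last_failure = failure
            continue
        return web, values, centres, widths
    raise FoodWebError(
        f"niche-model generation failed after {spec.max_retries} retries "
        f"(last failure: {last_failure}); connectance {spec.connectance} may be "
        f"infeasible for {spec.n_nodes} nodes"
    )


def generate_niche_web(spec: SyntheticWebSpec) -> FoodWeb:
    """Generate a connected, fully analysable niche-model web.

    Resamples (up to ``spec.max_retries``) until the web is a single
    connected component with at least ``n_basal_min`` basal nodes, no
    self-loops, every consumer supported from a basal node, and a feasible
    default-parameter flux balance; raises with diagnostics when retries
    are exhausted.  Fully reproducible from ``spec.seed``.
    """
    return _generate(spec)[0]


def _placeholder_attrs(name: str) -> NodeAttributes:
    return NodeAttributes(name=name, category="animal")


def assign_attributes(web: FoodWeb, spec: SyntheticWebSpec) -> FoodWeb:
    """Attach categories, biomasses and body masses, reproducibly from seed.

    Basal nodes (empty diet) draw a basal category from the spec
    distribution and get biomass exactly 1 (the placeholder the flux model
    expects); consumers are animals with lognormal biomass and body mass.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _ATTRIBUTE_STREAM]))
    cats = sorted(spec.basal_categories)
    weights = np.array([spec.basal_categories[c] for c in cats], dtype=float)
    weights /= weights.sum()
    attrs = []
    for name in web.nodes:  # alphabetical: stable draw order
        if web.graph.in_degree(name) == 0:
            attrs.append(
                NodeAttributes(
                    name=name,
                    category=str(rng.choice(cats, p=weights)),
                    biomass=1.0,
                    body_mass=None,
                )
            )
        else:
            attrs.append(
                NodeAttributes(
                    name=name,
                    category="animal",
                    biomass=float(rng.lognormal(spec.biomass_logmean, spec.biomass_logsd)),
                    body_mass=float(rng.lognormal(spec.bodymass_logmean, spec.bodymass_logsd)),
                )
            )
    return FoodWeb(attrs, web.edges, directed=True, label=web.label)


def generate_disturbance_pair(
    spec: SyntheticWebSpec, perturbation: Perturbation
) -> tuple[FoodWeb, FoodWeb]:
    """Baseline web plus a disturbed variant sharing part of its node set.

    The perturbed web re-draws the niche position and identity of a
    fraction of basal nodes (renamed, basal-category switched to the
    replacement category) and of consumers; all diets are rebuilt from the
    new niche configuration, so retained consumers may rewire.  Zero
    perturbation returns two identical webs.
    """
    baseline, values, centres, widths = _generate(spec)
    if perturbation.basal_replacement == 0.0 and perturbation.consumer_turnover == 0.0:
        return baseline, baseline.copy(label="synthetic (perturbed)")

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _PERTURB_STREAM]))
    names = baseline.nodes
    index = {n: i for i, n in enumerate(names)}
    basal = sorted(_basal_names(names, baseline.edges))
    consumers = [n for n in names if n not in basal]
    n_replace_basal = int(round(perturbation.basal_replacement * len(basal)))
    n_replace_cons = int(round(perturbation.consumer_turnover * len(consumers)))
    replaced_basal = set(
        rng.choice(basal, size=n_replace_basal, replace=False)
    ) if n_replace_basal else set()
    replaced_cons = set(
        rng.choice(consumers, size=n_replace_cons, replace=False)
    ) if n_replace_cons else set()
    replaced = replaced_basal | replaced_cons

    for attempt in range(spec.max_retries):
        new_values = values.copy()
        new_centres = centres.copy()
        new_widths = widths.copy()
        new_names = list(names)
        for node in sorted(replaced):
            i = index[node]
            new_names[i] = f"t{i + 1:02d}"
            new_values[i] = rng.uniform()
            if node in replaced_basal:
                new_widths[i] = 0.0  # stays basal
            else:
                m = _interval_mean(spec)
                new_widths[i] = new_values[i] * rng.beta(1.0, 1.0 / m - 1.0)
            lo = new_widths[i] / 2.0
            hi = max(lo, min(new_values[i], 1.0 - new_widths[i] / 2.0))
            new_centres[i] = lo + (hi - lo) * rng.uniform()
        new_widths[np.argmin(new_values)] = 0.0
        new_edges = _edges_from_intervals(new_names, new_values, new_centres, new_widths)
        if _topology_failure(new_names, new_edges, spec) is not None:
            continue
        perturbed = _assign_perturbed_attributes(
            FoodWeb([_placeholder_attrs(n) for n in new_names], new_edges,
                    directed=True, label="synthetic (perturbed)"),
            spec, perturbation,
        )
        if _flux_failure(perturbed) is None:
            return baseline, perturbed
    raise FoodWebError(
        f"no valid perturbed web found after {spec.max_retries} retries"
    )


def _assign_perturbed_attributes(
    web: FoodWeb,
    spec: SyntheticWebSpec,
    perturbation: Perturbation,
) -> FoodWeb:
    """Attributes for the perturbed web: re-drawn, replacement basal nodes
    forced to the replacement category (the regime-switch signature)."""
    attributed = assign_attributes(web, replace(spec, seed=spec.seed + 1))
    new_basal_names = {f"t{i + 1:02d}" for i in range(spec.n_nodes)}
    attrs = []
    for a in attributed.node_attributes():
        if a.name in new_basal_names and a.biomass == 1.0 and a.category != "animal":
            attrs.append(
                NodeAttributes(
                    name=a.name,
                    category=perturbation.replacement_basal_category,
                    biomass=1.0,
                )
            )
        else:
            attrs.append(a)
    return FoodWeb(attrs, attributed.edges, directed=True, label=attributed.label)
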