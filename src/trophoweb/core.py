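"""Core data model and I/O for binary trophic networks.

A food web is a directed binary graph whose edges point in the direction of
energy flow, prey -> predator.  Edge-list files on disk follow the common
field convention of ``predator,prey`` columns and are swapped on read.  Every
node carries a small set of ecological attributes (category, functional
group, biomass, mean body mass, period of presence) used downstream by the
trophic-level solver and the energy-flux solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

#: Allowed node categories.  The first three are basal (no trophic inputs in
#: the model); ``animal`` nodes are consumers.
CATEGORIES = frozenset({"producer", "cyanobacteria", "detritus", "animal"})
BASAL_CATEGORIES = frozenset({"producer", "cyanobacteria", "detritus"})
PERIODS = frozenset({"PRE", "POST"})

ATTRIBUTE_COLUMNS = [
    "taxon",
    "functional_group",
    "category",
    "period",
    "biomass_g",
    "body_mass_g",
]


class FoodWebError(ValueError):
    """Raised for structurally invalid webs or malformed input files."""


@dataclass(frozen=True)
class NodeAttributes:
    """Ecological attributes of one node (taxon or functional group).

    Parameters
    ----------
    name:
        Unique label within a web.
    category:
        One of ``producer``, ``cyanobacteria``, ``detritus``, ``animal``.
    functional_group:
        Aggregation target label; defaults to ``name``.
    biomass:
        Total biomass in grams (optional, > 0 when present).
    body_mass:
        Mean individual body mass in grams (optional, > 0 when present).
    period:
        Subset of ``{"PRE", "POST"}`` indicating presence.
    """

    name: str
    category: str
    functional_group: str | None = None
    biomass: float | None = None
    body_mass: float | None = None
    period: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.name:
            raise FoodWebError("node name must be nonempty")
        if self.category not in CATEGORIES:
            raise FoodWebError(
                f"node {self.name!r}: category {self.category!r} not in {sorted(CATEGORIES)}"
            )
        if self.functional_group is None:
            object.__setattr__(self, "functional_group", self.name)
        for label, value in (("biomass", self.biomass), ("body_mass", self.body_mass)):
            if value is not None and not value > 0:
                raise FoodWebError(f"node {self.name!r}: {label} must be > 0, got {value}")
        bad = set(self.period) - PERIODS
        if bad:
            raise FoodWebError(f"node {self.name!r}: unknown period labels {sorted(bad)}")
        object.__setattr__(self, "period", frozenset(self.period))

    @property
    def is_basal_category(self) -> bool:
        return self.category in BASAL_CATEGORIES


class FoodWeb:
    """A binary trophic network with per-node attributes.

    Directed webs store edges prey -> predator.  Undirected webs arise from
    :func:`symmetrize` and are what the global topology indices consume.
    Nodes are kept in alphabetical order everywhere so that output files are
    deterministic.
    """

    def __init__(
        self,
        nodes: Iterable[NodeAttributes],
        edges: Iterable[tuple[str, str]] = (),
        directed: bool = True,
        label: str = "",
    ) -> None:
        self.directed = bool(directed)
        self.label = label
        self._attrs: dict[str, NodeAttributes] = {}
        for attrs in nodes:
            if attrs.name in self._attrs:
                raise FoodWebError(f"duplicate node name {attrs.name!r}")
            self._attrs[attrs.name] = attrs
        self.graph: nx.DiGraph | nx.Graph = nx.DiGraph() if directed else nx.Graph()
        self.graph.add_nodes_from(sorted(self._attrs))
        for u, v in edges:
            for name in (u, v):
                if name not in self._attrs:
                    raise FoodWebError(f"edge ({u!r}, {v!r}) references unknown node {name!r}")
            self.graph.add_edge(u, v)

    # -- basic queries -----------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        if self.directed:
            return set(self.graph.edges)
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def attributes(self, name: str) -> NodeAttributes:
        return self._attrs[name]

    def node_attributes(self) -> list[NodeAttributes]:
        return [self._attrs[n] for n in self.nodes]

    def biomass(self, name: str) -> float | None:
        return self._attrs[name].biomass

    def category(self, name: str) -> str:
        return self._attrs[name].category

    def prey_of(self, name: str) -> list[str]:
        """Diet items of a consumer (in-neighbours on the directed web)."""
        if not self.directed:
            raise FoodWebError("prey_of requires a directed web")
        return sorted(self.graph.predecessors(name))

    def predators_of(self, name: str) -> list[str]:
        if not self.directed:
            raise FoodWebError("predators_of requires a directed web")
        return sorted(self.graph.successors(name))

    def subweb(self, keep: Iterable[str], label: str | None = None) -> "FoodWeb":
        """Induced sub-web on ``keep`` (attributes carried over)."""
        keep = set(keep)
        nodes = [a for n, a in self._attrs.items() if n in keep]
        edges = [(u, v) for u, v in self.graph.edges if u in keep and v in keep]
        return FoodWeb(nodes, edges, directed=self.directed,
                       label=self.label if label is None else label)

    def copy(self, label: str | None = None) -> "FoodWeb":
        return self.subweb(self.nodes, label=label)

    # -- validation --------------------------------------------------------

    def validate_analysis_ready(self) -> None:
        """Check the invariants of an analysis-ready web.

        Analysis-ready means: no self-loops, and a single connected
        component once feeding links are treated as undirected.
        """
        loops = [n for n in self.graph.nodes if self.graph.has_edge(n, n)]
        if loops:
            raise FoodWebError(f"web {self.label!r} has self-loops on {loops}")
        ok, components = check_connected(self)
        if not ok:
            raise FoodWebError(
                f"web {self.label!r} is not a single component: "
                f"{len(components)} components, sizes {[len(c) for c in components]}"
            )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "directed" if self.directed else "undirected"
        return f"<FoodWeb {self.label!r}: {self.n_nodes} nodes, {self.n_edges} {kind} links>"


@dataclass(frozen=True)
class AggregationScheme:
    """Many-to-one mapping from raw taxon names to functional-group nodes."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> str:
        return self.mapping[name]

    def covers(self, web: FoodWeb) -> bool:
        return all(n in self.mapping for n in web.nodes)

    @classmethod
    def identity(cls, web: FoodWeb) -> "AggregationScheme":
        return cls({n: n for n in web.nodes})

    @classmethod
    def from_functional_groups(cls, web: FoodWeb) -> "AggregationScheme":
        """Build the scheme from each node's ``functional_group`` attribute."""
        return cls({n: web.attributes(n).functional_group for n in web.nodes})

    @classmethod
    def from_csv(cls, path: str | Path) -> "AggregationScheme":
        df = pd.read_csv(path)
        required = {"taxon", "functional_group"}
        if not required <= set(df.columns):
            raise FoodWebError(f"scheme file {path} must have columns {sorted(required)}")
        return cls(dict(zip(df["taxon"].astype(str), df["functional_group"].astype(str))))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.mapping.items()), columns=["taxon", "functional_group"]
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_period(raw: object) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return frozenset()
    return frozenset(p for p in str(raw).replace("|", ";").split(";") if p)


def _parse_optional_float(raw: object) -> float | None:
    if raw is None or raw == "":
        return None
    value = float(raw)
    if math.isnan(value):
        return None
    return value


def read_attributes(attribute_file: str | Path) -> list[NodeAttributes]:
    df = pd.read_csv(attribute_file)
    if df.empty:
        raise FoodWebError(f"attribute file {attribute_file} is empty")
    missing = {"taxon", "category"} - set(df.columns)
    if missing:
        raise FoodWebError(f"attribute file {attribute_file} lacks columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            NodeAttributes(
                name=str(row["taxon"]),
                category=str(row["category"]),
                functional_group=(
                    str(row["functional_group"])
                    if "functional_group" in df.columns and not pd.isna(row["functional_group"])
                    else None
                ),
                biomass=_parse_optional_float(row.get("biomass_g")),
                body_mass=_parse_optional_float(row.get("body_mass_g")),
                period=_parse_period(row.get("period")),
            )
        )
    return out


def read_web(
    edge_file: str | Path, attribute_file: str | Path, label: str = ""
) -> FoodWeb:
    """Read a directed web from a ``predator,prey`` edge list plus attributes.

    Edge rows are swapped on read so that stored edges run prey -> predator
    (the direction of energy flow).  Duplicate rows collapse to one edge.
    Unknown node names in the edge file are a hard error naming the row.
    """
    attrs = read_attributes(attribute_file)
    known = {a.name for a in attrs}
    df = pd.read_csv(edge_file)
    if df.empty:
        raise FoodWebError(f"edge file {edge_file} is empty")
    missing = {"predator", "prey"} - set(df.columns)
    if missing:
        raise FoodWebError(f"edge file {edge_file} lacks columns {sorted(missing)}")
    edges = []
    for i, row in df.iterrows():
        predator, prey = str(row["predator"]), str(row["prey"])
        for name in (predator, prey):
            if name not in known:
                raise FoodWebError(
                    f"edge file {edge_file} row {i + 2}: unknown node {name!r}"
                )
        edges.append((prey, predator))
    return FoodWeb(attrs, edges, directed=True, label=label)


def write_web(
    web: FoodWeb,
    edge_file: str | Path,
    attribute_file: str | Path,
    adjacency_file: str | Path | None = None,
) -> None:
    """Write a web back to the CSV dialect :func:`read_web` consumes.

    The optional adjacency matrix is 0/1 with rows = prey, columns =
    predators, nodes in alphabetical order.
    """
    if web.directed:
        rows = [(pred, prey) for prey, pred in sorted(web.edges)]
    else:
        # undirected: emit each unordered pair once, alphabetical
        rows = [(v, u) for u, v in sorted(web.edges)]
    pd.DataFrame(rows, columns=["predator", "prey"]).sort_values(
        ["predator", "prey"]
    ).to_csv(edge_file, index=False)

    records = []
    for a in web.node_attributes():
        records.append(
            {
                "taxon": a.name,
                "functional_group": a.functional_group,
                "category": a.category,
                "period": ";".join(sorted(a.period)),
                "biomass_g": a.biomass if a.biomass is not None else "",
                "body_mass_g": a.body_mass if a.body_mass is not None else "",
            }
        )
    pd.DataFrame(records, columns=ATTRIBUTE_COLUMNS).to_csv(attribute_file, index=False)

    if adjacency_file is not None:
        names = web.nodes
        adj = pd.DataFrame(0, index=names, columns=names, dtype=int)
        for u, v in web.graph.edges:
            adj.loc[u, v] = 1
            if not web.directed:
                adj.loc[v, u] = 1
        adj.to_csv(adjacency_file, index_label="prey")


# ---------------------------------------------------------------------------
# Structural operations
# ---------------------------------------------------------------------------

def symmetrize(web: FoodWeb) -> FoodWeb:
    """Undirected view: i and j linked iff either feeds on the other.

    Mutual predation (i->j and j->i) collapses to a single undirected link,
    so the undirected link count L counts unordered pairs.  Self-loops are
    dropped.  Idempotent: symmetrizing an undirected web returns a copy.
    """
    pairs = {tuple(sorted((u, v))) for u, v in web.graph.edges if u != v}
    return FoodWeb(
        web.node_attributes(), pairs, directed=False,
        label=f"{web.label} (symmetrized)" if web.directed and web.label else web.label,
    )


def aggregate(web: FoodWeb, scheme: AggregationScheme) -> FoodWeb:
    """Merge raw taxa into functional-group nodes.

    An edge (G1, G2) exists iff some raw edge connects a member of G1 to a
    member of G2; within-group edges would become self-loops and are
    removed.  Aggregated biomass is the sum of member biomasses; body mass
    is the biomass-weighted mean over members with both values; category is
    inherited and must agree across members; periods are unioned.
    """
    uncovered = [n for n in web.nodes if n not in scheme.mapping]
    if uncovered:
        raise FoodWebError(f"aggregation scheme does not cover nodes {uncovered}")

    groups: dict[str, list[NodeAttributes]] = {}
    for n in web.nodes:
        groups.setdefault(scheme[n], []).append(web.attributes(n))

    merged = []
    for gname, members in sorted(groups.items()):
        cats = {m.category for m in members}
        if len(cats) > 1:
            raise FoodWebError(
                f"group {gname!r}: conflicting categories {sorted(cats)} among members "
                f"{[m.name for m in members]}"
            )
        biomasses = [m.biomass for m in members if m.biomass is not None]
        biomass = sum(biomasses) if biomasses else None
        weighted = [
            (m.biomass, m.body_mass)
            for m in members
            if m.biomass is not None and m.body_mass is not None
        ]
        if weighted:
            wsum = sum(b for b, _ in weighted)
            body_mass = sum(b * m for b, m in weighted) / wsum
        else:
            body_mass = None
        period = frozenset().union(*(m.period for m in members))
        merged.append(
            NodeAttributes(
                name=gname,
                category=cats.pop(),
                functional_group=gname,
                biomass=biomass,
                body_mass=body_mass,
                period=period,
            )
        )

    edges = {
        (scheme[u], scheme[v])
        for u, v in web.graph.edges
        if scheme[u] != scheme[v]  # drop within-group self-loops
    }
    return FoodWeb(merged, edges, directed=web.directed,
                   label=f"{web.label} (aggregated)" if web.label else "aggregated")


def check_connected(web: FoodWeb) -> tuple[bool, list[set[str]]]:
    """True iff the symmetrized web is a single connected component.

    Returns the component node sets (largest first) for diagnostics.
    """
    if web.n_nodes == 0:
        raise FoodWebError("cannot check connectivity of an empty web")
    g = web.graph.to_undirected() if web.directed else web.graph
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    return len(components) == 1, [set(c) for c in components]


def relabel(web: FoodWeb, label: str) -> FoodWeb:
    out = web.copy()
    out.label = label
    return out
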