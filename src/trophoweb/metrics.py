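"""Global and node-level topology indices on symmetrized webs.

Six whole-web indices — node count N, undirected link count L, density
D = 2L/N(N-1), degree-weighted overall clustering CL, average geodesic
distance d, and the small-world ratio SW = CL/d — plus two per-node
centralities: normalized degree (nDC = k/(N-1)) and normalized betweenness
(nBC, percent of the undirected maximum (N-1)(N-2)/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .core import FoodWeb, FoodWebError, check_connected


@dataclass(frozen=True)
class GlobalMetrics:
    """The six whole-web indices, with exact identities D = 2L/N(N-1) and SW = CL/d."""

    n_nodes: int
    n_links: int
    density: float
    clustering: float
    average_distance: float
    small_world: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "Number of nodes (N)": self.n_nodes,
                "Number of links (L)": self.n_links,
                "Network density (D)": round(self.density, 3),
                "Weighted overall graph clustering coefficient (CL)": round(self.clustering, 3),
                "Average distance (d)": round(self.average_distance, 3),
                "Small world index (CL/d)": round(self.small_world, 3),
            },
            dtype=object,  # keep N and L integral in output files
        )


def _require_undirected(web: FoodWeb, op: str) -> nx.Graph:
    if web.directed:
        raise FoodWebError(f"{op} expects a symmetrized (undirected) web")
    return web.graph


def density(web: FoodWeb) -> float:
    """Connectance D = 2L/(N(N-1)) of a simple undirected web."""
    g = _require_undirected(web, "density")
    n = g.number_of_nodes()
    if n < 2:
        raise FoodWebError("density needs at least 2 nodes")
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def clustering_weighted_overall(web: FoodWeb) -> float:
    """Degree-weighted mean of local clustering coefficients.

    c_i = 2 t_i / (k_i (k_i - 1)) with t_i the triangles through i; nodes of
    degree < 2 contribute c_i = 0; CL = sum(k_i c_i) / sum(k_i).
    """
    g = _require_undirected(web, "clustering")
    if g.number_of_nodes() == 0:
        raise FoodWebError("clustering of an empty web is undefined")
    degrees = dict(g.degree())
    total_degree = sum(degrees.values())
    if total_degree == 0:
        return 0.0
    local = nx.clustering(g)  # 0.0 for degree < 2, matching the convention above
    return sum(degrees[n] * local[n] for n in g) / total_degree


def average_distance(web: FoodWeb) -> float:
    """Mean geodesic length over all unordered pairs of distinct nodes."""
    g = _require_undirected(web, "average distance")
    if g.number_of_nodes() < 2:
        raise FoodWebError("average distance needs at least 2 nodes")
    ok, components = check_connected(web)
    if not ok:
        raise FoodWebError(
            f"average distance undefined on a disconnected web; components: "
            f"{[sorted(c) for c in components]}"
        )
    # ordered-pair mean equals unordered-pair mean on an undirected web
    return nx.average_shortest_path_length(g)


def small_world(clustering: float, avg_distance: float) -> float:
    """SW = CL/d."""
    if avg_distance == 0:
        raise FoodWebError("small-world index undefined for d = 0")
    return clustering / avg_distance


def global_metrics(web: FoodWeb) -> GlobalMetrics:
    """All six indices of a connected symmetrized web in one pass."""
    cl = clustering_weighted_overall(web)
    d = average_distance(web)
    return GlobalMetrics(
        n_nodes=web.n_nodes,
        n_links=web.n_edges,
        density=density(web),
        clustering=cl,
        average_distance=d,
        small_world=small_world(cl, d),
    )


def degree_centrality(web: FoodWeb) -> dict[str, float]:
    """nDC_i = k_i/(N-1), in [0, 1]."""
    g = _require_undirected(web, "degree centrality")
    n = g.number_of_nodes()
    if n < 2:
        raise FoodWebError("degree centrality needs at least 2 nodes")
    return {node: deg / (n - 1) for node, deg in g.degree()}


def betweenness_centrality(web: FoodWeb, percent: bool = True) -> dict[str, float]:
    """Normalized betweenness with exact geodesic counting.

    Raw betweenness B_i sums sigma_jk(i)/sigma_jk over unordered pairs
    excluding i.  With ``percent`` (default) values are scaled to percent of
    the undirected maximum (N-1)(N-2)/2; otherwise the fraction in [0, 1] is
    returned.
    """
    g = _require_undirected(web, "betweenness centrality")
    if g.number_of_nodes() < 3:
        raise FoodWebError("betweenness needs at least 3 nodes")
    ok, components = check_connected(web)
    if not ok:
        raise FoodWebError(
            f"betweenness expects a connected web; components: "
            f"{[sorted(c) for c in components]}"
        )
    bc = nx.betweenness_centrality(g, normalized=True)  # Brandes, exact counts
    scale = 100.0 if percent else 1.0
    return {node: scale * value for node, value in bc.items()}


def node_metrics(web: FoodWeb) -> pd.DataFrame:
    """Per-node table with nDC and nBC, nodes alphabetical."""
    ndc = degree_centrality(web)
    nbc = betweenness_centrality(web)
    return pd.DataFrame(
        {
            "node": web.nodes,
            "nDC": [round(ndc[n], 2) for n in web.nodes],
            "nBC": [round(nbc[n], 2) for n in web.nodes],
        }
    )
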