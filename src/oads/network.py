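"""Disease association networks: thresholding, topology, and WiND.

A disease network keeps an edge only when the pair's similarity exceeds the
90th percentile of all scored pairs AND the permutation p-value is below 0.05
(both configurable). Topology metrics mirror standard systems-biology usage:
centralities, clustering, transitivity, k-core, diameter and shortest paths.

WiND (within-network distance) summarises how tightly a disease subset sits
inside the full network: the mean hop-count shortest-path length over the
subset's connected pairs. The ratio of a category's WiND to the whole
network's WiND is < 1 when the category clusters more tightly than average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ContractError
from .powerlaw import powerlaw_classify  # noqa: F401  (re-exported surface)
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiseaseNetwork:
    """Undirected similarity graph of diseases surviving both thresholds."""

    graph: nx.Graph
    modality: str = ""
    percentile: float = 90.0
    alpha: float = 0.05
    score_cut: float = float("nan")
    isolated: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(u, v), max(u, v), d["similarity"])
            for u, v, d in self.graph.edges(data=True)
        )


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    transitivity: float
    kcore_k: int
    kcore_size: int
    average_clustering: float
    average_shortest_path: float
    diameter: int
    n_components: int
    degree: dict[str, int]
    betweenness: dict[str, float]
    closeness: dict[str, float]
    eigenvector: dict[str, float]

    def top_degree(self, k: int = 10) -> list[tuple[str, int]]:
        return sorted(self.degree.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def build_network(
    sim: SimilarityMatrix, percentile: float = 90.0, alpha: float = 0.05
) -> DiseaseNetwork:
    """Threshold a similarity matrix into a disease network.

    An edge (i, j) survives iff its score is strictly greater than the given
    percentile of all off-diagonal upper-triangle scores and its permutation
    p-value is below ``alpha``. Isolated diseases are dropped from the graph
    but recorded on the result.
    """
    if sim.pvalues is None:
        raise ContractError("similarity matrix carries no p-values")
    if not (0.0 < percentile < 100.0):
        raise ContractError("percentile must lie in (0, 100)")
    ids = sim.disease_ids
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    cut = float(np.percentile(sim.scores[iu], percentile))
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, j in zip(*iu):
        s = sim.scores[i, j]
        if s > cut and sim.pvalues[i, j] < alpha:
            g.add_edge(ids[i], ids[j], similarity=float(s))
    isolated = sorted(d for d in ids if g.degree(d) == 0)
    g.remove_nodes_from(isolated)
    if isolated:
        logger.info("%d isolated diseases dropped from %s network", len(isolated), sim.modality)
    return DiseaseNetwork(
        graph=g,
        modality=sim.modality,
        percentile=percentile,
        alpha=alpha,
        score_cut=cut,
        isolated=isolated,
    )


def topology_summary(net: DiseaseNetwork) -> TopologySummary:
    """All headline topology metrics of a disease network.

    Path-based metrics (average shortest path, diameter) are computed on the
    largest connected component; the component count is reported alongside.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ContractError("network has no edges")
    n, e = g.number_of_nodes(), g.number_of_edges()
    comps = list(nx.connected_components(g))
    lcc = g.subgraph(max(comps, key=len))
    core = nx.core_number(g)
    kmax = max(core.values())
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n,
        density=nx.density(g),
        transitivity=nx.transitivity(g),
        kcore_k=kmax,
        kcore_size=sum(1 for v in core.values() if v == kmax),
        average_clustering=nx.average_clustering(g),
        average_shortest_path=nx.average_shortest_path_length(lcc),
        diameter=nx.diameter(lcc),
        n_components=len(comps),
        degree=dict(g.degree()),
        betweenness=nx.betweenness_centrality(g),
        closeness=nx.closeness_centrality(g),
        eigenvector=nx.eigenvector_centrality(g, max_iter=1000),
    )


def wind(net: DiseaseNetwork, members: list[str] | None = None) -> dict:
    """Within-network distance of a disease subset (or the whole network).

    Mean shortest-path length (hop counts, measured in the full network) over
    all connected member pairs k. Disconnected pairs are excluded from both
    the sum and k. With ``members=None`` this equals the network's average
    shortest path length when the network is connected.

    Returns ``{"wind": mean distance, "pair_count": k, "direct_links":
    number of member pairs joined by an edge}``.
    """
    g = net.graph
    if members is None:
        members = sorted(g.nodes)
    else:
        members = sorted(set(members) & set(g.nodes))
    if len(members) < 2:
        raise ContractError("need at least 2 members present in the network")
    mset = set(members)
    total = 0.0
    k = 0
    direct = 0
    for idx, src in enumerate(members):
        lengths = nx.single_source_shortest_path_length(g, src)
        for tgt in members[idx + 1 :]:
            d = lengths.get(tgt)
            if d is not None:
                total += d
                k += 1
                if d == 1:
                    direct += 1
    if k == 0:
        raise ContractError("no connected member pair; WiND undefined")
    return {"wind": total / k, "pair_count": k, "direct_links": direct}


def wind_ratio(category_wind: float, network_wind: float) -> float:
    """Category WiND over Network WiND; < 1 indicates category clustering."""
    if network_wind <= 0:
        raise ContractError("network WiND must be positive")
    return category_wind / network_wind
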