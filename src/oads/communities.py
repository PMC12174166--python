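"""Community detection, consensus, and per-community feature enrichment.

Networks are clustered two ways — Ward hierarchical clustering on the
1 − similarity distance matrix and the Leiden modularity algorithm on the
thresholded graph — and partition agreement is quantified with the adjusted
Rand index and Kendall tau rank consistency. Robust communities are the
connected components of the co-clustering graph (two diseases linked iff they
share a cluster in every supplied partition) with at least ``min_size``
members. Features over-represented in a community are flagged with one-sided
Fisher exact tests under Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact, kendalltau
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .errors import ContractError
from .network import DiseaseNetwork
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class CommunityPartition:
    method: str  # "ward_hc" or "leiden"
    modality: str
    assignment: dict[str, int]
    parameters: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class RobustCommunity:
    community_id: int
    members: list[str]
    category_counts: dict[str, int] = field(default_factory=dict)
    enriched_features: list[dict] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def ward_clusters(
    sim: SimilarityMatrix, n_clusters: int, modality: str | None = None
) -> CommunityPartition:
    """Ward agglomerative clustering on the 1 − similarity distance matrix."""
    if n_clusters < 2:
        raise ContractError("n_clusters must be >= 2")
    n = len(sim.disease_ids)
    if sim.scores.shape != (n, n):
        raise ContractError("similarity matrix must be square")
    dist = 1.0 - sim.scores
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return CommunityPartition(
        method="ward_hc",
        modality=modality or sim.modality,
        assignment={d: int(c) for d, c in zip(sim.disease_ids, labels)},
        parameters={"n_clusters": n_clusters},
    )


def leiden_clusters(
    net: DiseaseNetwork, resolution: float = 1.0, seed: int = 0
) -> CommunityPartition:
    """Leiden modularity communities on the thresholded disease graph."""
    g = net.graph
    if g.number_of_edges() == 0:
        raise ContractError("network has no edges")
    nodes = sorted(g.nodes)
    index = {d: i for i, d in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges()]
    weights = [g[u][v]["similarity"] for u, v in g.edges()]
    h = ig.Graph(n=len(nodes), edges=edges)
    part = leidenalg.find_partition(
        h,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return CommunityPartition(
        method="leiden",
        modality=net.modality,
        assignment={d: int(part.membership[index[d]]) for d in nodes},
        parameters={"resolution": resolution, "seed": seed},
    )


def adjusted_rand_index(p1: CommunityPartition, p2: CommunityPartition) -> float:
    """ARI between two partitions over their shared disease set."""
    shared = sorted(set(p1.assignment) & set(p2.assignment))
    if not shared:
        raise ContractError("partitions share no diseases")
    a = [p1.assignment[d] for d in shared]
    b = [p2.assignment[d] for d in shared]
    return float(adjusted_rand_score(a, b))


def kendall_consistency(
    rankings: dict[str, list], reference: str | None = None
) -> dict[tuple[str, str], float]:
    """Kendall tau-b between disease-pair score rankings across modalities.

    ``rankings`` maps a modality name to a score (or rank) vector over one
    shared, identically ordered disease-pair list. With ``reference`` set,
    only pairs involving the reference modality plus all remaining mutual
    pairs are reported (every unordered modality pair, in practice).
    """
    names = sorted(rankings)
    lengths = {len(v) for v in rankings.values()}
    if len(lengths) != 1 or lengths.pop() < 2:
        raise ContractError("rankings must share >= 2 disease pairs")
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if reference is not None and reference not in (a, b):
                continue
            tau, _ = kendalltau(rankings[a], rankings[b])
            out[(a, b)] = float(tau)
    if reference is not None:
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if (a, b) not in out:
                    tau, _ = kendalltau(rankings[a], rankings[b])
                    out[(a, b)] = float(tau)
    return out


def robust_communities(
    partitions: list[CommunityPartition],
    min_size: int = 4,
    categories: dict[str, str] | None = None,
    rule: str = "all",
    k: int | None = None,
) -> list[RobustCommunity]:
    """Consensus communities stable across clustering methods and modalities.

    Builds a co-clustering graph on the diseases shared by every partition:
    two diseases are linked iff they co-cluster in every partition (rule
    ``"all"``) or in at least ``k`` partitions (rule ``"any_k"``). Connected
    components with >= ``min_size`` members are returned, largest first, with
    per-category member counts when ``categories`` is given.
    """
    if len(partitions) < 2:
        raise ContractError("need at least 2 partitions")
    shared = set(partitions[0].assignment)
    for p in partitions[1:]:
        shared &= set(p.assignment)
    if not shared:
        raise ContractError("partitions share no diseases")
    shared = sorted(shared)
    need = len(partitions) if rule == "all" else (k if k is not None else len(partitions))
    g = nx.Graph()
    g.add_nodes_from(shared)
    for i, d1 in enumerate(shared):
        for d2 in shared[i + 1 :]:
            votes = sum(p.assignment[d1] == p.assignment[d2] for p in partitions)
            if votes >= need:
                g.add_edge(d1, d2)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g) if len(c) >= min_size),
        key=lambda c: (-len(c), c[0]),
    )
    out = []
    for cid, members in enumerate(comps, start=1):
        counts = dict(Counter(categories[d] for d in members if d in categories)) if categories else {}
        out.append(RobustCommunity(community_id=cid, members=members, category_counts=counts))
    return out


def feature_enrichment(
    communities: list[RobustCommunity],
    features: dict[str, set],
    alpha: float = 0.05,
    adjust: str = "per_community",
) -> list[dict]:
    """One-sided Fisher enrichment of features within each robust community.

    For each (community, feature) a 2x2 table [[in-community with feature,
    in-community without], [outside with, outside without]] is tested for
    enrichment (alternative="greater"); BH adjustment is applied across the
    features tested within one community (``adjust="per_community"``) or
    across all tests (``adjust="global"``). Rows with p < ``alpha`` carry
    ``significant=True``.
    """
    universe = sorted({d for c in communities for d in c.members})
    all_feats = sorted({f for d in universe for f in features.get(d, ())})
    if not all_feats:
        raise ContractError("no feature covers any community member")
    rows = []
    for com in communities:
        inside = set(com.members)
        outside = [d for d in universe if d not in inside]
        com_rows = []
        for feat in all_feats:
            a = sum(feat in features.get(d, ()) for d in inside)
            if a == 0:
                continue  # feature absent in this community: nothing to enrich
            b = len(inside) - a
            c = sum(feat in features.get(d, ()) for d in outside)
            d_ = len(outside) - c
            _, p = fisher_exact([[a, b], [c, d_]], alternative="greater")
            com_rows.append(
                {"community_id": com.community_id, "feature": feat,
                 "a": a, "b": b, "c": c, "d": d_, "p": float(p)}
            )
        if adjust == "per_community" and com_rows:
            adj = multipletests([r["p"] for r in com_rows], method="fdr_bh")[1]
            for r, q in zip(com_rows, adj):
                r["p_adj"] = float(q)
        rows.extend(com_rows)
    if adjust == "global" and rows:
        adj = multipletests([r["p"] for r in rows], method="fdr_bh")[1]
        for r, q in zip(rows, adj):
            r["p_adj"] = float(q)
    for r in rows:
        r["significant"] = r["p"] < alpha and r.get("p_adj", 1.0) < alpha
    for com in communities:
        com.enriched_features = [r for r in rows if r["community_id"] == com.community_id and r["significant"]]
    return rows


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return list(multipletests(pvalues, method="fdr_bh")[1])
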