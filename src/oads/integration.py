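"""Cross-modality integration: similarity network fusion, benchmark
correlation, and minimum-spanning-tree disease trajectories.

SNF (similarity network fusion) iteratively diffuses each modality's full
affinity matrix through every other modality's K-nearest-neighbour local
kernel, converging to one integrated network that captures both intra- and
inter-modality relationships. Disease trajectories are read off the minimum
spanning tree of the significance-filtered distance matrix
(distance = 1 − similarity), grown with Prim's algorithm.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ContractError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class FusionConfig:
    K: int = 10  # neighbourhood size for the local kernel
    t: int = 20  # cross-diffusion iterations
    mu: float = 0.5  # kernel bandwidth scale
    use_kernel: bool = True  # scaled-exponential kernel on 1 - sim; False: raw affinities

    def __post_init__(self):
        if self.K < 1:
            raise ContractError("K must be >= 1")
        if self.t < 1:
            raise ContractError("t must be >= 1")


def _affinity(sim: np.ndarray, K: int, mu: float) -> np.ndarray:
    """Scaled-exponential affinity kernel on distance 1 − similarity."""
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    # mean distance to the K nearest neighbours (self excluded)
    srt = np.sort(d, axis=1)[:, 1 : K + 1]
    means = srt.mean(axis=1) + np.finfo(float).eps
    eps = (means[:, None] + means[None, :] + d) / 3.0
    W = np.exp(-(d**2) / (mu * eps + np.finfo(float).eps))
    return (W + W.T) / 2.0


def _p_normalise(W: np.ndarray) -> np.ndarray:
    """Full-kernel normalisation: off-diagonal rows sum to 1/2, diagonal 1/2."""
    P = W.copy().astype(float)
    np.fill_diagonal(P, 0.0)
    rs = P.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    P = P / (2.0 * rs)
    np.fill_diagonal(P, 0.5)
    return P


def _knn_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Sparse local kernel: each row keeps its K strongest neighbours, row-normalised."""
    n = W.shape[0]
    S = np.zeros_like(W, dtype=float)
    for i in range(n):
        row = W[i].copy()
        row[i] = -np.inf
        nbrs = np.argsort(-row, kind="stable")[:K]
        vals = W[i, nbrs]
        tot = vals.sum()
        if tot > 0:
            S[i, nbrs] = vals / tot
    return S


def snf_fuse(
    matrices: list[SimilarityMatrix], config: FusionConfig | None = None
) -> SimilarityMatrix:
    """Fuse >= 2 similarity matrices into one integrated network via SNF.

    Matrices are restricted to their shared diseases, converted to affinity
    kernels, and cross-diffused for ``config.t`` iterations:
    P_v <- S_v (mean of the other views' P) S_v^T, renormalised and
    symmetrised each step. The output is the symmetrised mean of the final
    diffused matrices, with unit diagonal.
    """
    cfg = config or FusionConfig()
    if len(matrices) < 2:
        raise ContractError("need at least 2 matrices to fuse")
    shared = set(matrices[0].disease_ids)
    for m in matrices[1:]:
        shared &= set(m.disease_ids)
    ids = sorted(shared)
    n = len(ids)
    if n < 3:
        raise ContractError("need at least 3 shared diseases")
    if cfg.K >= n:
        raise ContractError(f"K={cfg.K} must be < number of shared diseases ({n})")

    views = []
    for m in matrices:
        perm = [m.index_of(d) for d in ids]
        sub = m.scores[np.ix_(perm, perm)]
        if np.any(sub < 0):
            raise ContractError("similarity matrices must be non-negative")
        views.append(sub)

    Ws = [_affinity(v, cfg.K, cfg.mu) if cfg.use_kernel else v.copy() for v in views]
    eye = np.eye(n)
    Ps = []
    for W in Ws:
        P = W / W.sum(axis=1, keepdims=True)
        Ps.append((P + P.T) / 2.0)
    Ss = [_knn_kernel(W, cfg.K) for W in Ws]

    for _ in range(cfg.t):
        new = []
        for v in range(len(Ps)):
            others = [Ps[u] for u in range(len(Ps)) if u != v]
            mean_other = sum(others) / len(others)
            P = Ss[v] @ mean_other @ Ss[v].T
            # identity regularisation keeps the diffusion well-conditioned
            P = (P + P.T) / 2.0 + eye
            new.append(P)
        Ps = new

    fused = sum(Ps) / len(Ps)
    fused = fused / fused.sum(axis=1, keepdims=True)
    fused = (fused + fused.T) / 2.0
    if np.any(~np.isfinite(fused)):
        raise ContractError("fusion produced non-finite values")
    # rescale to [0, 1] with unit diagonal for downstream thresholding
    off = ~np.eye(n, dtype=bool)
    hi = fused[off].max()
    if hi > 0:
        out = fused / hi
        out = np.minimum(out, 1.0)
    else:
        out = fused
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(disease_ids=ids, scores=out, modality="fused")


def benchmark_correlation(m1: SimilarityMatrix, m2: SimilarityMatrix) -> float:
    """Pearson r between two matrices' off-diagonal entries on shared diseases."""
    shared = sorted(set(m1.disease_ids) & set(m2.disease_ids))
    if len(shared) < 3:
        raise ContractError("need at least 3 shared diseases")
    p1 = [m1.index_of(d) for d in shared]
    p2 = [m2.index_of(d) for d in shared]
    iu = np.triu_indices(len(shared), k=1)
    v1 = m1.scores[np.ix_(p1, p1)][iu]
    v2 = m2.scores[np.ix_(p2, p2)][iu]
    if v1.std() == 0 or v2.std() == 0:
        raise ContractError("zero variance: correlation undefined")
    return float(np.corrcoef(v1, v2)[0, 1])


def build_mst(
    sim: SimilarityMatrix, percentile: float = 90.0, alpha: float = 0.05
) -> list[tuple[str, str, float]]:
    """Minimum spanning tree (Prim) over significance-filtered distances.

    Pairs must pass the same filter as network construction (similarity
    strictly above the given percentile of all scored pairs and p < alpha);
    distance = 1 − similarity on surviving pairs only. Disconnected filtered
    graphs yield a spanning forest (per-component trees) with a logged
    component count. Equal-weight edges are broken by lexicographic disease-id
    pair, making the output deterministic.
    """
    if sim.pvalues is None:
        raise ContractError("similarity matrix carries no p-values")
    ids = sim.disease_ids
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    cut = float(np.percentile(sim.scores[iu], percentile))
    adj: dict[str, list[tuple[str, float]]] = {}
    for i, j in zip(*iu):
        s = sim.scores[i, j]
        if s > cut and sim.pvalues[i, j] < alpha:
            d = 1.0 - float(s)
            adj.setdefault(ids[i], []).append((ids[j], d))
            adj.setdefault(ids[j], []).append((ids[i], d))
    retained = sorted(adj)
    if len(retained) < 2:
        raise ContractError("fewer than 2 diseases survive the significance filter")

    visited: set[str] = set()
    tree: list[tuple[str, str, float]] = []
    n_components = 0
    for start in retained:
        if start in visited:
            continue
        n_components += 1
        visited.add(start)
        heap: list[tuple[float, str, str, str, str]] = []
        for v, d in adj[start]:
            heapq.heappush(heap, (d, min(start, v), max(start, v), start, v))
        while heap:
            d, _, _, u, v = heapq.heappop(heap)
            if v in visited:
                continue
            visited.add(v)
            tree.append((min(u, v), max(u, v), d))
            for w, dw in adj[v]:
                if w not in visited:
                    heapq.heappush(heap, (dw, min(v, w), max(v, w), v, w))
    if n_components > 1:
        logger.info("filtered graph is disconnected: spanning forest with %d components", n_components)
    return sorted(tree)


def mst_to_newick(tree: list[tuple[str, str, float]]) -> str:
    """Bracketed (Newick-like) rendering of an MST, rooted at the first node."""
    g = nx.Graph()
    for u, v, d in tree:
        g.add_edge(u, v, weight=d)

    parts = []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        root = sorted(comp)[0]

        def render(node, parent):
            children = [c for c in sorted(g[node]) if c != parent]
            if not children:
                return node
            inner = ",".join(
                f"{render(c, node)}:{g[node][c]['weight']:.6f}" for c in children
            )
            return f"({inner}){node}"

        parts.append(render(root, None) + ";")
    return "\n".join(parts)
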