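"""Clustering, partition agreement, consensus communities, enrichment."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import hypergeom

from oads.communities import (
    CommunityPartition,
    adjusted_rand_index,
    bh_adjust,
    feature_enrichment,
    kendall_consistency,
    leiden_clusters,
    robust_communities,
    ward_clusters,
)
from oads.errors import ContractError
from oads.network import DiseaseNetwork
from oads.similarity import SimilarityMatrix


def _block_sim(labels, within=0.9, between=0.1, noise=0.0, rng=None):
    labels = np.asarray(labels)
    n = len(labels)
    s = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if noise and rng is not None:
        s = s + rng.normal(0, noise, (n, n))
    s = np.clip((s + s.T) / 2, 0.0, 1.0)
    np.fill_diagonal(s, 1.0)
    ids = [f"D{i:03d}" for i in range(n)]
    return SimilarityMatrix(ids, s), ids


def _partition(assignment, method="ward_hc"):
    return CommunityPartition(method=method, modality="t", assignment=assignment)


class TestWardClusters:
    def test_separable_blocks_recovered(self):
        labels = [0] * 5 + [1] * 5
        sim, ids = _block_sim(labels, within=1.0, between=0.0)
        part = ward_clusters(sim, 2)
        got = [part.assignment[d] for d in ids]
        assert len(set(got[:5])) == 1 and len(set(got[5:])) == 1
        assert got[0] != got[5]

    def test_noisy_three_blocks(self, rng):
        labels = np.repeat([0, 1, 2], 10)
        sim, ids = _block_sim(labels, within=0.8, between=0.2, noise=0.05, rng=rng)
        part = ward_clusters(sim, 3)
        ari = adjusted_rand_index(
            part, _partition({d: int(l) for d, l in zip(ids, labels)})
        )
        assert ari >= 0.9

    def test_row_order_permutation_preserves_partition(self, rng):
        labels = np.repeat([0, 1], 8)
        sim, ids = _block_sim(labels, within=0.85, between=0.15, noise=0.03, rng=rng)
        perm = rng.permutation(len(ids))
        sim2 = SimilarityMatrix(
            [ids[i] for i in perm], sim.scores[np.ix_(perm, perm)]
        )
        p1 = ward_clusters(sim, 2)
        p2 = ward_clusters(sim2, 2)
        assert adjusted_rand_index(p1, p2) == 1.0


class TestLeidenClusters:
    def test_disconnected_cliques(self):
        g = nx.Graph()
        for base in (0, 10):
            for u, v in itertools.combinations(range(base, base + 5), 2):
                g.add_edge(f"D{u}", f"D{v}", similarity=1.0)
        part = leiden_clusters(DiseaseNetwork(graph=g), seed=1)
        assert part.n_clusters == 2

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(12)
        labels = {f"D{i:02d}": i // 10 for i in range(40)}
        g = nx.Graph()
        g.add_nodes_from(labels)
        for u, v in itertools.combinations(sorted(labels), 2):
            p = 0.6 if labels[u] == labels[v] else 0.02
            if rng.random() < p:
                g.add_edge(u, v, similarity=1.0)
        part = leiden_clusters(DiseaseNetwork(graph=g), seed=7)
        ari = adjusted_rand_index(part, _partition(labels))
        assert ari >= 0.9

    def test_resolution_never_decreases_cluster_count(self):
        rng = np.random.default_rng(12)
        labels = {f"D{i:02d}": i // 10 for i in range(40)}
        g = nx.Graph()
        for u, v in itertools.combinations(sorted(labels), 2):
            p = 0.6 if labels[u] == labels[v] else 0.05
            if rng.random() < p:
                g.add_edge(u, v, similarity=1.0)
        net = DiseaseNetwork(graph=g)
        counts = [
            leiden_clusters(net, resolution=r, seed=3).n_clusters
            for r in (0.3, 0.6, 1.0, 2.0, 4.0)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_empty_graph_rejected(self):
        with pytest.raises(ContractError):
            leiden_clusters(DiseaseNetwork(graph=nx.Graph()))


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        p = _partition({"a": 0, "b": 0, "c": 1})
        assert adjusted_rand_index(p, p) == 1.0

    def test_hand_contingency_case(self):
        p1 = _partition({"a": 0, "b": 0, "c": 1, "d": 1})
        p2 = _partition({"a": 0, "b": 1, "c": 0, "d": 1})
        assert adjusted_rand_index(p1, p2) == pytest.approx(-0.5)

    def test_random_labelings_near_zero(self):
        rng = np.random.default_rng(0)
        items = [f"D{i}" for i in range(200)]
        vals = []
        for _ in range(100):
            a = _partition({d: int(v) for d, v in zip(items, rng.integers(5, size=200))})
            b = _partition({d: int(v) for d, v in zip(items, rng.integers(5, size=200))})
            vals.append(adjusted_rand_index(a, b))
        assert abs(np.mean(vals)) < 0.05

    def test_disjoint_sets_rejected(self):
        with pytest.raises(ContractError):
            adjusted_rand_index(_partition({"a": 0}), _partition({"b": 0}))


class TestKendallConsistency:
    def test_identical_and_reversed(self):
        r = {"m1": [1, 2, 3, 4], "m2": [1, 2, 3, 4], "m3": [4, 3, 2, 1]}
        taus = kendall_consistency(r)
        assert taus[("m1", "m2")] == 1.0
        assert taus[("m1", "m3")] == -1.0

    def test_single_swap(self):
        taus = kendall_consistency({"a": [1, 2, 3], "b": [1, 3, 2]})
        assert taus[("a", "b")] == pytest.approx(1 / 3)

    def test_too_short_rejected(self):
        with pytest.raises(ContractError):
            kendall_consistency({"a": [1], "b": [2]})


class TestRobustCommunities:
    def test_identical_partitions_return_large_clusters(self):
        assignment = {f"D{i}": i // 5 for i in range(12)}  # sizes 5, 5, 2
        parts = [_partition(assignment), _partition(dict(assignment))]
        robust = robust_communities(parts, min_size=4)
        assert sorted(len(c.members) for c in robust) == [5, 5]

    def test_split_block_shrinks_by_intersection(self):
        base = {f"D{i}": 0 for i in range(8)}
        split = {f"D{i}": (0 if i < 4 else 1) for i in range(8)}
        robust = robust_communities([_partition(base), _partition(split)], min_size=4)
        got = sorted(tuple(c.members) for c in robust)
        # brute-force co-membership: pairs agreeing in BOTH partitions
        expected = [
            tuple(sorted(f"D{i}" for i in range(4))),
            tuple(sorted(f"D{i}" for i in range(4, 8))),
        ]
        assert got == sorted(expected)

    def test_planted_stable_blocks_with_noise_diseases(self):
        blocks = {**{f"A{i}": 0 for i in range(6)},
                  **{f"B{i}": 1 for i in range(5)},
                  **{f"C{i}": 2 for i in range(4)}}
        noise = ["N0", "N1", "N2"]
        parts = []
        for k in range(4):
            a = dict(blocks)
            for j, d in enumerate(noise):  # noise diseases wander between runs
                a[d] = 10 + ((j + k) % 3)
            parts.append(_partition(a))
        robust = robust_communities(parts, min_size=4)
        assert sorted(len(c.members) for c in robust) == [4, 5, 6]
        assert all(not set(c.members) & set(noise) for c in robust)

    def test_order_invariance(self):
        a = {f"D{i}": i // 4 for i in range(16)}
        b = {f"D{i}": (i + 1) // 4 for i in range(16)}
        r1 = robust_communities([_partition(a), _partition(b)], min_size=2)
        r2 = robust_communities([_partition(b), _partition(a)], min_size=2)
        assert [c.members for c in r1] == [c.members for c in r2]

    def test_category_counts_sum_to_size(self):
        assignment = {f"D{i}": i // 4 for i in range(8)}
        cats = {f"D{i}": ("AD" if i % 2 else "AID") for i in range(8)}
        robust = robust_communities(
            [_partition(assignment), _partition(dict(assignment))],
            min_size=4,
            categories=cats,
        )
        for c in robust:
            assert sum(c.category_counts.values()) == c.size


class TestFeatureEnrichment:
    def _communities(self):
        from oads.communities import RobustCommunity

        return [
            RobustCommunity(1, [f"A{i}" for i in range(8)]),
            RobustCommunity(2, [f"B{i}" for i in range(61)]),
        ]

    def test_ubiquitous_feature_not_enriched(self):
        coms = self._communities()
        feats = {d: {"everywhere"} for c in coms for d in c.members}
        rows = feature_enrichment(coms, feats)
        assert all(r["p"] == 1.0 for r in rows)

    def test_fisher_matches_hypergeometric_enumeration(self):
        """[[7,1],[8,53]] one-sided p equals the exact hypergeometric tail."""
        coms = self._communities()
        feats = {}
        for i in range(7):
            feats[f"A{i}"] = {"aid"}
        for i in range(8):
            feats[f"B{i}"] = {"aid"}
        rows = feature_enrichment(coms, feats)
        row = next(r for r in rows if r["community_id"] == 1 and r["feature"] == "aid")
        assert (row["a"], row["b"], row["c"], row["d"]) == (7, 1, 8, 53)
        expected = sum(hypergeom.pmf(k, 69, 15, 8) for k in (7, 8))
        assert row["p"] == pytest.approx(expected, abs=1e-12)

    def test_bh_step_up_hand_case(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])
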