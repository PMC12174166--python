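"""FunSimAvg aggregation and disease-level similarity matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oads.errors import ContractError
from oads.profiles import AnnotationProfile
from oads.similarity import (
    dc_weighted_oads,
    drug_based_similarity,
    funsim_avg,
    pairwise_oads,
    tanimoto,
)


def _lookup(sims: dict) -> callable:
    def f(a, b):
        if a == b:
            return 1.0
        return sims.get((a, b), sims.get((b, a), 0.0))

    return f


class TestFunSimAvg:
    def test_identical_sets_identity_termsim(self):
        t = [("a", 1.0), ("b", 1.0)]
        assert funsim_avg(t, t, _lookup({})) == 1.0

    def test_hand_bma(self):
        f = _lookup({("a", "b"): 0.5, ("a", "c"): 0.9})
        got = funsim_avg([("a", 1.0)], [("b", 1.0), ("c", 1.0)], f)
        assert got == pytest.approx(0.5 * (0.9 + (0.5 + 0.9) / 2), abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ContractError):
            funsim_avg([], [("a", 1.0)], _lookup({}))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 6, size=2)
        terms = [f"t{i}" for i in range(10)]
        sims = {
            (a, b): float(rng.random())
            for i, a in enumerate(terms)
            for b in terms[i + 1 :]
        }
        f = _lookup(sims)
        t1 = [(terms[i], float(rng.random())) for i in rng.choice(10, n1, replace=False)]
        t2 = [(terms[i], float(rng.random())) for i in rng.choice(10, n2, replace=False)]
        for weighted in (False, True):
            a = funsim_avg(t1, t2, f, weighted=weighted)
            b = funsim_avg(t2, t1, f, weighted=weighted)
            assert a == pytest.approx(b, abs=1e-12)
            assert 0.0 <= a <= 1.0


def _random_profiles(dag, rng, n=10, modality="genetic", weights=None):
    terms = sorted(dag.terms)
    out = []
    for i in range(n):
        k = int(rng.integers(3, 8))
        pick = sorted(terms[j] for j in rng.choice(len(terms), size=k, replace=False))
        w = weights(rng, k) if weights else [1.0] * k
        out.append(AnnotationProfile(f"D{i:02d}", modality, list(zip(pick, w))))
    return out


class TestPairwiseOads:
    def test_identical_profiles_score_one(self, random_dag):
        terms = sorted(random_dag.terms)[:5]
        p = [
            AnnotationProfile("a", "genetic", [(t, 1.0) for t in terms]),
            AnnotationProfile("b", "genetic", [(t, 1.0) for t in terms]),
        ]
        sim = pairwise_oads(p, random_dag)
        assert sim.scores[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matrix_equals_bruteforce(self, random_dag, rng):
        from oads.ontology import wang_similarity

        profiles = _random_profiles(random_dag, rng)
        sim = pairwise_oads(profiles, random_dag)
        f = lambda a, b: wang_similarity(random_dag, a, b)
        for i, pi in enumerate(profiles):
            for j, pj in enumerate(profiles):
                if i < j:
                    expected = funsim_avg(pi.terms, pj.terms, f)
                    assert abs(sim.scores[i, j] - expected) < 1e-12

    def test_empty_profiles_excluded(self, random_dag):
        terms = sorted(random_dag.terms)[:4]
        p = [
            AnnotationProfile("a", "genetic", [(t, 1.0) for t in terms]),
            AnnotationProfile("b", "genetic", []),
            AnnotationProfile("c", "genetic", [(t, 1.0) for t in terms[:2]]),
        ]
        sim = pairwise_oads(p, random_dag)
        assert sim.disease_ids == ["a", "c"]

    def test_root_only_overlap_is_positive(self):
        """Terms sharing only the ontology root still yield a positive score."""
        from oads.ontology import OntologyDAG, OntologyTerm

        dag = OntologyDAG(
            [
                OntologyTerm("R"),
                OntologyTerm("A", parents=[("R", "is_a")]),
                OntologyTerm("B", parents=[("R", "is_a")]),
                OntologyTerm("a1", parents=[("A", "is_a")]),
                OntologyTerm("b1", parents=[("B", "is_a")]),
            ]
        )
        p = [
            AnnotationProfile("a", "genetic", [("a1", 1.0)]),
            AnnotationProfile("b", "genetic", [("b1", 1.0)]),
        ]
        sim = pairwise_oads(p, dag)
        # only the root is shared: S-value 0.64 on each side
        expected = (0.64 + 0.64) / (2.44 + 2.44)
        assert sim.scores[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_mixed_modalities_rejected(self, random_dag):
        terms = sorted(random_dag.terms)[:2]
        p = [
            AnnotationProfile("a", "genetic", [(terms[0], 1.0)]),
            AnnotationProfile("b", "phenotypic", [(terms[1], 1.0)]),
        ]
        with pytest.raises(ContractError):
            pairwise_oads(p, random_dag)


class TestDcWeightedOads:
    def test_uniform_weights_reduce_to_unweighted(self, random_dag, rng):
        profiles = _random_profiles(random_dag, rng, modality="transcriptomic")
        unweighted = pairwise_oads(profiles, random_dag)
        weighted = dc_weighted_oads(profiles, random_dag)
        assert np.abs(weighted.scores - unweighted.scores).max() < 1e-12

    def test_scale_invariance_of_one_disease(self, random_dag, rng):
        mk = lambda r, k: [float(v) for v in r.random(k)]
        profiles = _random_profiles(
            random_dag, rng, n=4, modality="transcriptomic", weights=mk
        )
        base = dc_weighted_oads(profiles, random_dag)
        halved = [
            AnnotationProfile(
                profiles[0].disease_id,
                "transcriptomic",
                [(t, w / 2) for t, w in profiles[0].terms],
            )
        ] + profiles[1:]
        again = dc_weighted_oads(halved, random_dag)
        assert np.abs(base.scores - again.scores).max() < 1e-12

    def test_zero_weight_terms_do_not_contribute(self, random_dag):
        terms = sorted(random_dag.terms)
        t_far = terms[-1]
        shared = terms[:3]
        p1 = AnnotationProfile(
            "a", "transcriptomic", [(t, 1.0) for t in shared] + [(t_far, 0.0)]
        )
        p1_clean = AnnotationProfile("a", "transcriptomic", [(t, 1.0) for t in shared])
        p2 = AnnotationProfile("b", "transcriptomic", [(t, 1.0) for t in shared])
        with_zero = dc_weighted_oads([p1, p2], random_dag).scores[0, 1]
        without = dc_weighted_oads([p1_clean, p2], random_dag).scores[0, 1]
        # the zero-weight term drops out of a's outer mean; b's direction is
        # unaffected because its best matches stay within the shared terms
        assert with_zero == pytest.approx(without, abs=1e-12)


class TestTanimoto:
    def test_identity_and_disjoint(self):
        assert tanimoto({1, 2}, {1, 2}) == 1.0
        assert tanimoto({1}, {2}) == 0.0

    def test_enumeration(self):
        assert tanimoto({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_both_empty_rejected(self):
        with pytest.raises(ContractError):
            tanimoto(set(), set())

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.sets(st.integers(0, 63)), st.sets(st.integers(0, 63)))
    def test_bounds_and_symmetry(self, a, b):
        if not a and not b:
            return
        assert 0.0 <= tanimoto(a, b) == tanimoto(b, a) <= 1.0


class TestDrugBasedSimilarity:
    def test_identical_drug_sets_score_one(self):
        fps = {"x": {1, 2}, "y": {3, 4}}
        sim = drug_based_similarity({"d1": ["x", "y"], "d2": ["x", "y"]}, fingerprints=fps)
        assert sim.scores[0, 1] == 1.0

    def test_hand_bma_via_matrix(self):
        import pandas as pd

        ds = pd.DataFrame(
            [[1.0, 0.2, 0.6], [0.2, 1.0, 0.1], [0.6, 0.1, 1.0]],
            index=["x", "y", "z"],
            columns=["x", "y", "z"],
        )
        sim = drug_based_similarity({"d1": ["x"], "d2": ["y", "z"]}, drug_sim=ds)
        assert sim.scores[0, 1] == pytest.approx(0.5 * (0.6 + (0.2 + 0.6) / 2))

    def test_matrix_equals_bruteforce(self, rng):
        drugs = [f"dr{i}" for i in range(8)]
        fps = {d: set(map(int, rng.choice(32, size=6, replace=False))) for d in drugs}
        assignment = {
            f"d{i}": [drugs[j] for j in rng.choice(8, size=int(rng.integers(1, 4)), replace=False)]
            for i in range(6)
        }
        sim = drug_based_similarity(assignment, fingerprints=fps)
        f = lambda a, b: 1.0 if a == b else tanimoto(fps[a], fps[b])
        ids = sim.disease_ids
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    expected = funsim_avg(
                        [(x, 1.0) for x in assignment[a]],
                        [(x, 1.0) for x in assignment[b]],
                        f,
                    )
                    assert sim.scores[i, j] == pytest.approx(expected, abs=1e-12)


class TestModalityDistributionShift:
    def test_transcriptomic_above_phenotypic_above_genetic(self, default_scenario_data):
        """Tighter per-modality term pools push mean similarity upward."""
        profiles, _, dag = default_scenario_data
        mean_gen = pairwise_oads(profiles["genetic"], dag).upper_triangle().mean()
        mean_phe = pairwise_oads(profiles["phenotypic"], dag).upper_triangle().mean()
        mean_trans = dc_weighted_oads(profiles["transcriptomic"], dag).upper_triangle().mean()
        assert mean_trans > mean_phe > mean_gen
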