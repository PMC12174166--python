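"""Ontology-aware disease similarity (OADS).

Two diseases are compared through their annotation profiles with the
best-match-average (FunSimAvg) aggregation: every term of one disease is
matched to its most similar term in the other, the best matches are averaged
in both directions, and the two directional means are averaged. Term-level
similarity comes from the Wang method on the ontology DAG; variants weight
terms by differential co-expression magnitude (transcriptomic), cell-type
proportion (cellular), or replace term similarity with drug-structure
Tanimoto similarity (drug modality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, LookupError_, ValidationError
from .ontology import OntologyDAG, term_similarity_matrix
from .profiles import AnnotationProfile

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Symmetric disease-by-disease similarity with optional empirical p-values."""

    disease_ids: list[str]
    scores: np.ndarray
    pvalues: np.ndarray | None = None
    modality: str = ""

    def __post_init__(self):
        n = len(self.disease_ids)
        if self.scores.shape != (n, n):
            raise ContractError("score matrix shape does not match disease list")
        if not np.allclose(self.scores, self.scores.T, atol=1e-12):
            raise ValidationError("similarity matrix must be symmetric")
        if self.pvalues is not None and self.pvalues.shape != (n, n):
            raise ContractError("p-value matrix shape does not match disease list")

    def index_of(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise LookupError_(f"unknown disease {disease_id!r}") from None

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.disease_ids), k=1)
        return self.scores[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.disease_ids, columns=self.disease_ids)


def _normalise_weights(w: np.ndarray) -> np.ndarray:
    """Min-max rescale profile weights to [0, 1]; constant vectors become ones."""
    if np.any(w < 0):
        raise ValidationError("negative profile weight")
    lo, hi = w.min(), w.max()
    if hi == lo:
        return np.ones_like(w)
    return (w - lo) / (hi - lo)


def _bma(S: np.ndarray, w1: np.ndarray | None = None, w2: np.ndarray | None = None,
         weight_mode: str = "geometric", weight_scope: str = "mean_only") -> float:
    """Best-match-average of a |T1| x |T2| term-similarity block.

    Unweighted: mean of row maxima and column maxima, averaged. Weighted:
    each entry is multiplied by a coupling g(w_t, w_u) of the two term
    weights before taking maxima (scope ``max_and_mean``), and the outer
    means become weight-weighted means.
    """
    if w1 is None and w2 is None:
        return 0.5 * (S.max(axis=1).mean() + S.max(axis=0).mean())
    w1 = np.ones(S.shape[0]) if w1 is None else _normalise_weights(np.asarray(w1, float))
    w2 = np.ones(S.shape[1]) if w2 is None else _normalise_weights(np.asarray(w2, float))
    if weight_scope == "max_and_mean":
        if weight_mode == "geometric":
            g = np.sqrt(np.outer(w1, w2))
        elif weight_mode == "arithmetic":
            g = 0.5 * (w1[:, None] + w2[None, :])
        else:
            raise ContractError(f"unknown weight_mode {weight_mode!r}")
        Sw = S * g
    elif weight_scope == "mean_only":
        Sw = S
    else:
        raise ContractError(f"unknown weight_scope {weight_scope!r}")
    s1 = w1.sum() or 1.0
    s2 = w2.sum() or 1.0
    row = float(Sw.max(axis=1) @ w1) / s1
    col = float(Sw.max(axis=0) @ w2) / s2
    return 0.5 * (row + col)


def funsim_avg(
    t1: list[tuple[str, float]],
    t2: list[tuple[str, float]],
    termsim,
    weighted: bool = False,
    weight_mode: str = "geometric",
    weight_scope: str = "mean_only",
) -> float:
    """FunSimAvg score between two weighted term sets.

    ``termsim`` is a callable (term, term) -> similarity in [0, 1]. With
    ``weighted=True``, per-set weights are min-max normalised to [0, 1]
    (a uniform weight vector reduces exactly to the unweighted score) and the
    two directional means become weight-weighted means; ``weight_scope=
    "max_and_mean"`` additionally couples term-pair similarity with
    g(w_t, w_u) inside the max operator.
    """
    if not t1 or not t2:
        raise ContractError("term sets must be non-empty")
    S = np.array([[termsim(a, b) for b, _ in t2] for a, _ in t1], dtype=float)
    if not weighted:
        return _bma(S)
    return _bma(
        S,
        np.array([w for _, w in t1]),
        np.array([w for _, w in t2]),
        weight_mode=weight_mode,
        weight_scope=weight_scope,
    )


def _profile_blocks(profiles: list[AnnotationProfile], dag: OntologyDAG):
    """Shared term-similarity matrix plus per-profile index/weight arrays."""
    union: list[str] = []
    pos: dict[str, int] = {}
    for p in profiles:
        for t in p.term_ids:
            if t not in pos:
                pos[t] = len(union)
                union.append(t)
    S = term_similarity_matrix(dag, union, union)
    idx = [np.array([pos[t] for t in p.term_ids], dtype=int) for p in profiles]
    wts = [p.weights for p in profiles]
    return S, idx, wts


def pairwise_oads(
    profiles: list[AnnotationProfile],
    dag: OntologyDAG,
    weighted: bool = False,
    weight_mode: str = "geometric",
    weight_scope: str = "mean_only",
    modality: str | None = None,
) -> SimilarityMatrix:
    """All-pairs FunSimAvg over Wang term similarity for one modality.

    Diseases with empty profiles are excluded (and logged); at least two
    usable profiles are required. The result is symmetric with unit diagonal.
    """
    mods = {p.modality for p in profiles}
    if len(mods) > 1:
        raise ContractError(f"mixed modalities: {sorted(mods)}")
    usable = [p for p in profiles if len(p) > 0]
    dropped = [p.disease_id for p in profiles if len(p) == 0]
    if dropped:
        logger.info("excluding %d empty profiles: %s", len(dropped), dropped[:5])
    if len(usable) < 2:
        raise ContractError("need at least 2 non-empty profiles")

    S, idx, wts = _profile_blocks(usable, dag)
    n = len(usable)
    out = np.eye(n)
    for i in range(n):
        Si = S[idx[i]]
        for j in range(i + 1, n):
            block = Si[:, idx[j]]
            if weighted:
                out[i, j] = out[j, i] = _bma(
                    block, wts[i], wts[j], weight_mode=weight_mode, weight_scope=weight_scope
                )
            else:
                out[i, j] = out[j, i] = _bma(block)
    return SimilarityMatrix(
        disease_ids=[p.disease_id for p in usable],
        scores=out,
        modality=modality or (usable[0].modality if usable else ""),
    )


def dc_weighted_oads(
    profiles: list[AnnotationProfile],
    dag: OntologyDAG,
    weight_mode: str = "geometric",
    weight_scope: str = "mean_only",
) -> SimilarityMatrix:
    """Transcriptomic OADS with dC-magnitude term weighting.

    Profile weights must be the [0, 1]-rescaled dysregulation magnitudes
    (see :func:`oads.profiles.rescale_dc_weights`); with all weights equal the
    result coincides with the unweighted :func:`pairwise_oads`.
    """
    for p in profiles:
        if len(p) and np.any(p.weights < 0):
            raise ValidationError(f"negative dC weight in profile {p.disease_id}")
    return pairwise_oads(
        profiles, dag, weighted=True, weight_mode=weight_mode, weight_scope=weight_scope
    )


def tanimoto(a: set, b: set) -> float:
    """Tanimoto coefficient |a ∩ b| / |a ∪ b| between fingerprint bit sets."""
    if not a and not b:
        raise ContractError("both fingerprints empty")
    union = len(a | b)
    return len(a & b) / union


def drug_based_similarity(
    disease_drugs: dict[str, list[str]],
    fingerprints: dict[str, set] | None = None,
    drug_sim: pd.DataFrame | None = None,
) -> SimilarityMatrix:
    """Drug-profile disease similarity: FunSimAvg over drug-drug similarity.

    Drug-drug similarity is Tanimoto on ``fingerprints`` bit sets, or looked
    up in a precomputed ``drug_sim`` matrix (exactly one must be given).
    """
    if (fingerprints is None) == (drug_sim is None):
        raise ContractError("provide exactly one of fingerprints or drug_sim")
    for did, drugs in disease_drugs.items():
        if not drugs:
            raise ContractError(f"disease {did!r} has no drugs")
        for d in drugs:
            if fingerprints is not None and d not in fingerprints:
                raise LookupError_(f"no fingerprint for drug {d!r}")
            if drug_sim is not None and d not in drug_sim.index:
                raise LookupError_(f"drug {d!r} absent from similarity matrix")

    if fingerprints is not None:
        def sim(x, y):
            return 1.0 if x == y else tanimoto(fingerprints[x], fingerprints[y])
    else:
        def sim(x, y):
            return float(drug_sim.loc[x, y])

    ids = sorted(disease_drugs)
    n = len(ids)
    out = np.eye(n)
    sets = {d: [(x, 1.0) for x in disease_drugs[d]] for d in ids}
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = funsim_avg(sets[ids[i]], sets[ids[j]], sim)
    return SimilarityMatrix(disease_ids=ids, scores=out, modality="drug")
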