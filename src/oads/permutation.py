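"""Permutation null model for disease similarity.

Significance of an observed disease-disease similarity is assessed against a
null built by shuffling the disease-term bipartite assignment: all (term,
weight) slots are pooled across diseases and re-dealt, so every disease keeps
its term count and the global multiset of term occurrences is preserved.
Similarities are recomputed on each shuffled dataset; empirical p-values use
the add-one (Phipson-Smyth) estimator so that p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .profiles import AnnotationProfile
from .similarity import SimilarityMatrix


@dataclass
class PermutationConfig:
    n_permutations: int = 500
    seed: int = 0
    preserve: str = "term_counts_and_distribution"

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ContractError("n_permutations must be >= 1")


def shuffle_annotations(
    profiles: list[AnnotationProfile], seed: int | np.random.Generator
) -> list[AnnotationProfile]:
    """One bipartite shuffle of disease-term assignments.

    Pools every profile's (term, weight) slots, permutes the pool, and deals
    the slots back so each disease retains its original term count. Duplicate
    terms landing in one disease are repaired by swapping the offending slot
    with a compatible slot of another disease, so both the per-disease counts
    and the global term multiset are conserved exactly.
    """
    if len(profiles) < 2:
        raise ContractError("need at least 2 profiles to shuffle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = [slot for p in profiles for slot in p.terms]
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]

    chunks: list[list[tuple[str, float]]] = []
    start = 0
    for p in profiles:
        chunks.append(pool[start : start + len(p)])
        start += len(p)
    held = [set(t for t, _ in c) for c in chunks]

    for i, chunk in enumerate(chunks):
        seen: set[str] = set()
        for idx, (term, w) in enumerate(chunk):
            if term not in seen:
                seen.add(term)
                continue
            # duplicate: swap this slot with another disease's slot whose term
            # we do not hold and which does not already hold ours
            placed = False
            for j in rng.permutation(len(chunks)):
                if j == i or term in held[j]:
                    continue
                for idx2, (term2, w2) in enumerate(chunks[j]):
                    if term2 not in seen and term2 != term:
                        chunks[i][idx] = (term2, w2)
                        chunks[j][idx2] = (term, w)
                        held[j] = {t for t, _ in chunks[j]}
                        seen.add(term2)
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                raise ContractError(
                    f"cannot shuffle: term {term!r} occurs more often than "
                    "there are diseases able to hold it"
                )
        held[i] = seen

    return [
        AnnotationProfile(p.disease_id, p.modality, list(chunk))
        for p, chunk in zip(profiles, chunks)
    ]


def empirical_pvalues(
    observed: SimilarityMatrix,
    profiles: list[AnnotationProfile],
    null_fn,
    config: PermutationConfig,
) -> np.ndarray:
    """Empirical p-value matrix for every disease pair.

    ``null_fn`` maps a shuffled profile list to a :class:`SimilarityMatrix`
    over the same diseases (one shared permutation stream scores all pairs on
    each shuffled dataset). p(i,j) = (1 + #{null >= observed}) / (1 + N).
    """
    if config.n_permutations < 1:
        raise ContractError("n_permutations must be >= 1")
    rng = np.random.default_rng(config.seed)
    n = len(observed.disease_ids)
    obs = observed.scores
    exceed = np.zeros((n, n))
    order = {d: i for i, d in enumerate(observed.disease_ids)}
    for _ in range(config.n_permutations):
        null = null_fn(shuffle_annotations(profiles, rng))
        perm = [order[d] for d in null.disease_ids]
        ns = np.full((n, n), -np.inf)
        ns[np.ix_(perm, perm)] = null.scores
        exceed += ns >= obs - 1e-12
    p = (1.0 + exceed) / (1.0 + config.n_permutations)
    np.fill_diagonal(p, 1.0 / (1.0 + config.n_permutations))
    return np.minimum(p, 1.0)
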