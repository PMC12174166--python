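"""Per-disease annotation profiles across data modalities.

A profile is a disease's weighted set of ontology terms in one modality:
GO terms from genetically associated genes (weight 1), GO terms from
dysregulated genes weighted by differential co-expression magnitude, HPO
phenotype terms (weight 1), Cell Ontology terms weighted by cell-type
proportions, or drugs treated as pseudo-terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, LookupError_, ValidationError

logger = logging.getLogger(__name__)

MODALITIES = ("genetic", "transcriptomic", "phenotypic", "cellular", "drug")


@dataclass
class AnnotationProfile:
    """A disease's weighted term set in one modality."""

    disease_id: str
    modality: str
    terms: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        ids = [t for t, _ in self.terms]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate term ids in profile {self.disease_id}")
        if any(w < 0 for _, w in self.terms):
            raise ValidationError(f"negative term weight in profile {self.disease_id}")

    @property
    def term_ids(self) -> list[str]:
        return [t for t, _ in self.terms]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.terms], dtype=float)

    def __len__(self) -> int:
        return len(self.terms)


def build_profile(
    disease_id: str,
    modality: str,
    raw: list[tuple[str, float]],
    mapping: dict[str, str | list[str]] | None = None,
    top_k: int | None = None,
) -> AnnotationProfile:
    """Map raw annotated items (genes, phenotypes, ...) to ontology terms.

    Items are translated through ``mapping`` (identity when None; an item may
    map to several terms). Duplicate terms keep the maximum weight. When
    ``top_k`` is set, only the ``top_k`` heaviest terms are retained
    (descending weight, ties broken by ascending term id).

    An empty result is returned (not raised) when nothing maps: downstream
    similarity computations exclude and report such diseases.
    """
    if modality not in MODALITIES:
        raise ContractError(f"unknown modality {modality!r}")
    merged: dict[str, float] = {}
    n_unmapped = 0
    for item, w in raw:
        if w < 0:
            raise ValidationError(f"negative weight for item {item!r}")
        if mapping is None:
            targets = [item]
        else:
            t = mapping.get(item)
            if t is None:
                n_unmapped += 1
                continue
            targets = t if isinstance(t, list) else [t]
        for term in targets:
            if term not in merged or w > merged[term]:
                merged[term] = w
    if n_unmapped:
        logger.debug("%s/%s: %d unmapped items", disease_id, modality, n_unmapped)
    if not merged:
        logger.info("%s/%s: empty profile (no mappable items)", disease_id, modality)
        return AnnotationProfile(disease_id, modality, [])
    items = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        items = items[:top_k]
    return AnnotationProfile(disease_id, modality, items)


def rescale_dc_weights(weights: dict[str, float]) -> dict[str, float]:
    """Map Z-score-normalised dC values to [0, 1] dysregulation magnitudes.

    Takes absolute values (direction of dysregulation is discarded) then
    min-max rescales per disease; a constant vector maps to all ones.
    """
    mags = {k: abs(v) for k, v in weights.items()}
    lo, hi = min(mags.values()), max(mags.values())
    if hi == lo:
        return {k: 1.0 for k in mags}
    return {k: (v - lo) / (hi - lo) for k, v in mags.items()}


def cell_proportion_profile(
    disease_id: str,
    counts: dict[str, float],
    cl_ids: dict[str, str] | None = None,
) -> AnnotationProfile:
    """Build a cellular profile from per-cell-type counts.

    Counts are normalised to proportions summing to 1 and mapped to Cell
    Ontology ids through ``cl_ids`` (identity when None).
    """
    if any(c < 0 for c in counts.values()):
        raise ValidationError("cell counts must be non-negative")
    total = float(sum(counts.values()))
    if total <= 0:
        raise ContractError("all-zero cell counts")
    terms: dict[str, float] = {}
    for ct, c in counts.items():
        if cl_ids is not None:
            if ct not in cl_ids:
                raise LookupError_(f"no Cell Ontology id for cell type {ct!r}")
            term = cl_ids[ct]
        else:
            term = ct
        terms[term] = terms.get(term, 0.0) + c / total
    items = sorted(terms.items(), key=lambda kv: (-kv[1], kv[0]))
    return AnnotationProfile(disease_id, "cellular", items)


def cell_consistency_ratio(
    p1: dict[str, float], p2: dict[str, float], cell_type: str
) -> float:
    """Fold-consistency of one cell type's proportion between two diseases.

    Returns max(p1, p2) / min(p1, p2), always >= 1; values near 1 mark the
    most consistent cell types between the diseases.
    """
    if cell_type not in p1 or cell_type not in p2:
        raise LookupError_(f"cell type {cell_type!r} absent from a profile")
    a, b = p1[cell_type], p2[cell_type]
    if min(a, b) <= 0:
        raise ContractError(f"zero proportion for {cell_type!r}")
    return max(a, b) / min(a, b)


def cell_consistency_ranking(
    p1: dict[str, float], p2: dict[str, float]
) -> list[tuple[str, float]]:
    """Cell types shared by both diseases, ranked most-consistent first."""
    shared = [ct for ct in p1 if ct in p2 and p1[ct] > 0 and p2[ct] > 0]
    ratios = [(ct, cell_consistency_ratio(p1, p2, ct)) for ct in shared]
    return sorted(ratios, key=lambda kv: (kv[1], kv[0]))
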