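"""Multi-source disease classification repository.

Autoimmune (AD) and autoinflammatory (AID) disease labels disagree across
classification systems (Mondo, DO, MeSH, ICD, expert panels, patient-advocacy
knowledge bases). This module integrates per-source labels into one record per
disease and scores the agreement:

* ACS — the signed label count: +1 per source calling the disease AD, −1 per
  source calling it AID.
* ACS_norm — a confidence-weighted version on [−1, +1]:
  sum_i(w_i * s_i) / sum_i(w_i) with s_i in {+1, 0, −1} and w_i the source's
  confidence weight.
* Category — CA (contested) when both polarities appear anywhere; else AD
  (ACS >= 1) or AID (ACS <= −1); else AA when the disease carries the HPO
  "autoimmunity" phenotype (HP:0002960) without an explicit label.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Default per-source confidence weights (coverage / update frequency / endorsement).
DEFAULT_SOURCE_WEIGHTS = {
    "Mondo": 1.0,
    "DO": 0.8,
    "MeSH": 0.7,
    "ICD": 0.7,
    "expert": 1.0,
    "AA": 1.0,
    "ARI": 1.0,
    "GAI": 1.0,
}

AD, AID, CA, AA, UNCLASSIFIED = "AD", "AID", "CA", "AA", "unclassified"


@dataclass
class ClassificationSource:
    source_name: str
    weight: float

    def __post_init__(self):
        if self.weight <= 0:
            raise ValidationError(f"source weight must be > 0, got {self.weight}")


@dataclass
class DiseaseRecord:
    """One disease with its per-source labels and derived scores."""

    disease_id: str
    labels: list[tuple[str, str]] = field(default_factory=list)  # (source, AD|AID)
    has_autoimmunity_phenotype: bool = False
    acs: int | None = None
    acs_norm: float | None = None
    category: str | None = None


def compute_acs(record: DiseaseRecord) -> int:
    """Signed label count: +1 per AD label, −1 per AID label."""
    seen = Counter(record.labels)
    dupes = [k for k, v in seen.items() if v > 1]
    if dupes:
        raise ValidationError(f"duplicate (source,label) pairs for {record.disease_id}: {dupes}")
    for _, lab in record.labels:
        if lab not in (AD, AID):
            raise ValidationError(f"label must be AD or AID, got {lab!r}")
    return sum(1 if lab == AD else -1 for _, lab in record.labels)


def compute_acs_norm(
    record: DiseaseRecord,
    sources: dict[str, float] | None = None,
    covering_sources: set[str] | None = None,
) -> float:
    """Confidence-weighted classification score on [−1, +1].

    Each labeled source contributes s_i = +1 (AD) or −1 (AID) with its weight.
    Sources in ``covering_sources`` that mention the disease without an AD/AID
    label contribute s_i = 0 with their weight in the denominator; sources
    not covering the disease at all are excluded.
    """
    weights = dict(sources or DEFAULT_SOURCE_WEIGHTS)
    num = 0.0
    den = 0.0
    labeled = set()
    for src, lab in record.labels:
        if src not in weights:
            raise ConfigurationError(f"no weight configured for source {src!r}")
        s = 1.0 if lab == AD else -1.0
        num += weights[src] * s
        den += weights[src]
        labeled.add(src)
    for src in covering_sources or ():
        if src in labeled:
            continue
        if src not in weights:
            raise ConfigurationError(f"no weight configured for source {src!r}")
        den += weights[src]  # s_i = 0
    if den == 0:
        return 0.0
    return num / den


def assign_category(record: DiseaseRecord) -> str:
    """Categorise a record as CA, AD, AID, AA or unclassified.

    Contested (CA) takes precedence: both polarities present across any
    sources (including within one source). Otherwise the binary ACS decides
    AD (>= 1) / AID (<= −1); label-free diseases flagged with the autoimmunity
    phenotype become AA.
    """
    pols = {lab for _, lab in record.labels}
    if AD in pols and AID in pols:
        return CA
    if record.acs is None:
        record.acs = compute_acs(record)
    if record.acs >= 1:
        return AD
    if record.acs <= -1:
        return AID
    if record.has_autoimmunity_phenotype and not record.labels:
        return AA
    return UNCLASSIFIED


def integrate_sources(
    tables: pd.DataFrame | list[pd.DataFrame],
    phenotype_flags: set[str] | None = None,
    source_weights: dict[str, float] | None = None,
) -> tuple[dict[str, DiseaseRecord], dict]:
    """Merge per-source label tables into one record per disease.

    Parameters
    ----------
    tables
        DataFrame(s) with columns ``disease_id``, ``source``, ``label``
        (label in {AD, AID}). Exact duplicate rows are logged and dropped.
    phenotype_flags
        Disease ids carrying the HPO autoimmunity phenotype.
    source_weights
        Source confidence weights for ACS_norm (defaults to the standard map).

    Returns
    -------
    (records, summary)
        Records keyed by disease id; summary holds per-category counts and,
        per AD/AID category, the fraction of diseases with \\|ACS\\| = 1
        (i.e. recognised by a single classification system).
    """
    if isinstance(tables, list):
        df = pd.concat(tables, ignore_index=True)
    else:
        df = tables.copy()
    n0 = len(df)
    df = df.drop_duplicates(subset=["disease_id", "source", "label"])
    if len(df) < n0:
        logger.info("dropped %d duplicate label rows", n0 - len(df))

    flags = set(phenotype_flags or ())
    records: dict[str, DiseaseRecord] = {}
    for did, grp in df.groupby("disease_id", sort=True):
        rec = DiseaseRecord(
            disease_id=did,
            labels=list(zip(grp["source"], grp["label"])),
            has_autoimmunity_phenotype=did in flags,
        )
        rec.acs = compute_acs(rec)
        rec.acs_norm = compute_acs_norm(rec, source_weights)
        rec.category = assign_category(rec)
        records[did] = rec
    # phenotype-flagged diseases never labeled by any source
    for did in sorted(flags - set(records)):
        rec = DiseaseRecord(disease_id=did, has_autoimmunity_phenotype=True)
        rec.acs = 0
        rec.acs_norm = 0.0
        rec.category = AA
        records[did] = rec

    counts = Counter(r.category for r in records.values())
    single_source = {}
    for cat in (AD, AID):
        members = [r for r in records.values() if r.category == cat]
        if members:
            single_source[cat] = sum(abs(r.acs) == 1 for r in members) / len(members)
    summary = {
        "n_diseases": len(records),
        "category_counts": dict(counts),
        "single_source_fraction": single_source,
        "n_phenotype_flagged": len(flags),
        "n_flagged_already_labeled": len(flags & set(df["disease_id"])),
    }
    return records, summary
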