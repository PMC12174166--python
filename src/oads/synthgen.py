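"""Synthetic data generator with planted community structure.

Emulates the structure (not the content) of the real inputs the pipeline
consumes: a rooted ontology DAG, per-disease weighted term sets per modality,
per-disease cell-type proportion vectors, and multi-source AD/AID
classification labels. Disease communities are planted by sampling each
community's terms from one ontology subtree, so that hierarchical (Wang)
similarity — not mere term overlap — separates communities. Transcriptomic
term weights are half-normal dysregulation magnitudes standing in for
Z-score-normalised differential co-expression (dC) values.

Per-modality term pools differ in tightness (transcriptomic tightest,
genetic loosest), which reproduces the qualitative ordering of mean
similarity across modalities: transcriptomic > phenotypic > genetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .ontology import OntologyDAG, OntologyTerm
from .profiles import AnnotationProfile, rescale_dc_weights

#: Fraction of a community's term pool each modality samples from.
POOL_FRACTION = {"transcriptomic": 0.35, "phenotypic": 0.6, "genetic": 1.0}

#: The seven classification systems emulated (four mainstream, three specialised).
LABEL_SOURCES = ("Mondo", "DO", "MeSH", "ICD", "AA", "ARI", "GAI")


@dataclass
class SyntheticScenario:
    seed: int = 0
    n_terms: int = 200
    n_diseases: int = 100
    k_communities: int = 5
    terms_per_disease: int = 8
    pool_overlap: float = 0.2
    noise: float = 0.05
    modalities: tuple = ("genetic", "transcriptomic", "phenotypic")
    source_agreement: float = 0.8
    max_parents: int = 2
    n_cell_types_per_branch: int = 3
    p_autoimmune: float = 0.8  # prior that a disease's true polarity is AD

    def __post_init__(self):
        for name in ("pool_overlap", "noise", "source_agreement"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ContractError(f"{name} must lie in [0, 1], got {v}")
        if self.k_communities > self.n_diseases:
            raise ContractError("k_communities cannot exceed n_diseases")


def _term_id(i: int) -> str:
    return f"SYN:{i:07d}"


def gen_branched_ontology(
    n_terms: int, max_parents: int = 2, seed: int = 0, n_branches: int = 1
) -> tuple[OntologyDAG, list[list[str]]]:
    """Single-rooted random DAG with ``n_branches`` disjoint subtrees.

    Term 0 is the root; the next ``n_branches`` terms are branch anchors
    (children of the root); every later term attaches to 1..max_parents
    earlier terms of its branch, guaranteeing acyclicity by construction.
    Returns the DAG and the per-branch term lists (anchors included).
    """
    if n_terms < 2:
        raise ContractError("need at least 2 terms")
    if max_parents < 1:
        raise ContractError("max_parents must be >= 1")
    if n_terms < n_branches + 1:
        raise ContractError("n_terms too small for the requested branches")
    rng = np.random.default_rng(seed)
    root = _term_id(0)
    terms = {root: OntologyTerm(root, name="root")}
    branches: list[list[str]] = [[] for _ in range(n_branches)]
    for b in range(n_branches):
        tid = _term_id(1 + b)
        terms[tid] = OntologyTerm(tid, name=f"branch_{b}", parents=[(root, "is_a")])
        branches[b].append(tid)
    for i in range(1 + n_branches, n_terms):
        b = int(rng.integers(n_branches))
        pool = branches[b]
        n_par = 1 + int(rng.integers(min(max_parents, len(pool))))
        idx = rng.choice(len(pool), size=min(n_par, len(pool)), replace=False)
        parents = [(pool[int(j)], "is_a") for j in sorted(idx)]
        tid = _term_id(i)
        terms[tid] = OntologyTerm(tid, name=f"term_{i}", parents=parents)
        branches[b].append(tid)
    return OntologyDAG(terms), branches


def gen_ontology(n_terms: int, max_parents: int = 2, seed: int = 0) -> OntologyDAG:
    """Single-rooted random ontology DAG (see :func:`gen_branched_ontology`)."""
    dag, _ = gen_branched_ontology(n_terms, max_parents=max_parents, seed=seed)
    return dag


def _community_pools(
    branches: list[list[str]], overlap: float, rng: np.random.Generator
) -> list[list[str]]:
    """Per-community pools: own subtree, with a fraction swapped in from others."""
    pools = []
    k = len(branches)
    for c in range(k):
        pool = list(branches[c])
        n_swap = int(round(overlap * len(pool)))
        if n_swap and k > 1:
            others = [t for b in range(k) if b != c for t in branches[b]]
            repl_pos = rng.choice(len(pool), size=n_swap, replace=False)
            repl_terms = rng.choice(len(others), size=n_swap, replace=False)
            for p, t in zip(repl_pos, repl_terms):
                pool[int(p)] = others[int(t)]
        pools.append(sorted(set(pool)))
    return pools


def gen_annotations(
    scenario: SyntheticScenario,
) -> tuple[dict[str, list[AnnotationProfile]], dict[str, int], OntologyDAG]:
    """Multi-modal annotation profiles with planted community labels.

    Each disease samples ``terms_per_disease`` distinct terms from its
    community's pool (restricted per modality by :data:`POOL_FRACTION`), then
    each term is replaced by a uniformly random ontology term with
    probability ``noise``. Transcriptomic weights are half-normal dC
    magnitudes rescaled to [0, 1] per disease; cellular profiles are
    Dirichlet draws concentrated on the community's own cell types.

    Returns (profiles per modality, disease -> planted community, DAG).
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    dag, branches = gen_branched_ontology(
        sc.n_terms, max_parents=sc.max_parents, seed=sc.seed, n_branches=sc.k_communities
    )
    pools = _community_pools(branches, sc.pool_overlap, rng)
    all_terms = sorted(dag.terms)
    planted = {
        f"D{i:04d}": i % sc.k_communities for i in range(sc.n_diseases)
    }

    profiles: dict[str, list[AnnotationProfile]] = {m: [] for m in sc.modalities}
    for did in sorted(planted):
        c = planted[did]
        for modality in sc.modalities:
            if modality == "cellular":
                continue
            frac = POOL_FRACTION.get(modality, 1.0)
            pool = pools[c][: max(sc.terms_per_disease, int(round(frac * len(pools[c]))))]
            if len(pool) < sc.terms_per_disease:
                raise ContractError(
                    f"community pool ({len(pool)}) smaller than terms_per_disease"
                )
            idx = rng.choice(len(pool), size=sc.terms_per_disease, replace=False)
            chosen = [pool[int(i)] for i in idx]
            final: set[str] = set()
            for t in chosen:
                cand = t
                if rng.random() < sc.noise:
                    cand = all_terms[int(rng.integers(len(all_terms)))]
                while cand in final:  # keep the per-disease term count exact
                    cand = all_terms[int(rng.integers(len(all_terms)))]
                final.add(cand)
            terms = sorted(final)
            if modality == "transcriptomic":
                dc = {t: float(abs(rng.normal())) for t in terms}
                weights = rescale_dc_weights(dc)
                items = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
            else:
                items = [(t, 1.0) for t in terms]
            profiles[modality].append(AnnotationProfile(did, modality, items))
        if "cellular" in sc.modalities:
            profiles["cellular"].append(
                _cellular_profile(did, c, branches, sc, rng)
            )
    return profiles, planted, dag


def _cellular_profile(
    did: str,
    community: int,
    branches: list[list[str]],
    sc: SyntheticScenario,
    rng: np.random.Generator,
) -> AnnotationProfile:
    """Dirichlet cell-type proportions concentrated on the community's branch."""
    m = sc.n_cell_types_per_branch
    cell_terms = [b_terms[i] for b_terms in branches for i in range(min(m, len(b_terms)))]
    alpha = np.full(len(cell_terms), 0.5)
    own = [i for i, t in enumerate(cell_terms) if t in set(branches[community][:m])]
    alpha[own] += 5.0
    props = rng.dirichlet(alpha)
    items = sorted(zip(cell_terms, props.tolist()), key=lambda kv: (-kv[1], kv[0]))
    return AnnotationProfile(did, "cellular", items)


def gen_classification_labels(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-source AD/AID label tables with a configurable agreement rate.

    Each disease carries a true polarity (AD with probability
    ``p_autoimmune``); each of the seven sources labels it correctly with
    probability ``source_agreement``, with the opposite polarity with
    probability (1 − agreement)/2, and omits it otherwise.

    Returns the long-format label table and the true polarity per disease.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed + 1)
    rows = []
    truth = {}
    for i in range(sc.n_diseases):
        did = f"D{i:04d}"
        true_lab = "AD" if rng.random() < sc.p_autoimmune else "AID"
        truth[did] = true_lab
        wrong = "AID" if true_lab == "AD" else "AD"
        for src in LABEL_SOURCES:
            u = rng.random()
            if u < sc.source_agreement:
                rows.append((did, src, true_lab))
            elif u < sc.source_agreement + (1.0 - sc.source_agreement) / 2.0:
                rows.append((did, src, wrong))
            # else: source omits the disease
    return pd.DataFrame(rows, columns=["disease_id", "source", "label"]), truth
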