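"""Ontology DAG handling and Wang-method semantic similarity.

Terms live in a rooted directed acyclic graph (GO, HPO, Cell Ontology or any
OBO-format vocabulary). Semantic similarity between two terms follows the Wang
method: each term contributes an S-value of 1.0 to itself and propagates a
decaying contribution to its ancestors (multiplying by a per-relation factor at
every step, taking the maximum over alternative paths); the similarity of two
terms is the summed S-values over their common ancestors, normalised by the
total semantic value of each term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import TopologicalSorter

import networkx as nx
import numpy as np
import obonet

from .errors import ContractError, FormatError, LookupError_, ValidationError

logger = logging.getLogger(__name__)

#: Standard Wang-method semantic contribution factors per relation type.
DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class OntologyTerm:
    """A single ontology term with typed parent links."""

    term_id: str
    name: str = ""
    parents: list[tuple[str, str]] = field(default_factory=list)  # (parent_id, relation)


class OntologyDAG:
    """Rooted DAG of ontology terms with per-relation contribution factors.

    Parameters
    ----------
    terms
        Terms keyed or listed by unique ``term_id``. Parent references must
        resolve within the collection.
    edge_weights
        Map from relation kind (``is_a``, ``part_of``, ...) to the semantic
        contribution factor in (0, 1). Relations absent from the map do not
        participate in S-value propagation.
    replaced_by
        Optional map from obsolete term ids to their replacement, used to
        remap annotations made against retired terms.
    """

    def __init__(
        self,
        terms: list[OntologyTerm] | dict[str, OntologyTerm],
        edge_weights: dict[str, float] | None = None,
        replaced_by: dict[str, str] | None = None,
    ):
        if isinstance(terms, dict):
            self.terms = dict(terms)
        else:
            self.terms = {}
            for t in terms:
                if t.term_id in self.terms:
                    raise ValidationError(f"duplicate term id {t.term_id!r}")
                self.terms[t.term_id] = t
        self.edge_weights = dict(edge_weights or DEFAULT_EDGE_WEIGHTS)
        for rel, w in self.edge_weights.items():
            if not (0.0 < w < 1.0):
                raise ValidationError(
                    f"contribution factor for {rel!r} must lie strictly in (0,1), got {w}"
                )
        self.replaced_by = dict(replaced_by or {})
        self._validate()
        self._svalue_cache: dict[str, dict[str, float]] = {}

    # -- structure -----------------------------------------------------------

    def _validate(self) -> None:
        for t in self.terms.values():
            for pid, _rel in t.parents:
                if pid not in self.terms:
                    raise ValidationError(
                        f"term {t.term_id!r} references unknown parent {pid!r}"
                    )
        # acyclicity via topological sort of the child->parent graph
        ts = TopologicalSorter(
            {tid: [p for p, _ in t.parents] for tid, t in self.terms.items()}
        )
        try:
            ts.prepare()
        except Exception as exc:  # CycleError carries the offending node chain
            cyc = getattr(exc, "args", ("", []))
            member = cyc[1][0] if len(cyc) > 1 and cyc[1] else "?"
            raise ValidationError(f"ontology graph is cyclic (involves {member!r})") from exc

    @property
    def root_ids(self) -> list[str]:
        """Terms with no weighted parent relation (sorted for determinism)."""
        weighted = set(self.edge_weights)
        return sorted(
            tid
            for tid, t in self.terms.items()
            if not any(rel in weighted for _, rel in t.parents)
        )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str | None:
        """Resolve a possibly-obsolete id to a live term id, else None."""
        if term_id in self.terms:
            return term_id
        repl = self.replaced_by.get(term_id)
        return repl if repl in self.terms else None

    # -- Wang S-values -------------------------------------------------------

    def svalues(self, term_id: str) -> dict[str, float]:
        """S-values of ``term_id`` at itself and every ancestor.

        S(t)=1 at the term; each hop to a parent multiplies by the relation's
        contribution factor; multiple paths to one ancestor keep the maximum.
        """
        if term_id not in self.terms:
            raise LookupError_(f"unknown term {term_id!r}")
        cached = self._svalue_cache.get(term_id)
        if cached is not None:
            return cached
        s = {term_id: 1.0}
        # relax child->parent edges in topological order of the ancestor closure
        order = [term_id]
        seen = {term_id}
        frontier = [term_id]
        while frontier:
            nxt = []
            for tid in frontier:
                for pid, rel in self.terms[tid].parents:
                    if rel in self.edge_weights and pid not in seen:
                        seen.add(pid)
                        nxt.append(pid)
            order.extend(nxt)
            frontier = nxt
        # BFS layering is not a topological order in a DAG with shortcuts, so
        # iterate relaxations until fixpoint (max-product converges fast: the
        # ancestor closure is shallow and factors are < 1).
        changed = True
        while changed:
            changed = False
            for tid in order:
                base = s.get(tid)
                if base is None:
                    continue
                for pid, rel in self.terms[tid].parents:
                    w = self.edge_weights.get(rel)
                    if w is None:
                        continue
                    cand = base * w
                    if cand > s.get(pid, 0.0):
                        s[pid] = cand
                        changed = True
        self._svalue_cache[term_id] = s
        return s

    def semantic_value(self, term_id: str) -> float:
        """SV(t): sum of all S-values of a term."""
        return sum(self.svalues(term_id).values())


def wang_similarity(dag: OntologyDAG, t1: str, t2: str) -> float:
    """Wang semantic similarity between two terms, in [0, 1].

    sim(t1, t2) = sum over common ancestors a of (S1(a) + S2(a)),
    divided by (SV(t1) + SV(t2)). Symmetric; 1 exactly for identical terms.
    """
    s1 = dag.svalues(t1)
    s2 = dag.svalues(t2)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    # deterministic summation order keeps s(a,b) == s(b,a) to the last ulp
    num = sum(s1[a] + s2[a] for a in sorted(common))
    return num / (sum(s1[a] for a in sorted(s1)) + sum(s2[a] for a in sorted(s2)))


def term_similarity_matrix(
    dag: OntologyDAG, terms1: list[str], terms2: list[str]
) -> np.ndarray:
    """Matrix of Wang similarities, entry (i, j) = sim(terms1[i], terms2[j])."""
    if not terms1 or not terms2:
        raise ContractError("term lists must be non-empty")
    s1 = [dag.svalues(t) for t in terms1]
    s2 = [dag.svalues(t) for t in terms2]
    sv1 = [sum(s[a] for a in sorted(s)) for s in s1]
    sv2 = [sum(s[a] for a in sorted(s)) for s in s2]
    out = np.zeros((len(terms1), len(terms2)))
    for i, (si, svi) in enumerate(zip(s1, sv1)):
        for j, (sj, svj) in enumerate(zip(s2, sv2)):
            common = si.keys() & sj.keys()
            if common:
                out[i, j] = sum(si[a] + sj[a] for a in sorted(common)) / (svi + svj)
    return out


def load_ontology(
    path: str, edge_weights: dict[str, float] | None = None
) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Obsolete terms are dropped (with a logged count); their ``replaced_by``
    pointers are retained so annotations can be remapped. Cyclic input is
    rejected with a :class:`ValidationError` naming one cycle member.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except (ValueError, KeyError) as exc:
        raise FormatError(f"failed to parse OBO file {path!r}: {exc}") from exc

    obsolete = {
        n for n, d in graph.nodes(data=True) if d.get("is_obsolete") in ("true", True)
    }
    replaced_by = {}
    for n in obsolete:
        repl = graph.nodes[n].get("replaced_by")
        if repl:
            replaced_by[n] = repl[0] if isinstance(repl, list) else repl
    if obsolete:
        logger.info("dropping %d obsolete terms from %s", len(obsolete), path)

    live = [n for n in graph.nodes if n not in obsolete]
    live_set = set(live)
    terms = {}
    for n in live:
        data = graph.nodes[n]
        parents: list[tuple[str, str]] = []
        # obonet encodes child -> parent edges keyed by relation type
        for _, parent, rel in graph.out_edges(n, keys=True):
            if parent in live_set:
                parents.append((parent, rel))
        terms[n] = OntologyTerm(term_id=n, name=data.get("name", ""), parents=parents)

    # detect cycles on the raw parsed graph before DAG construction for a
    # clearer error than the generic validator's
    sub = graph.subgraph(live)
    if not nx.is_directed_acyclic_graph(sub):
        cycle = nx.find_cycle(sub)
        raise ValidationError(
            f"ontology contains a cycle involving term {cycle[0][0]!r}"
        )

    return OntologyDAG(terms, edge_weights=edge_weights, replaced_by=replaced_by)


def write_obo(dag: OntologyDAG, path: str, ontology_name: str = "synthetic") -> None:
    """Serialise a DAG back to a minimal OBO 1.2 flat file."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n\n")
        for tid in sorted(dag.terms):
            t = dag.terms[tid]
            fh.write("[Term]\n")
            fh.write(f"id: {t.term_id}\n")
            if t.name:
                fh.write(f"name: {t.name}\n")
            for pid, rel in sorted(t.parents):
                if rel == "is_a":
                    fh.write(f"is_a: {pid}\n")
                else:
                    fh.write(f"relationship: {rel} {pid}\n")
            fh.write("\n")
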