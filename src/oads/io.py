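"""Plain-text readers/writers for the pipeline's TSV interchange formats."""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .errors import ContractError, FormatError
from .network import DiseaseNetwork
from .profiles import AnnotationProfile
from .similarity import SimilarityMatrix


def write_similarity(sim: SimilarityMatrix, path: str, what: str = "scores") -> None:
    """Matrix TSV with disease ids as header row and first column."""
    mat = sim.scores if what == "scores" else sim.pvalues
    if mat is None:
        raise ContractError(f"matrix has no {what}")
    df = pd.DataFrame(mat, index=sim.disease_ids, columns=sim.disease_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_similarity(
    path: str, pvalues_path: str | None = None, modality: str = ""
) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column ids differ")
    pv = None
    if pvalues_path:
        pdf = pd.read_csv(pvalues_path, sep="\t", index_col=0)
        if list(pdf.index) != list(df.index):
            raise FormatError(f"{pvalues_path}: ids do not match {path}")
        pv = pdf.to_numpy(dtype=float)
    return SimilarityMatrix(
        disease_ids=[str(i) for i in df.index],
        scores=df.to_numpy(dtype=float),
        pvalues=pv,
        modality=modality,
    )


def write_annotations(profiles: list[AnnotationProfile], path: str) -> None:
    """Long-format TSV: disease_id, term_id, weight."""
    rows = [(p.disease_id, t, w) for p in profiles for t, w in p.terms]
    pd.DataFrame(rows, columns=["disease_id", "term_id", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_annotations(path: str, modality: str) -> list[AnnotationProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"disease_id": str, "term_id": str})
    if "weight" not in df.columns:
        df["weight"] = 1.0
    profiles = []
    for did, grp in df.groupby("disease_id", sort=True):
        items = sorted(
            zip(grp["term_id"], grp["weight"].astype(float)),
            key=lambda kv: (-kv[1], kv[0]),
        )
        profiles.append(AnnotationProfile(str(did), modality, items))
    return profiles


def read_labels(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"disease_id", "source", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    return df


def write_edges(net: DiseaseNetwork, path: str) -> None:
    pd.DataFrame(net.edges, columns=["i", "j", "similarity"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_edges(path: str, modality: str = "") -> DiseaseNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"i": str, "j": str})
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row["i"], row["j"], similarity=float(row["similarity"]))
    return DiseaseNetwork(graph=g, modality=modality)


def write_graphml(net: DiseaseNetwork, path: str) -> None:
    nx.write_graphml(net.graph, path)


def write_partition(assignment: dict[str, int], path: str) -> None:
    pd.DataFrame(
        sorted(assignment.items()), columns=["disease_id", "label"]
    ).to_csv(path, sep="\t", index=False)


def read_partition(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"disease_id": str})
    return {str(d): int(l) for d, l in zip(df["disease_id"], df["label"])}
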