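"""End-to-end orchestration: repository -> profiles -> OADS -> permutation ->
networks -> communities -> integration, driven by one JSON-serialisable
configuration with explicit seeds, producing a manifest with content hashes
so that identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as oio
from .communities import (
    feature_enrichment,
    leiden_clusters,
    robust_communities,
    ward_clusters,
)
from .errors import ContractError
from .integration import FusionConfig, benchmark_correlation, build_mst, snf_fuse
from .network import build_network, topology_summary, wind
from .permutation import PermutationConfig, empirical_pvalues
from .powerlaw import powerlaw_classify
from .repository import integrate_sources
from .similarity import dc_weighted_oads, pairwise_oads
from .synthgen import SyntheticScenario, gen_annotations, gen_classification_labels

logger = logging.getLogger(__name__)


class StageError(ContractError):
    """A pipeline stage failed; prior stage outputs are left on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (JSON round-trippable)."""

    out_dir: str = "oads_run"
    scenario: dict = field(default_factory=dict)  # SyntheticScenario overrides
    percentile: float = 90.0
    alpha: float = 0.05
    n_permutations: int = 500
    leiden_resolution: float = 1.0
    snf_K: int = 10
    snf_t: int = 20
    min_community_size: int = 4
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.percentile < 100.0):
            raise ContractError(f"percentile must lie in (0, 100), got {self.percentile}")
        if not (0.0 < self.alpha <= 1.0):
            raise ContractError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.n_permutations < 1:
            raise ContractError("n_permutations must be >= 1")
        if self.snf_K < 1 or self.snf_t < 1:
            raise ContractError("SNF parameters must be positive")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order and return the run manifest.

    The manifest lists each output file with a content hash plus per-stage
    counts (diseases, edges, communities). Reruns with the same configuration
    reproduce identical hashes.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}

    def emit(name: str, path: Path) -> None:
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    # -- stage 1: synthetic inputs + classification repository ---------------
    scenario = SyntheticScenario(**{"seed": config.seed, **config.scenario})
    profiles_by_mod, planted, dag = gen_annotations(scenario)
    labels, truth = gen_classification_labels(scenario)
    labels_path = out / "labels.tsv"
    labels.to_csv(labels_path, sep="\t", index=False)
    emit("labels", labels_path)

    records, repo_summary = integrate_sources(labels)
    categories = {d: r.category for d, r in records.items()}
    repo_path = out / "repository.json"
    repo_path.write_text(
        json.dumps(
            {
                "summary": repo_summary,
                "records": {
                    d: {"acs": r.acs, "acs_norm": r.acs_norm, "category": r.category}
                    for d, r in sorted(records.items())
                },
            },
            indent=1,
            sort_keys=True,
        )
    )
    emit("repository", repo_path)
    manifest["stages"]["repository"] = repo_summary

    # -- stage 2: similarity + permutation significance per modality ---------
    sims = {}
    for mi, (modality, profiles) in enumerate(sorted(profiles_by_mod.items())):
        if modality == "transcriptomic":
            sim = dc_weighted_oads(profiles, dag)
        else:
            sim = pairwise_oads(profiles, dag)
        null_fn = (
            (lambda p: dc_weighted_oads(p, dag))
            if modality == "transcriptomic"
            else (lambda p: pairwise_oads(p, dag))
        )
        pcfg = PermutationConfig(
            n_permutations=config.n_permutations, seed=config.seed + 1000 + mi
        )
        sim.pvalues = empirical_pvalues(sim, profiles, null_fn, pcfg)
        sims[modality] = sim
        oio.write_annotations(profiles, out / f"annotations_{modality}.tsv")
        oio.write_similarity(sim, out / f"sim_{modality}.tsv")
        oio.write_similarity(sim, out / f"pvalues_{modality}.tsv", what="pvalues")
        emit(f"annotations_{modality}", out / f"annotations_{modality}.tsv")
        emit(f"sim_{modality}", out / f"sim_{modality}.tsv")
        emit(f"pvalues_{modality}", out / f"pvalues_{modality}.tsv")
        manifest["stages"][f"similarity_{modality}"] = {
            "n_diseases": len(sim.disease_ids),
            "n_permutations": pcfg.n_permutations,
            "seed": pcfg.seed,
        }

    # -- stage 3: networks, topology, power law, WiND -------------------------
    nets = {}
    for modality, sim in sorted(sims.items()):
        try:
            net = build_network(sim, percentile=config.percentile, alpha=config.alpha)
            if net.graph.number_of_edges() == 0:
                raise ContractError(
                    "no edge passed both thresholds (with few permutations the "
                    "add-one p-value floor may exceed alpha)"
                )
        except ContractError as exc:
            raise StageError(f"network_{modality}", exc) from exc
        nets[modality] = net
        oio.write_edges(net, out / f"network_{modality}.tsv")
        oio.write_graphml(net, out / f"network_{modality}.graphml")
        emit(f"network_{modality}", out / f"network_{modality}.tsv")
        emit(f"network_{modality}_graphml", out / f"network_{modality}.graphml")
        topo = topology_summary(net)
        report = {
            "n_nodes": topo.n_nodes,
            "n_edges": topo.n_edges,
            "average_degree": topo.average_degree,
            "density": topo.density,
            "transitivity": topo.transitivity,
            "kcore_k": topo.kcore_k,
            "kcore_size": topo.kcore_size,
            "average_clustering": topo.average_clustering,
            "average_shortest_path": topo.average_shortest_path,
            "diameter": topo.diameter,
            "n_components": topo.n_components,
            "network_wind": wind(net)["wind"],
        }
        try:
            report["powerlaw"] = {
                k: v
                for k, v in powerlaw_classify(
                    [d for _, d in net.graph.degree()]
                ).items()
                if k in ("alpha", "xmin", "better_fit", "classification")
            }
        except Exception as exc:  # tiny or degenerate networks
            report["powerlaw"] = {"error": str(exc)}
        cat_wind = {}
        for cat in sorted(set(categories.values())):
            members = [d for d, c in categories.items() if c == cat]
            try:
                w = wind(net, members)
                cat_wind[cat] = {
                    "category_wind": w["wind"],
                    "wind_ratio": w["wind"] / report["network_wind"],
                    "pair_count": w["pair_count"],
                    "direct_links": w["direct_links"],
                }
            except ContractError:
                cat_wind[cat] = None
        report["category_wind"] = cat_wind
        (out / f"topology_{modality}.json").write_text(
            json.dumps(report, indent=1, sort_keys=True)
        )
        emit(f"topology_{modality}", out / f"topology_{modality}.json")
        manifest["stages"][f"network_{modality}"] = {
            "n_nodes": topo.n_nodes,
            "n_edges": topo.n_edges,
            "n_isolated": len(net.isolated),
        }

    # -- stage 4: communities and consensus ------------------------------------
    partitions = []
    for modality in sorted(nets):
        leiden = leiden_clusters(
            nets[modality], resolution=config.leiden_resolution, seed=config.seed
        )
        # cut the Ward dendrogram to the Leiden community count for comparability
        shared_ids = sorted(nets[modality].graph.nodes)
        sub = sims[modality]
        keep = [sub.index_of(d) for d in shared_ids]
        restricted = type(sub)(
            disease_ids=shared_ids,
            scores=sub.scores[np.ix_(keep, keep)],
            modality=modality,
        )
        ward = ward_clusters(restricted, n_clusters=max(2, leiden.n_clusters))
        for part, tag in ((leiden, "leiden"), (ward, "ward")):
            oio.write_partition(part.assignment, out / f"partition_{modality}_{tag}.tsv")
            emit(f"partition_{modality}_{tag}", out / f"partition_{modality}_{tag}.tsv")
        partitions.extend([leiden, ward])
        manifest["stages"][f"communities_{modality}"] = {
            "leiden_clusters": leiden.n_clusters,
            "ward_clusters": ward.n_clusters,
        }

    robust = robust_communities(
        partitions, min_size=config.min_community_size, categories=categories
    )
    enrichment = feature_enrichment(
        robust, {d: {c} for d, c in categories.items()}
    ) if robust else []
    consensus_path = out / "robust_communities.json"
    consensus_path.write_text(
        json.dumps(
            [
                {
                    "community_id": c.community_id,
                    "members": c.members,
                    "category_counts": c.category_counts,
                    "planted_majority": (
                        Counter(
                            planted[d] for d in c.members if d in planted
                        ).most_common(1)[0][0]
                        if any(d in planted for d in c.members)
                        else None
                    ),
                }
                for c in robust
            ]
            + [{"enrichment": enrichment}],
            indent=1,
            sort_keys=True,
        )
    )
    emit("robust_communities", consensus_path)
    manifest["stages"]["consensus"] = {"n_robust_communities": len(robust)}

    # -- stage 5: integration ---------------------------------------------------
    mods = sorted(sims)
    if len(mods) >= 2:
        n_shared = len(set.intersection(*(set(sims[m].disease_ids) for m in mods)))
        K = min(config.snf_K, max(1, n_shared - 1))
        fused = snf_fuse(
            [sims[m] for m in mods], FusionConfig(K=K, t=config.snf_t)
        )
        oio.write_similarity(fused, out / "fused.tsv")
        emit("fused", out / "fused.tsv")
        corr = {
            f"{a}|{b}": benchmark_correlation(sims[a], sims[b])
            for i, a in enumerate(mods)
            for b in mods[i + 1 :]
        }
        manifest["stages"]["integration"] = {"snf_K": K, "correlations": corr}
    first = mods[0]
    mst = build_mst(sims[first], percentile=config.percentile, alpha=config.alpha)
    mst_path = out / f"mst_{first}.tsv"
    with open(mst_path, "w") as fh:
        fh.write("i\tj\tdistance\n")
        for u, v, d in mst:
            fh.write(f"{u}\t{v}\t{d:.10g}\n")
    emit("mst", mst_path)
    manifest["stages"]["mst"] = {"n_edges": len(mst)}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
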