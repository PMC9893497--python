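"""End-to-end orchestration: DE -> venn -> networks -> MCL -> evolution ->
enrichment -> hubs, from one config, with a machine-readable run manifest.

The analysis branch is fully deterministic; the single seed only feeds the
synthetic-data branch. Every threshold lives in the config with the
workflow's standard values as defaults; nothing is hard-coded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import io as snio
from .datatypes import (
    ClinicalTable,
    CountMatrix,
    GeneSetCollection,
    InteractionNetwork,
    Stage,
    TUMOUR_STAGES,
)
from .deg import DEGSet, run_stage_de
from .enrichment import (
    common_pathways,
    enrich_module,
    pathway_stage_matrix,
)
from .evolution import (
    EvolutionNetwork,
    adjacent_overlap_network,
    cluster_interaction_network,
    combine_evolution_network,
    largest_connected_component,
)
from .hubs import hub_subnetwork, top_hubs
from .mcl import ModulePartition, mcl_cluster, select_modules
from .networks import build_ppi_graph, build_stage_network, filter_degs
from .simulate import GroundTruth, SimulationConfig, simulate_all
from .venn import venn_partition

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "plant_recovery_report"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one run.

    Either the four input paths are set, or ``synthetic`` is true and the
    inputs are generated from ``simulation`` (seeded). The config
    round-trips losslessly through YAML.
    """

    counts_path: str | None = None
    clinical_path: str | None = None
    interactions_path: str | None = None
    pathways_path: str | None = None
    synthetic: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    cpm_threshold: float = 1.0
    fdr_cut: float = 0.05
    lfc_cut: float = 1.0
    filter_lfc: float = 1.5
    fi_conf: float = 0.75
    ppi_score: float = 0.75
    min_module: int = 5
    enrich_fdr: float = 0.05
    enrich_p: float = 0.05
    universe_mode: str = "pathway_overlap"  # or "all_measured"
    ppi_gene_source: str = "filtered_union"  # or "intersection"
    hub_k: int = 10
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    mcl_prune: float = 1e-5
    mcl_max_iter: int = 200
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name in ("fdr_cut", "enrich_fdr", "enrich_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("fi_conf", "ppi_score"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_module < 1:
            raise ValueError("min_module must be >= 1")
        # keep the synthetic seed in lockstep with the pipeline seed
        self.simulation.seed = self.seed

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["simulation"]["group_sizes"] = {
            s.value: n for s, n in self.simulation.group_sizes.items()
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        sim = payload.pop("simulation", {})
        if "group_sizes" in sim:
            sim["group_sizes"] = {
                Stage.from_label(k): v for k, v in sim["group_sizes"].items()
            }
        for key in ("baseline_logmean_range", "library_scale_range",
                    "module_size_range", "confidence_high_range", "pathway_size_range"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        return cls(simulation=SimulationConfig(**sim), **payload)


@dataclass
class PipelineResult:
    """In-memory artifacts of one run (also written to ``outdir`` if set)."""

    config: PipelineConfig
    de_results: dict[Stage, pd.DataFrame]
    degsets: dict[Stage, DEGSet]
    venn: object
    filtered_genes: dict[Stage, frozenset[str]]
    stage_networks: dict[Stage, InteractionNetwork]
    partitions: dict[Stage, ModulePartition]
    evolution: EvolutionNetwork
    largest_component: EvolutionNetwork
    enrichments: dict[Stage, list[pd.DataFrame]]
    common_pathway_ids: list[str]
    pathway_matrix: object
    ppi: InteractionNetwork
    hub_table: pd.DataFrame
    manifest: dict
    truth: GroundTruth | None = None


def _load_inputs(
    config: PipelineConfig,
) -> tuple[CountMatrix, ClinicalTable, list, GeneSetCollection, GroundTruth | None]:
    if config.synthetic:
        data = simulate_all(config.simulation)
        return data.counts, data.clinical, data.edges, data.genesets, data.truth
    missing = [
        n
        for n in ("counts_path", "clinical_path", "interactions_path", "pathways_path")
        if getattr(config, n) is None
    ]
    if missing:
        raise ValueError(f"non-synthetic run needs paths: {missing}")
    return (
        snio.read_counts(config.counts_path),
        snio.read_clinical(config.clinical_path),
        snio.read_edge_list(config.interactions_path),
        snio.read_gmt(config.pathways_path),
        None,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the staged analysis end-to-end; idempotent for a fixed seed."""
    counts, clinical, edges, genesets, truth = _load_inputs(config)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    stages = [s for s in TUMOUR_STAGES if clinical.samples_for(s)]
    de_results: dict[Stage, pd.DataFrame] = {}
    degsets: dict[Stage, DEGSet] = {}
    measured: dict[Stage, frozenset[str]] = {}
    phis: dict[Stage, float] = {}
    for stage in stages:
        try:
            results, degset, phi = run_stage_de(
                counts,
                clinical,
                stage,
                cpm_threshold=config.cpm_threshold,
                fdr_cut=config.fdr_cut,
                lfc_cut=config.lfc_cut,
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"DE analysis failed at stage {stage.value}: {exc}") from exc
        de_results[stage] = results
        degsets[stage] = degset
        measured[stage] = frozenset(results["gene"])
        phis[stage] = phi
        if outdir:
            results.to_csv(outdir / f"de_stage_{stage.value}.tsv", sep="\t", index=False)

    venn_result = venn_partition(list(degsets.values()))
    if outdir:
        venn_result.to_frame().to_csv(outdir / "venn_regions.tsv", sep="\t", index=False)
        inter = sorted(venn_result.intersection_genes(tuple(stages)))
        (outdir / "intersection_degs.txt").write_text("\n".join(inter) + "\n")

    filtered: dict[Stage, frozenset[str]] = {}
    stage_nets: dict[Stage, InteractionNetwork] = {}
    partitions: dict[Stage, ModulePartition] = {}
    for stage in stages:
        genes = filter_degs(degsets[stage], edges, config.filter_lfc, config.fi_conf)
        filtered[stage] = genes
        if not genes:
            logger.warning(
                "network filter left no genes at stage %s; downstream "
                "artifacts for this stage are empty",
                stage.value,
            )
            stage_nets[stage] = InteractionNetwork(graph=nx.Graph(), kind="FI")
            partitions[stage] = ModulePartition(
                modules=[], retained=[], graph=stage_nets[stage].graph
            )
            continue
        net = build_stage_network(genes, edges, config.fi_conf)
        if net.n_edges == 0:
            logger.warning("stage %s FI network has no edges", stage.value)
        stage_nets[stage] = net
        part = mcl_cluster(
            net,
            inflation=config.mcl_inflation,
            expansion=config.mcl_expansion,
            prune_threshold=config.mcl_prune,
            max_iter=config.mcl_max_iter,
        )
        partitions[stage] = select_modules(part, config.min_module)
        if outdir:
            snio.write_network(net.graph, outdir / f"fi_stage_{stage.value}.sif")
            labels = partitions[stage].labels()
            retained_ids = {
                i for i, r in enumerate(partitions[stage].retained) if r
            }
            with open(outdir / f"modules_stage_{stage.value}.tsv", "w") as fh:
                fh.write("gene\tmodule_id\tretained\n")
                for gene in sorted(labels):
                    mid = labels[gene]
                    fh.write(f"{gene}\t{mid}\t{int(mid in retained_ids)}\n")

    intra = {s: cluster_interaction_network(stage_nets[s], partitions[s]) for s in stages}
    inter_edges = {}
    for a, b in zip(stages, stages[1:]):
        if TUMOUR_STAGES.index(b) - TUMOUR_STAGES.index(a) == 1:
            inter_edges[(a, b)] = adjacent_overlap_network(
                partitions[a], a, partitions[b], b
            )
    evolution = combine_evolution_network(intra, inter_edges)
    largest = largest_connected_component(evolution)
    if outdir:
        snio.write_network(evolution.graph, outdir / "evolution.sif", weight_attr="weight")
        pd.DataFrame(evolution.node_table()).to_csv(
            outdir / "evolution_nodes.tsv", sep="\t", index=False
        )

    pathway_genes = genesets.all_genes()
    enrichments: dict[Stage, list[pd.DataFrame]] = {}
    stage_sig: dict[Stage, dict[str, float]] = {}
    for stage in stages:
        universe = (
            measured[stage] & pathway_genes
            if config.universe_mode == "pathway_overlap"
            else measured[stage]
        )
        tables = []
        sig: dict[str, float] = {}
        for mod in partitions[stage].retained_modules():
            testable = frozenset(mod) & universe
            if not testable:
                continue
            df = enrich_module(testable, genesets, universe)
            df["significant"] = (df["fdr"] < config.enrich_fdr) & (
                df["p_value"] < config.enrich_p
            )
            tables.append(df)
            for pid, p, s in zip(df["pathway_id"], df["p_value"], df["significant"]):
                if s:
                    sig[pid] = min(sig.get(pid, 1.0), float(p))
        enrichments[stage] = tables
        stage_sig[stage] = sig
        if outdir and tables:
            pd.concat(tables, keys=range(len(tables)), names=["module"]).to_csv(
                outdir / f"enrichment_stage_{stage.value}.tsv", sep="\t"
            )

    common = common_pathways(stage_sig) if stage_sig else []
    matrix = pathway_stage_matrix(enrichments)
    if outdir:
        matrix.p_values.to_csv(outdir / "pathway_stage_matrix.tsv", sep="\t")
        (outdir / "common_pathways.txt").write_text("\n".join(common) + "\n")

    if config.ppi_gene_source == "intersection":
        ppi_genes = venn_result.intersection_genes(tuple(stages))
    else:
        ppi_genes = frozenset().union(*filtered.values())
    if ppi_genes:
        ppi = build_ppi_graph(ppi_genes, edges, config.ppi_score)
        k = min(config.hub_k, len(ppi.nodes))
        hub_table = top_hubs(ppi, k)
        hub_net = hub_subnetwork(ppi, hub_table)
    else:
        ppi = InteractionNetwork(graph=nx.Graph(), kind="PPI")
        hub_table = pd.DataFrame(columns=["gene", "degree", "betweenness", "rank"])
        hub_net = ppi
    if outdir:
        snio.write_network(ppi.graph, outdir / "ppi.sif")
        hub_table.to_csv(outdir / "hub_genes.tsv", sep="\t", index=False)
        snio.write_network(hub_net.graph, outdir / "hub_subnetwork.sif")

    manifest = {
        "seed": config.seed,
        "thresholds": {
            "cpm_threshold": config.cpm_threshold,
            "fdr_cut": config.fdr_cut,
            "lfc_cut": config.lfc_cut,
            "filter_lfc": config.filter_lfc,
            "fi_conf": config.fi_conf,
            "ppi_score": config.ppi_score,
            "min_module": config.min_module,
            "enrich_fdr": config.enrich_fdr,
            "enrich_p": config.enrich_p,
        },
        "mcl": {
            "inflation": config.mcl_inflation,
            "expansion": config.mcl_expansion,
            "prune_threshold": config.mcl_prune,
        },
        "per_stage": {
            s.value: {
                "de_set_size": len(clinical.samples_for(s))
                + len(clinical.samples_for(Stage.NORMAL)),
                "n_genes_tested": len(measured[s]),
                "dispersion": round(phis[s], 6),
                "n_degs": len(degsets[s].genes),
                "n_up": len(degsets[s].up),
                "n_down": len(degsets[s].down),
                "n_filtered_degs": len(filtered[s]),
                "n_clusters": len(partitions[s]),
                "n_modules_retained": sum(partitions[s].retained),
            }
            for s in stages
        },
        "venn": {
            "union_size": len(venn_result.union),
            "intersection_size": len(venn_result.intersection_genes(tuple(stages))),
            "class_totals": venn_result.class_totals(),
        },
        "evolution": {
            "n_nodes": evolution.graph.number_of_nodes(),
            "n_edges": evolution.graph.number_of_edges(),
            "largest_component_nodes": largest.graph.number_of_nodes(),
            "largest_component_all_stages": largest.all_stages_present,
        },
        "ppi": {"n_nodes": len(ppi.nodes), "n_edges": ppi.n_edges},
        "hub_genes": list(hub_table["gene"]),
        "common_pathways": common,
    }
    if outdir:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )

    return PipelineResult(
        config=config,
        de_results=de_results,
        degsets=degsets,
        venn=venn_result,
        filtered_genes=filtered,
        stage_networks=stage_nets,
        partitions=partitions,
        evolution=evolution,
        largest_component=largest,
        enrichments=enrichments,
        common_pathway_ids=common,
        pathway_matrix=matrix,
        ppi=ppi,
        hub_table=hub_table,
        manifest=manifest,
        truth=truth,
    )


def plant_recovery_report(result: PipelineResult) -> dict:
    """Compare a synthetic run's outputs against the planted ground truth.

    A planted module counts as *persistent* when, in every stage, some
    retained module recovers at least half of its genes and those four
    recovered cluster nodes lie in a single connected component of the
    evolution network. Also reports, per planted module, whether its
    aligned pathway came out significant in at least one stage.
    """
    if result.truth is None:
        raise ValueError("no ground truth: not a synthetic run")
    truth = result.truth
    stages = list(result.partitions)
    planted = truth.modules()

    components = list(nx.connected_components(result.evolution.graph))
    node_component = {
        node: ci for ci, comp in enumerate(components) for node in comp
    }

    n_persistent = 0
    per_module = {}
    for mid, members in sorted(planted.items()):
        nodes_found = []
        for stage in stages:
            part = result.partitions[stage]
            best, best_overlap = None, 0
            for i, (mod, r) in enumerate(zip(part.modules, part.retained)):
                if not r:
                    continue
                overlap = len(mod & members)
                if overlap > best_overlap:
                    best, best_overlap = i, overlap
            if best is not None and best_overlap >= 0.5 * len(members):
                from .evolution import stage_node_id

                nodes_found.append(stage_node_id(stage, best))
        recovered_all = len(nodes_found) == len(stages)
        same_component = (
            recovered_all
            and len({node_component[n] for n in nodes_found if n in node_component})
            == 1
            and all(n in node_component for n in nodes_found)
        )
        if same_component:
            n_persistent += 1
        per_module[mid] = {
            "recovered_stages": len(nodes_found),
            "spans_all_stages": same_component,
        }

    pathway_hits = 0
    aligned = {mid: pid for pid, mid in truth.pathway_module_map.items()}
    for mid in planted:
        pid = aligned.get(mid)
        hit = False
        if pid is not None:
            for stage in stages:
                for df in result.enrichments[stage]:
                    sel = df.loc[df["pathway_id"] == pid, "significant"]
                    if len(sel) and bool(sel.iloc[0]):
                        hit = True
        per_module[mid]["pathway_recovered"] = hit
        pathway_hits += int(hit)

    n = len(planted)
    return {
        "n_planted_modules": n,
        "n_persistent_recovered": n_persistent,
        "persistent_recovery_rate": n_persistent / n if n else float("nan"),
        "pathway_recovery_rate": pathway_hits / n if n else float("nan"),
        "per_module": per_module,
    }
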