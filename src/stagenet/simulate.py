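"""Synthetic staged-cohort data with known ground truth.

Emulates the statistical structure of a staged bulk RNA-seq tumour cohort
(the TCGA-COAD staging design: 41 normals, 45/109/80/37 tumour samples in
stages I-IV) together with a gene interaction network and pathway gene sets:

* counts are negative binomial, gene-wise mean ``mu_gs = L_s * exp(b_g +
  delta_gs)`` with per-sample library scale ``L_s`` log-uniform and a
  planted log2 fold change ``delta`` for differentially expressed genes;
* a planted-module interaction graph in which within-module edges receive
  high confidence scores and cross-module noise edges low ones;
* pathway gene sets aligned (to a configurable degree) with the planted
  modules.

Genes carried by the planted modules are differentially expressed in every
stage with a per-gene sign that is consistent across stages, so modules
persist through the staged analysis; the remaining DE quota per stage is
filled with stage-exclusive genes. Everything is reproducible from one
integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    CountMatrix,
    GeneSetCollection,
    Stage,
    TUMOUR_STAGES,
)
from .cohort import REFERENCE_GROUP_SIZES

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_counts",
    "simulate_interactions",
    "simulate_genesets",
    "simulate_all",
]

LN2 = math.log(2.0)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the reference cohort.

    ``de_logfc_magnitude`` is in log2 units (a value of 2 plants 4-fold
    changes); ``baseline_logmean_range`` is the natural-log range of the
    per-gene baseline mean count at library scale 1; ``nb_dispersion`` is
    the NB dispersion phi in ``var = mu + phi * mu**2``.
    """

    n_genes: int = 2000
    group_sizes: dict[Stage, int] = field(
        default_factory=lambda: dict(REFERENCE_GROUP_SIZES)
    )
    nb_dispersion: float = 0.1
    baseline_logmean_range: tuple[float, float] = (math.log(8.0), math.log(400.0))
    library_scale_range: tuple[float, float] = (0.5, 2.0)
    de_fraction_per_stage: float = 0.05
    de_logfc_magnitude: float = 2.0
    n_modules: int = 8
    module_size_range: tuple[int, int] = (8, 12)
    within_module_edge_prob: float = 0.9
    between_module_edge_prob: float = 0.002
    confidence_high_range: tuple[float, float] = (0.8, 1.0)
    cross_module_confidence_max: float = 0.75
    n_pathways: int = 12
    pathway_size_range: tuple[int, int] = (10, 25)
    pathway_module_alignment: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 samples")
        if not 0.0 <= self.de_fraction_per_stage < 1.0:
            raise ValueError("de_fraction_per_stage must be in [0, 1)")
        if self.within_module_edge_prob <= self.between_module_edge_prob:
            raise ValueError(
                "within_module_edge_prob must exceed between_module_edge_prob"
            )
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        n_de = self.n_de_per_stage
        n_specific = max(0, n_de - self.n_modules * self.module_size_range[1])
        if n_de > self.n_genes or 4 * n_specific > self.n_genes:
            raise ValueError("requested DE genes exceed n_genes")
        if self.n_pathways < self.n_modules:
            raise ValueError("need at least one pathway per module")

    @property
    def n_de_per_stage(self) -> int:
        return int(round(self.n_genes * self.de_fraction_per_stage))


@dataclass
class GroundTruth:
    """Planted structure recorded by the generator, for validation."""

    de_genes_per_stage: dict[Stage, dict[str, int]]  # gene -> sign (+1/-1)
    module_assignment: dict[str, int]  # gene -> module id (module genes only)
    pathway_module_map: dict[str, int]  # pathway id -> aligned module id

    def de_sets(self, stage: Stage) -> tuple[set[str], set[str]]:
        signed = self.de_genes_per_stage[stage]
        up = {g for g, s in signed.items() if s > 0}
        down = {g for g, s in signed.items() if s < 0}
        return up, down

    def module_members(self, module_id: int) -> set[str]:
        return {g for g, m in self.module_assignment.items() if m == module_id}

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for g, m in self.module_assignment.items():
            out.setdefault(m, set()).add(g)
        return out

    def to_json(self) -> str:
        payload = {
            "de_genes_per_stage": {
                s.value: signed for s, signed in self.de_genes_per_stage.items()
            },
            "module_assignment": self.module_assignment,
            "pathway_module_map": self.pathway_module_map,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    clinical: ClinicalTable
    edges: list[tuple[str, str, float]]
    genesets: GeneSetCollection
    truth: GroundTruth


def _plant_structure(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[str], GroundTruth]:
    """Choose gene ids, module membership, signs and per-stage DE sets."""
    width = len(str(config.n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]

    sizes = rng.integers(
        config.module_size_range[0], config.module_size_range[1] + 1, config.n_modules
    )
    shuffled = list(rng.permutation(genes))
    module_assignment: dict[str, int] = {}
    pos = 0
    for mid, size in enumerate(sizes):
        for g in shuffled[pos : pos + int(size)]:
            module_assignment[g] = mid
        pos += int(size)
    module_genes = shuffled[:pos]
    pool = shuffled[pos:]

    # Per-gene direction fixed once: consistent across stages, so no gene is
    # planted both up- and down-regulated.
    sign_of = {g: int(s) for g, s in zip(genes, rng.choice([-1, 1], config.n_genes))}

    n_de = config.n_de_per_stage
    persistent = module_genes[: min(len(module_genes), n_de)]
    n_specific = n_de - len(persistent)
    de_per_stage: dict[Stage, dict[str, int]] = {}
    cursor = 0
    for stage in TUMOUR_STAGES:
        specific = pool[cursor : cursor + n_specific]
        cursor += n_specific
        de_per_stage[stage] = {g: sign_of[g] for g in persistent + specific}

    truth = GroundTruth(
        de_genes_per_stage=de_per_stage,
        module_assignment=module_assignment,
        pathway_module_map={},
    )
    return genes, truth


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, ClinicalTable, GroundTruth]:
    """Draw the count matrix, clinical table, and planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, truth = _plant_structure(config, rng)
    n_genes = config.n_genes

    groups: list[tuple[Stage, str]] = []
    for stage in Stage:
        n = config.group_sizes.get(stage, 0)
        tag = "N" if stage is Stage.NORMAL else f"S{TUMOUR_STAGES.index(stage) + 1}"
        groups += [(stage, f"{tag}_{j:03d}") for j in range(1, n + 1)]
    sample_ids = [sid for _, sid in groups]
    stages = [st for st, _ in groups]

    lo, hi = config.baseline_logmean_range
    base_log = rng.uniform(lo, hi, n_genes)
    s_lo, s_hi = config.library_scale_range
    lib_scale = np.exp(rng.uniform(math.log(s_lo), math.log(s_hi), len(sample_ids)))

    gene_index = {g: i for i, g in enumerate(genes)}
    delta = np.zeros((n_genes, len(sample_ids)))
    for j, stage in enumerate(stages):
        if stage is Stage.NORMAL:
            continue
        for g, sign in truth.de_genes_per_stage[stage].items():
            delta[gene_index[g], j] = sign * config.de_logfc_magnitude * LN2

    mu = np.exp(base_log[:, None] + delta) * lib_scale[None, :]
    phi = config.nb_dispersion
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(pd.DataFrame(counts.astype(np.int64), index=genes, columns=sample_ids))
    clinical = ClinicalTable(
        pd.DataFrame({"sample_id": sample_ids, "stage": stages})
    )
    return cm, clinical, truth


def simulate_interactions(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str, float]]:
    """Planted-module interaction graph.

    Within-module pairs become edges with probability ``p_in`` and a
    confidence drawn from the high range; every other pair becomes a noise
    edge with probability ``p_out`` and a confidence uniform below the
    cross-module cap, so a confidence filter above that cap provably strips
    cross-module noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    width = len(str(config.n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    module_of = np.array([truth.module_assignment.get(g, -1) for g in genes])

    iu, ju = np.triu_indices(len(genes), k=1)
    same = (module_of[iu] >= 0) & (module_of[iu] == module_of[ju])
    prob = np.where(same, config.within_module_edge_prob, config.between_module_edge_prob)
    present = rng.random(len(iu)) < prob

    c_lo, c_hi = config.confidence_high_range
    conf = np.where(
        same,
        rng.uniform(c_lo, c_hi, len(iu)),
        rng.uniform(0.0, config.cross_module_confidence_max, len(iu)),
    )
    return [
        (genes[i], genes[j], float(c))
        for i, j, c in zip(iu[present], ju[present], conf[present])
    ]


def simulate_genesets(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> GeneSetCollection:
    """Pathway gene sets, the first ``n_modules`` aligned one-to-one with modules.

    An aligned pathway draws ``pathway_module_alignment`` of its members
    from its target module and the rest uniformly; surplus pathways are
    uniform draws (unaligned background)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    width = len(str(config.n_genes))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)])
    modules = truth.modules()

    names: dict[str, str] = {}
    sets: dict[str, frozenset[str]] = {}
    pathway_module: dict[str, int] = {}
    for p in range(config.n_pathways):
        pid = f"PW{p + 1:02d}"
        if p < config.n_modules and p in modules:
            members = sorted(modules[p])
            n_from_module = int(round(config.pathway_module_alignment * len(members)))
            chosen = set(rng.choice(members, n_from_module, replace=False))
            n_fill = len(members) - n_from_module
            while len(chosen) < n_from_module + n_fill:
                chosen.add(str(rng.choice(genes)))
            pathway_module[pid] = p
            names[pid] = f"planted pathway for module {p}"
        else:
            size = int(rng.integers(config.pathway_size_range[0], config.pathway_size_range[1] + 1))
            chosen = set(rng.choice(genes, size, replace=False))
            names[pid] = "background pathway"
        sets[pid] = frozenset(str(g) for g in chosen)
    truth.pathway_module_map = pathway_module
    return GeneSetCollection(names=names, sets=sets)


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Counts + clinical + interactions + gene sets from one seed."""
    counts, clinical, truth = simulate_counts(config)
    edges = simulate_interactions(config, truth)
    genesets = simulate_genesets(config, truth)
    return SimulatedDataset(counts, clinical, edges, genesets, truth)


def write_dataset(data: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the standard on-disk form of a simulated dataset."""
    from . import io as snio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "clinical": outdir / "clinical.tsv",
        "interactions": outdir / "interactions.tsv",
        "pathways": outdir / "pathways.gmt",
        "truth": outdir / "truth.json",
    }
    snio.write_counts(data.counts, paths["counts"])
    snio.write_clinical(data.clinical, paths["clinical"])
    snio.write_edge_list(data.edges, paths["interactions"])
    snio.write_gmt(data.genesets, paths["pathways"])
    paths["truth"].write_text(data.truth.to_json(), encoding="utf-8")
    return paths
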