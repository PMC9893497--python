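"""Hypergeometric pathway enrichment per module and per stage.

For a module of ``n`` genes drawn from a universe of ``N``, the overlap
``k`` with a pathway of ``K`` genes is tested against the upper tail of
the hypergeometric distribution, ``p = P(X >= k)``; Benjamini-Hochberg
adjustment runs across the pathways tested within one module. A pathway is
significant in a module when ``FDR < 0.05`` and ``p < 0.05``.

The stage-level summary (one p-value per pathway per stage, the heatmap
input) takes the *minimum* module-level p of that pathway in the stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datatypes import GeneSetCollection, Stage, TUMOUR_STAGES
from .deg import bh_adjust

__all__ = [
    "hypergeom_p",
    "enrich_module",
    "significant_pathways",
    "common_pathways",
    "pathway_stage_matrix",
    "PathwayStageMatrix",
]


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value, ``P(X >= k)``.

    ``k`` overlap genes in a draw of ``n`` from a universe of ``N``
    containing ``K`` pathway genes.
    """
    if not (0 <= k <= min(n, K) <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds: k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def enrich_module(
    module: frozenset[str] | set[str],
    genesets: GeneSetCollection,
    universe: frozenset[str] | set[str],
    include_empty: bool = False,
) -> pd.DataFrame:
    """Enrichment table of one module against all pathways.

    Pathways are restricted to the universe before testing; rows with zero
    overlap are omitted unless ``include_empty``. The ``fdr`` column is BH
    across all pathways tested in this module.
    """
    offenders = set(module) - set(universe)
    if offenders:
        raise ValueError(
            f"module genes outside the universe: {sorted(offenders)[:5]}"
        )
    n = len(module)
    N = len(universe)
    rows = []
    for pid, genes in genesets.items():
        in_universe = genes & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(module & in_universe)
        if k == 0 and not include_empty:
            continue
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": genesets.names.get(pid, pid),
                "overlap": k,
                "module_size": n,
                "pathway_size": K,
                "universe_size": N,
                "p_value": hypergeom_p(k, n, K, N),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "pathway_id",
            "pathway_name",
            "overlap",
            "module_size",
            "pathway_size",
            "universe_size",
            "p_value",
        ],
    )
    df["fdr"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    df["significant"] = (df["fdr"] < 0.05) & (df["p_value"] < 0.05) if len(df) else []
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def significant_pathways(enrichments: list[pd.DataFrame]) -> set[str]:
    """Pathways significant in at least one of the given module tables."""
    out: set[str] = set()
    for df in enrichments:
        out |= set(df.loc[df["significant"], "pathway_id"])
    return out


def common_pathways(per_stage: dict[Stage, set[str]]) -> list[str]:
    """Pathways significant in every stage, ordered by worst-case p.

    ``per_stage`` may carry either plain pathway-id sets or dicts mapping
    pathway id to its stage-level p-value; in the latter case ordering is
    by the maximum p across stages ascending (ties: pathway id).
    """
    stages = list(per_stage)
    if not stages:
        return []
    ids = set.intersection(*(set(per_stage[s]) for s in stages))

    def sort_key(pid: str):
        ps = [
            per_stage[s][pid]
            for s in stages
            if isinstance(per_stage[s], dict)
        ]
        return (max(ps) if ps else 0.0, pid)

    return sorted(ids, key=sort_key)


@dataclass
class PathwayStageMatrix:
    """Pathway x stage grid of best module-level p-values (NaN = untested)."""

    p_values: pd.DataFrame  # index: pathway_id, columns: stage labels

    def neglog10(self) -> pd.DataFrame:
        return -np.log10(self.p_values.clip(lower=np.finfo(float).tiny))

    def clustered(self) -> pd.DataFrame:
        """Rows/columns reordered by average-linkage hierarchical similarity
        of the -log10 p profiles (untested cells treated as p = 1)."""
        mat = self.neglog10().fillna(0.0)
        out = mat
        if len(mat) > 2:
            link = hierarchy.linkage(pdist(mat.to_numpy()), method="average")
            order = hierarchy.leaves_list(link)
            out = out.iloc[order]
        if mat.shape[1] > 2:
            link = hierarchy.linkage(pdist(mat.to_numpy().T), method="average")
            order = hierarchy.leaves_list(link)
            out = out.iloc[:, order]
        return out


def pathway_stage_matrix(
    per_stage_enrichments: dict[Stage, list[pd.DataFrame]],
) -> PathwayStageMatrix:
    """Best (minimum) module-level p per pathway per stage."""
    cells: dict[str, dict[str, float]] = {}
    for stage, tables in per_stage_enrichments.items():
        col = f"S{TUMOUR_STAGES.index(stage) + 1}"
        for df in tables:
            for pid, p in zip(df["pathway_id"], df["p_value"]):
                stage_cells = cells.setdefault(pid, {})
                stage_cells[col] = min(stage_cells.get(col, 1.0), float(p))
    columns = [f"S{TUMOUR_STAGES.index(s) + 1}" for s in per_stage_enrichments]
    mat = pd.DataFrame.from_dict(cells, orient="index").reindex(columns=columns)
    return PathwayStageMatrix(p_values=mat.sort_index())
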