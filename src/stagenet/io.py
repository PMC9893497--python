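"""Readers and writers for the pipeline's tab-delimited file formats.

All formats are plain UTF-8 TSV; lines starting with ``#`` are comments.
Gene identifiers are treated as opaque case-sensitive strings — no symbol
mapping is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .datatypes import ClinicalTable, CountMatrix, GeneSetCollection, Stage

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "read_clinical",
    "write_clinical",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "write_network",
    "read_network",
]


def _data_lines(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count matrix.

    First column holds gene ids, remaining columns per-sample counts; a
    header row with sample ids is required. Row and column order are
    preserved from the file.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        g, s = next(zip(*numeric.isna().to_numpy().nonzero()))
        raise ValueError(
            f"non-numeric count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return CountMatrix(numeric)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a sample annotation table with columns ``sample_id`` and ``stage``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"sample_id", "stage"} - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing column(s): {sorted(missing)}")
    return ClinicalTable(df.loc[:, ["sample_id", "stage"]])


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    out = clinical.table.copy()
    out["stage"] = [s.value for s in out["stage"]]
    out.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a 3-column (gene_a, gene_b, confidence) undirected edge list.

    Reversed duplicates are merged keeping the maximum confidence (the best
    evidence wins); self-loops are dropped with a logged count.
    """
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    n_loops = 0
    for i, line in enumerate(_data_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"line {i}: expected 3 tab-separated fields")
        a, b, conf_s = fields[0], fields[1], fields[2]
        conf = float(conf_s)
        if not 0.0 <= conf <= 1.0:
            raise ValueError(f"line {i}: confidence {conf} outside [0, 1]")
        if a == b:
            n_loops += 1
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in best:
            order.append(key)
            best[key] = conf
        else:
            best[key] = max(best[key], conf)
    if n_loops:
        logger.info("dropped %d self-loop edge(s) from %s", n_loops, path)
    return [(a, b, best[(a, b)]) for a, b in order]


def write_edge_list(edges: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene_a\tgene_b\tconfidence\n")
        for a, b, conf in edges:
            fh.write(f"{a}\t{b}\t{conf:.6g}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read standard GMT: pathway id, description, then member genes.

    Duplicate genes within a set collapse; duplicate pathway ids are an error.
    """
    names: dict[str, str] = {}
    sets: dict[str, frozenset[str]] = {}
    for i, line in enumerate(_data_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"line {i}: GMT line needs at least 3 fields")
        pid, desc, genes = fields[0], fields[1], fields[2:]
        if pid in sets:
            raise ValueError(f"line {i}: duplicate pathway id {pid!r}")
        names[pid] = desc
        sets[pid] = frozenset(g for g in genes if g)
    return GeneSetCollection(names=names, sets=sets)


def write_gmt(genesets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, genes in genesets.items():
            name = genesets.names.get(pid, pid)
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


def write_network(
    graph: nx.Graph,
    path: str | Path,
    relation: str = "interacts",
    weight_attr: str = "confidence",
) -> None:
    """Write a weighted graph as SIF-like TSV plus a companion node table.

    Edge lines are ``a<TAB>relation<TAB>b<TAB>weight``; every node
    (including isolated ones) is listed in ``<path>.nodes``. Re-reading with
    :func:`read_network` reproduces the graph exactly.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#node_a\trelation\tnode_b\t{weight_attr}\n")
        for a, b, d in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{a}\t{relation}\t{b}\t{d.get(weight_attr, 1.0):.10g}\n")
    with open(path.with_suffix(path.suffix + ".nodes"), "w", encoding="utf-8") as fh:
        fh.write("#node\n")
        for node in sorted(graph.nodes, key=str):
            fh.write(f"{node}\n")


def read_network(path: str | Path, weight_attr: str = "confidence") -> nx.Graph:
    """Inverse of :func:`write_network`."""
    path = Path(path)
    g = nx.Graph()
    node_file = path.with_suffix(path.suffix + ".nodes")
    if node_file.exists():
        for line in _data_lines(node_file):
            g.add_node(line.strip())
    for i, line in enumerate(_data_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"line {i}: expected 4 fields in SIF-like file")
        a, _rel, b, w = fields[0], fields[1], fields[2], float(fields[3])
        g.add_edge(a, b, **{weight_attr: w})
    return g
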