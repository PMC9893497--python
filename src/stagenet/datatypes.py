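"""Core containers shared across the pipeline.

Counts, clinical annotation, gene sets and interaction graphs are thin,
validated wrappers around pandas/networkx objects so every downstream module
can rely on their invariants (unique identifiers, non-negative integer
counts, simple graphs) without re-checking them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "TUMOUR_STAGES",
    "CountMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "InteractionNetwork",
]


class Stage(str, enum.Enum):
    """Sample group label: healthy tissue or one of four tumour stages."""

    NORMAL = "normal"
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "Stage":
        try:
            return cls(label)
        except ValueError:
            allowed = ", ".join(s.value for s in cls)
            raise ValueError(
                f"unknown stage label {label!r}; allowed labels: {allowed}"
            ) from None


#: Tumour stages in progression order (adjacency is defined on this order).
TUMOUR_STAGES: tuple[Stage, ...] = (Stage.I, Stage.II, Stage.III, Stage.IV)


@dataclass
class CountMatrix:
    """Gene x sample matrix of raw read counts.

    ``counts`` is a genes-by-samples DataFrame with unique gene ids as the
    index and unique sample ids as columns; cells are non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        values = self.counts.to_numpy()
        if values.size:
            if np.any(values < 0):
                g, s = np.argwhere(values < 0)[0]
                raise ValueError(
                    f"negative count at gene {idx[g]!r}, sample {cols[s]!r}"
                )
            if not np.issubdtype(values.dtype, np.integer):
                if not np.allclose(values, np.round(values)):
                    g, s = np.argwhere(values != np.round(values))[0]
                    raise ValueError(
                        f"non-integer count at gene {idx[g]!r}, sample {cols[s]!r}"
                    )
                self.counts = self.counts.round().astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Per-sample total read count (column sums)."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids), :])


@dataclass
class ClinicalTable:
    """Sample -> stage annotation with unique sample ids."""

    table: pd.DataFrame  # columns: sample_id, stage (Stage values)

    def __post_init__(self) -> None:
        if list(self.table.columns) != ["sample_id", "stage"]:
            self.table = self.table.loc[:, ["sample_id", "stage"]]
        if self.table["sample_id"].duplicated().any():
            dup = self.table["sample_id"][self.table["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        self.table["stage"] = [
            s if isinstance(s, Stage) else Stage.from_label(str(s))
            for s in self.table["stage"]
        ]

    def __len__(self) -> int:
        return len(self.table)

    def samples_for(self, stage: Stage) -> list[str]:
        mask = self.table["stage"] == stage
        return list(self.table.loc[mask, "sample_id"])

    def group_sizes(self) -> dict[Stage, int]:
        return {s: len(self.samples_for(s)) for s in Stage}

    def stages_present(self) -> list[Stage]:
        present = set(self.table["stage"])
        return [s for s in Stage if s in present]


@dataclass
class GeneSetCollection:
    """Named pathway gene sets (GMT content)."""

    names: dict[str, str] = field(default_factory=dict)  # pathway_id -> name
    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set {pid!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id]

    def items(self):
        return self.sets.items()

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    @classmethod
    def from_mapping(
        cls,
        sets: Mapping[str, Iterable[str]],
        names: Mapping[str, str] | None = None,
    ) -> "GeneSetCollection":
        frozen = {pid: frozenset(genes) for pid, genes in sets.items()}
        return cls(names=dict(names or {pid: pid for pid in frozen}), sets=frozen)


@dataclass
class InteractionNetwork:
    """Simple undirected gene graph; edges carry a ``confidence`` in [0, 1].

    ``kind`` distinguishes functional-interaction ("FI") graphs from the
    protein-protein interaction ("PPI") graph; the structure is identical.
    """

    graph: nx.Graph
    kind: str = "FI"

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loop on node {loops[0][0]!r}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        return [
            (a, b, d.get("confidence", 1.0)) for a, b, d in self.graph.edges(data=True)
        ]

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        nodes: Iterable[str] = (),
        kind: str = "FI",
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b, conf in edges:
            g.add_edge(a, b, confidence=float(conf))
        return cls(graph=g, kind=kind)
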