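"""Four-set DEG comparison with regulation-direction classes.

Partitions the union of the four stages' DEG sets into the 15 non-empty
membership regions of a four-set Venn diagram and classifies every gene as
up-, down-, or contra-regulated. A gene is *contra*-regulated iff it is
called up in at least one stage and down in another; a gene up in one
stage and simply absent from another is not contra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datatypes import Stage
from .deg import DEGSet

__all__ = ["VennRegion", "VennResult", "venn_partition"]


@dataclass
class VennRegion:
    """One membership region: the stages a gene is a DEG in."""

    stages: frozenset[Stage]
    genes: frozenset[str]
    class_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class VennResult:
    regions: dict[frozenset[Stage], VennRegion]
    gene_class: dict[str, str]  # gene -> up | down | contra

    @property
    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for region in self.regions.values():
            out |= region.genes
        return frozenset(out)

    def intersection_genes(self, stages: tuple[Stage, ...]) -> frozenset[str]:
        """Genes differentially expressed in every listed stage ("intersection DEGs")."""
        key = frozenset(stages)
        merged: set[str] = set()
        for stages_key, region in self.regions.items():
            if key <= stages_key:
                merged |= region.genes
        return frozenset(merged)

    def class_totals(self) -> dict[str, int]:
        totals = {"up": 0, "down": 0, "contra": 0}
        for cls in self.gene_class.values():
            totals[cls] += 1
        return totals

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stages_key in sorted(
            self.regions, key=lambda k: (-len(k), sorted(s.value for s in k))
        ):
            region = self.regions[stages_key]
            rows.append(
                {
                    "region": "+".join(
                        s.value for s in Stage if s in stages_key
                    ),
                    "n_genes": len(region.genes),
                    **{f"n_{c}": region.class_counts.get(c, 0) for c in ("up", "down", "contra")},
                }
            )
        return pd.DataFrame(rows)


def venn_partition(degsets: list[DEGSet]) -> VennResult:
    """Assign every DEG in the union to exactly one membership region.

    Expects one called-DEG set per distinct stage (normally the four
    tumour stages); direction is taken from each set's own up/down split.
    """
    seen: set[Stage] = set()
    for ds in degsets:
        if ds.stage in seen:
            raise ValueError(f"duplicate stage {ds.stage.value} in input sets")
        seen.add(ds.stage)

    membership: dict[str, set[Stage]] = {}
    directions: dict[str, set[int]] = {}
    for ds in degsets:
        for gene in ds.up:
            membership.setdefault(gene, set()).add(ds.stage)
            directions.setdefault(gene, set()).add(+1)
        for gene in ds.down:
            membership.setdefault(gene, set()).add(ds.stage)
            directions.setdefault(gene, set()).add(-1)

    gene_class = {
        g: "contra" if len(dirs) > 1 else ("up" if +1 in dirs else "down")
        for g, dirs in directions.items()
    }

    regions: dict[frozenset[Stage], VennRegion] = {}
    by_region: dict[frozenset[Stage], set[str]] = {}
    for gene, stages in membership.items():
        by_region.setdefault(frozenset(stages), set()).add(gene)
    for key, genes in by_region.items():
        counts = {"up": 0, "down": 0, "contra": 0}
        for g in genes:
            counts[gene_class[g]] += 1
        regions[key] = VennRegion(stages=key, genes=frozenset(genes), class_counts=counts)
    return VennResult(regions=regions, gene_class=gene_class)
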