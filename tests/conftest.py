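"""Shared fixtures: small deterministic datasets generated in memory."""

import numpy as np
import pandas as pd
import pytest

from stagenet.datatypes import ClinicalTable, CountMatrix, InteractionNetwork, Stage
from stagenet.simulate import SimulationConfig


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            [[1, 2], [3, 4]], index=["gA", "gB"], columns=["s1", "s2"]
        )
    )


@pytest.fixture
def small_clinical() -> ClinicalTable:
    rows = (
        [("n%d" % i, Stage.NORMAL) for i in range(3)]
        + [("a%d" % i, Stage.I) for i in range(3)]
        + [("b%d" % i, Stage.II) for i in range(3)]
        + [("c%d" % i, Stage.III) for i in range(3)]
        + [("d%d" % i, Stage.IV) for i in range(3)]
    )
    return ClinicalTable(pd.DataFrame(rows, columns=["sample_id", "stage"]))


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """Reduced cohort for fast pipeline tests."""
    return SimulationConfig(
        n_genes=400,
        group_sizes={
            Stage.NORMAL: 10,
            Stage.I: 10,
            Stage.II: 12,
            Stage.III: 10,
            Stage.IV: 8,
        },
        n_modules=4,
        module_size_range=(6, 8),
        n_pathways=6,
        de_fraction_per_stage=0.1,
        seed=11,
    )


def random_graph(rng: np.random.Generator, n: int, p: float) -> InteractionNetwork:
    """Erdos-Renyi helper used by several oracle tests."""
    edges = []
    nodes = [f"n{i:02d}" for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((nodes[i], nodes[j], float(rng.uniform(0.5, 1.0))))
    return InteractionNetwork.from_edges(edges, nodes=nodes)
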