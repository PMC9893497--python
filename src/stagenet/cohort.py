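"""Reference TCGA-COAD cohort bookkeeping.

The published TCGA-COAD staging cohort that this pipeline's synthetic data
emulates: 41 normal tissues and 45/109/80/37 tumour samples in stages
I-IV. Pooling the normals with each stage gives the four differential-
expression comparison cohorts ("DE sets"). The clinical-characteristics
frequency table of the same cohort is kept here so its percentages can be
recomputed from the raw frequencies.
"""

from __future__ import annotations

from .datatypes import Stage, TUMOUR_STAGES

__all__ = [
    "REFERENCE_GROUP_SIZES",
    "CLINICAL_CHARACTERISTICS",
    "CLINICAL_TABLE_TOTAL",
    "de_set_sizes",
    "tumour_sample_total",
    "processed_sample_total",
    "characteristic_percentages",
]

#: Samples per group in the reference cohort.
REFERENCE_GROUP_SIZES: dict[Stage, int] = {
    Stage.NORMAL: 41,
    Stage.I: 45,
    Stage.II: 109,
    Stage.III: 80,
    Stage.IV: 37,
}

#: Total rows of the published clinical-characteristics table.
CLINICAL_TABLE_TOTAL = 323

#: (group, subgroup) -> frequency in the published characteristics table.
CLINICAL_CHARACTERISTICS: dict[tuple[str, str], int] = {
    ("age", "<60"): 101,
    ("age", ">=60"): 222,
    ("gender", "male"): 173,
    ("gender", "female"): 150,
    ("histology", "adenocarcinoma"): 282,
    ("histology", "mucinous_adenocarcinoma"): 41,
    ("stage", "I"): 49,
    ("stage", "II"): 132,
    ("stage", "III"): 87,
    ("stage", "IV"): 44,
    ("t_stage", "Tis_T1-3"): 278,
    ("t_stage", "T4"): 45,
    ("n_stage", "N0"): 194,
    ("n_stage", "N1_N2"): 129,
    ("m_stage", "MX_M0"): 274,
    ("m_stage", "M1"): 44,
    ("vital", "alive"): 244,
    ("vital", "dead"): 79,
}


def de_set_sizes(group_sizes: dict[Stage, int] | None = None) -> dict[Stage, int]:
    """Comparison-cohort size per stage: stage samples plus all normals."""
    sizes = group_sizes or REFERENCE_GROUP_SIZES
    n_normal = sizes[Stage.NORMAL]
    return {s: sizes[s] + n_normal for s in TUMOUR_STAGES if s in sizes}


def tumour_sample_total(group_sizes: dict[Stage, int] | None = None) -> int:
    """Total tumour samples = sum of the four stage group sizes."""
    sizes = group_sizes or REFERENCE_GROUP_SIZES
    return sum(sizes[s] for s in TUMOUR_STAGES if s in sizes)


def processed_sample_total(group_sizes: dict[Stage, int] | None = None) -> int:
    """Total analysed samples = tumour samples plus normals."""
    sizes = group_sizes or REFERENCE_GROUP_SIZES
    return tumour_sample_total(sizes) + sizes[Stage.NORMAL]


def characteristic_percentages(
    frequencies: dict[tuple[str, str], int] | None = None,
    total: int | None = None,
) -> dict[tuple[str, str], float]:
    """Percentage of each clinical subgroup relative to the table total."""
    freqs = frequencies or CLINICAL_CHARACTERISTICS
    n = total or CLINICAL_TABLE_TOTAL
    return {key: 100.0 * count / n for key, count in freqs.items()}
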