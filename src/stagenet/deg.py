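"""Stage-wise differential expression against pooled normal controls.

The classic count-based DE workflow for a two-group comparison:

1. each tumour stage is pooled with *all* normal samples into one
   comparison cohort ("DE set");
2. lowly expressed genes are removed on a counts-per-million (CPM) cutoff;
3. between-sample normalization uses the trimmed mean of M-values (TMM):
   a per-sample scaling factor computed from a doubly trimmed,
   inverse-variance-weighted mean of gene-wise log-ratios of library
   proportions against a reference sample;
4. a single common negative-binomial dispersion ``phi`` (``var = mu +
   phi*mu**2``) is estimated by maximizing the conditional likelihood on
   quantile-adjusted pseudo-counts, i.e. counts mapped to a common library
   size so group totals are sufficient statistics;
5. each gene gets a two-sided exact test: conditional on the gene's total,
   the tumour group sum follows a beta-binomial (binomial when ``phi = 0``)
   and the p-value sums the probabilities of all outcomes no more likely
   than the observed one;
6. Benjamini-Hochberg adjustment, then genes with ``FDR < 0.05`` and
   ``|log2 fold change| >= 1`` are called differentially expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import ClinicalTable, CountMatrix, Stage, TUMOUR_STAGES

__all__ = [
    "DESetDesign",
    "NormalizationState",
    "DEGSet",
    "build_de_sets",
    "cpm",
    "filter_low_expression",
    "tmm_factors",
    "estimate_common_dispersion",
    "exact_test",
    "bh_adjust",
    "call_degs",
    "run_stage_de",
]


@dataclass
class DESetDesign:
    """One stage-vs-control comparison cohort."""

    stage: Stage
    tumour_samples: list[str]
    control_samples: list[str]

    def __post_init__(self) -> None:
        if set(self.tumour_samples) & set(self.control_samples):
            raise ValueError("tumour and control samples overlap")

    @property
    def total_n(self) -> int:
        return len(self.tumour_samples) + len(self.control_samples)

    @property
    def samples(self) -> list[str]:
        return self.tumour_samples + self.control_samples


@dataclass
class NormalizationState:
    """TMM factors and the effective library sizes they imply."""

    tmm_factor: pd.Series
    effective_library_size: pd.Series

    def __post_init__(self) -> None:
        if (self.tmm_factor <= 0).any():
            raise ValueError("TMM factors must be positive")


@dataclass
class DEGSet:
    """Called DEGs of one stage, split by regulation direction."""

    stage: Stage
    up: frozenset[str]
    down: frozenset[str]
    logfc_map: dict[str, float]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down


def build_de_sets(clinical: ClinicalTable) -> dict[Stage, DESetDesign]:
    """One comparison design per tumour stage present; controls = all normals."""
    normals = clinical.samples_for(Stage.NORMAL)
    if len(normals) < 2:
        raise ValueError(f"need >=2 normal samples, found {len(normals)}")
    designs: dict[Stage, DESetDesign] = {}
    for stage in TUMOUR_STAGES:
        tumour = clinical.samples_for(stage)
        if not tumour:
            continue
        if len(tumour) < 2:
            raise ValueError(f"stage {stage.value} has {len(tumour)} sample(s); need >=2")
        designs[stage] = DESetDesign(stage, tumour, list(normals))
    return designs


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million: each column rescaled to sum to 1e6."""
    lib = counts.library_sizes()
    if (lib == 0).any():
        zero = lib.index[lib == 0][0]
        raise ValueError(f"sample {zero!r} has zero library size")
    return counts.counts / lib * 1e6


def filter_low_expression(
    counts: CountMatrix, cpm_threshold: float = 1.0, min_samples: int = 2
) -> CountMatrix:
    """Keep genes with CPM above threshold in at least ``min_samples`` samples."""
    if cpm_threshold <= 0 or min_samples <= 0:
        raise ValueError("thresholds must be positive")
    keep = (cpm(counts) > cpm_threshold).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            "all genes filtered out; lower cpm_threshold or min_samples"
        )
    return CountMatrix(counts.counts.loc[keep])


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> float:
    """log2 TMM factor of one sample against the reference.

    M-values (log2 ratio of library-relative proportions) are trimmed by
    their own ranks and by abundance (A-value) ranks, then averaged with
    inverse asymptotic-binomial-variance weights.
    """
    both = (obs > 0) & (ref > 0)
    obs_p = obs[both] / lib_obs
    ref_p = ref[both] / lib_ref
    m = np.log2(obs_p / ref_p)
    a = 0.5 * (np.log2(obs_p) + np.log2(ref_p))
    # delta-method variance of M from binomial sampling in both samples
    v = (lib_obs - obs[both]) / (lib_obs * obs[both]) + (lib_ref - ref[both]) / (
        lib_ref * ref[both]
    )
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))


def tmm_factors(
    counts: CountMatrix,
    reference: str | None = None,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> NormalizationState:
    """TMM normalization factors, rescaled to geometric mean 1.

    The reference defaults to the sample whose 75th count-proportion
    percentile is closest to the mean of those percentiles.
    """
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    y = counts.counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    if reference is None:
        f75 = np.percentile(y, 75, axis=0) / lib
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.sample_ids.index(reference)
    ref_col = y[:, ref_idx]
    log_factors = np.zeros(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref_idx:
            continue
        if not np.any((y[:, j] > 0) & (ref_col > 0)):
            raise ValueError(
                f"sample {counts.sample_ids[j]!r} shares no expressed genes "
                "with the reference"
            )
        log_factors[j] = _tmm_pair(
            y[:, j], ref_col, lib[j], lib[ref_idx], logratio_trim, abundance_trim
        )
    factors = 2.0 ** (log_factors - log_factors.mean())
    tmm = pd.Series(factors, index=counts.sample_ids)
    eff = pd.Series(lib * factors, index=counts.sample_ids)
    return NormalizationState(tmm_factor=tmm, effective_library_size=eff)


# ---------------------------------------------------------------------------
# quantile-adjusted pseudo-counts (equalized library sizes)
# ---------------------------------------------------------------------------


def _fit_group_means(
    y: np.ndarray, offsets: np.ndarray, phi: float, max_iter: int = 50, tol: float = 1e-10
) -> np.ndarray:
    """Per-gene NB log-rate (intercept-only log-link fit with offsets).

    Newton iteration on the concave per-gene log-likelihood; errors out if
    any gene fails to converge within ``max_iter`` steps.
    """
    total = y.sum(axis=1)
    denom = np.exp(offsets).sum()
    with np.errstate(divide="ignore"):
        beta = np.log(total / denom)
    active = total > 0
    for it in range(max_iter):
        mu = np.exp(beta[active, None] + offsets[None, :])
        w = 1.0 + phi * mu
        score = ((y[active] - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = score / info
        beta[active] = beta[active] + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise RuntimeError(
            f"group-mean fit did not converge within {max_iter} iterations"
        )
    return beta


def _q2q_nbinom(
    x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray, phi: float
) -> np.ndarray:
    """Quantile-map counts between NB distributions of equal dispersion.

    Averages a normal and a gamma continuous approximation of the NB tail,
    matching the observation's tail probability at the input mean to the
    same tail probability at the output mean.
    """
    eps = 1e-14
    input_mean = np.where(input_mean < eps, input_mean + 0.25, input_mean)
    output_mean = np.where(output_mean < eps, output_mean + 0.25, output_mean)
    r_in = 1.0 + phi * input_mean
    r_out = 1.0 + phi * output_mean
    sd_in = np.sqrt(input_mean * r_in)
    sd_out = np.sqrt(output_mean * r_out)
    upper = x >= input_mean

    out = np.empty_like(x, dtype=float)
    # normal approximation, log-space to survive extreme tails
    z = (x - input_mean) / sd_in
    logp_hi = stats.norm.logsf(z)
    logp_lo = stats.norm.logcdf(z)
    q_norm = np.where(
        upper,
        output_mean - sd_out * special.ndtri_exp(logp_hi),
        output_mean + sd_out * special.ndtri_exp(logp_lo),
    )
    # gamma approximation (shape = mean/r, scale = r keeps the variance)
    shape_in = input_mean / r_in
    shape_out = output_mean / r_out
    tiny = np.finfo(float).tiny
    p_hi = np.clip(special.gammaincc(shape_in, x / r_in), tiny, 1.0)
    p_lo = np.clip(special.gammainc(shape_in, x / r_in), tiny, 1.0)
    q_gamma = np.where(
        upper,
        special.gammainccinv(shape_out, p_hi) * r_out,
        special.gammaincinv(shape_out, p_lo) * r_out,
    )
    out = 0.5 * (q_norm + q_gamma)
    return np.maximum(out, 0.0)


def _equalize_lib_sizes(
    y: np.ndarray, groups: np.ndarray, lib: np.ndarray, phi: float
) -> tuple[np.ndarray, float]:
    """Map counts to pseudo-counts at a common (geometric-mean) library size."""
    common_lib = float(np.exp(np.mean(np.log(lib))))
    pseudo = np.empty_like(y, dtype=float)
    for g in np.unique(groups):
        cols = groups == g
        beta = _fit_group_means(y[:, cols], np.log(lib[cols]), phi)
        lam = np.exp(beta)
        input_mean = lam[:, None] * lib[cols][None, :]
        output_mean = np.repeat(lam[:, None] * common_lib, cols.sum(), axis=1)
        pseudo[:, cols] = _q2q_nbinom(y[:, cols], input_mean, output_mean, phi)
    return pseudo, common_lib


def _conditional_loglik(pseudo: np.ndarray, groups: np.ndarray, phi: float) -> float:
    """Common NB conditional log-likelihood over genes and groups.

    With equal library sizes the group total is sufficient; terms not
    involving ``phi`` are dropped.
    """
    inv = 1.0 / phi
    total = 0.0
    for g in np.unique(groups):
        yg = pseudo[:, groups == g]
        n = yg.shape[1]
        z = yg.sum(axis=1)
        total += float(
            special.gammaln(yg + inv).sum()
            + len(z) * special.gammaln(n * inv)
            - special.gammaln(z + n * inv).sum()
            - len(z) * n * special.gammaln(inv)
        )
    return total


def estimate_common_dispersion(
    counts: CountMatrix,
    design: DESetDesign,
    norm: NormalizationState,
    grid: tuple[float, float, int] = (1e-4, 10.0, 25),
) -> float:
    """Common dispersion ``phi`` by conditional ML on pseudo-counts.

    Pseudo-counts and the dispersion estimate are alternated twice (the
    pseudo-count map itself depends on ``phi``); the conditional likelihood
    is maximized on a log-spaced grid followed by bounded refinement.
    Returns 0 when the likelihood is maximized at the lower boundary.
    """
    samples = design.samples
    y = counts.counts.loc[:, samples].to_numpy(dtype=float)
    groups = np.array(
        [0 if s in set(design.tumour_samples) else 1 for s in samples]
    )
    if min(np.bincount(groups)) < 2:
        raise ValueError("need >=2 samples per group to estimate dispersion")
    lib = norm.effective_library_size.loc[samples].to_numpy(dtype=float)

    phi = 0.01
    for _ in range(2):
        pseudo, _ = _equalize_lib_sizes(y, groups, lib, phi)
        lo, hi, n_grid = grid
        phis = np.geomspace(lo, hi, n_grid)
        lls = np.array([_conditional_loglik(pseudo, groups, p) for p in phis])
        best = int(np.argmax(lls))
        if best == 0:
            return 0.0
        lo_b = phis[max(best - 1, 0)]
        hi_b = phis[min(best + 1, n_grid - 1)]
        res = optimize.minimize_scalar(
            lambda p: -_conditional_loglik(pseudo, groups, p),
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": 1e-6},
        )
        phi = float(res.x)
    return phi


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------


def _conditional_logpmf_tables(
    max_total: int, a_tumour: float, a_control: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute gammaln tables reused across genes."""
    s = np.arange(max_total + 1, dtype=float)
    return (
        special.gammaln(s + a_tumour),
        special.gammaln(s + a_control),
        special.gammaln(s + 1.0),
    )


def exact_test(
    counts: CountMatrix,
    design: DESetDesign,
    norm: NormalizationState,
    phi: float,
    prior_count: float = 0.125,
    big_total: int = 2_000_000,
) -> pd.DataFrame:
    """Two-sided exact NB test per gene on equalized pseudo-counts.

    Conditional on a gene's (rounded) pseudo-count total ``z``, the tumour
    group sum is beta-binomial with weights ``n_tumour/phi`` and
    ``n_control/phi`` (binomial with ``p = n_tumour/n`` when ``phi = 0``);
    the p-value sums all outcome probabilities no more likely than the
    observed one (ties within 1e-12 relative tolerance count). The log2
    fold change uses prior-count-damped normalized group means. Totals
    beyond ``big_total`` fall back to a normal approximation with the
    smaller tail doubled.
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    samples = design.samples
    y = counts.counts.loc[:, samples].to_numpy(dtype=float)
    tumour_mask = np.array([s in set(design.tumour_samples) for s in samples])
    groups = np.where(tumour_mask, 0, 1)
    lib = norm.effective_library_size.loc[samples].to_numpy(dtype=float)

    pseudo, common_lib = _equalize_lib_sizes(y, groups, lib, phi)
    n_t = int(tumour_mask.sum())
    n_c = int((~tumour_mask).sum())
    s_t = np.round(pseudo[:, tumour_mask].sum(axis=1)).astype(np.int64)
    s_c = np.round(pseudo[:, ~tumour_mask].sum(axis=1)).astype(np.int64)
    z = s_t + s_c

    if phi > 0:
        a_t, a_c = n_t / phi, n_c / phi
    else:
        a_t = a_c = None  # binomial branch
    frac_t = n_t / (n_t + n_c)

    max_small = int(min(z.max(initial=0), big_total))
    if phi > 0:
        gl_t, gl_c, gl_f = _conditional_logpmf_tables(max_small, a_t, a_c)
    else:
        gl_f = special.gammaln(np.arange(max_small + 1, dtype=float) + 1.0)

    p_values = np.ones(counts.n_genes)
    log_tie = math.log1p(1e-12)
    for i in range(counts.n_genes):
        zi, si = int(z[i]), int(s_t[i])
        if zi == 0:
            continue
        if zi <= big_total:
            s_all = np.arange(zi + 1)
            if phi > 0:
                lp = (
                    gl_t[: zi + 1]
                    + gl_c[zi::-1]
                    - gl_f[: zi + 1]
                    - gl_f[zi::-1]
                )
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    lp = (
                        s_all * math.log(frac_t)
                        + (zi - s_all) * math.log(1 - frac_t)
                        - gl_f[: zi + 1]
                        - gl_f[zi::-1]
                    )
            lp -= special.logsumexp(lp)
            mask = lp <= lp[si] + log_tie
            p_values[i] = min(1.0, float(np.exp(special.logsumexp(lp[mask]))))
        else:
            # normal approximation with overdispersion factor of the
            # beta-binomial; smaller tail doubled
            mean = zi * frac_t
            var = zi * frac_t * (1 - frac_t)
            if phi > 0:
                var *= (a_t + a_c + zi) / (a_t + a_c + 1)
            sd = math.sqrt(var)
            lo_tail = stats.norm.cdf(si + 0.5, mean, sd)
            hi_tail = stats.norm.sf(si - 0.5, mean, sd)
            p_values[i] = min(1.0, 2.0 * min(lo_tail, hi_tail))

    mean_t = s_t / n_t
    mean_c = s_c / n_c
    logfc = np.log2(mean_t + prior_count) - np.log2(mean_c + prior_count)
    logcpm = np.log2((z + 2 * prior_count) / ((n_t + n_c) * common_lib) * 1e6)

    return pd.DataFrame(
        {
            "gene": counts.gene_ids,
            "logFC": logfc,
            "logCPM": logcpm,
            "p_value": p_values,
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; order of the input is preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    fdr_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = np.minimum(fdr_sorted, 1.0)
    return fdr


def call_degs(
    results: pd.DataFrame,
    stage: Stage,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> DEGSet:
    """Call DEGs: strict ``fdr < fdr_cut``, non-strict ``|logFC| >= lfc_cut``."""
    sig = results["fdr"] < fdr_cut
    up = frozenset(results.loc[sig & (results["logFC"] >= lfc_cut), "gene"])
    down = frozenset(results.loc[sig & (results["logFC"] <= -lfc_cut), "gene"])
    logfc_map = dict(zip(results["gene"], results["logFC"]))
    return DEGSet(stage=stage, up=up, down=down, logfc_map=logfc_map)


def run_stage_de(
    counts: CountMatrix,
    clinical: ClinicalTable,
    stage: Stage,
    cpm_threshold: float = 1.0,
    min_samples: int | None = None,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> tuple[pd.DataFrame, DEGSet, float]:
    """Full single-stage DE analysis; returns (results, called set, phi).

    ``min_samples`` for the CPM filter defaults to the smaller group size.
    """
    design = build_de_sets(clinical)[stage]
    sub = counts.subset_samples(design.samples)
    if min_samples is None:
        min_samples = min(len(design.tumour_samples), len(design.control_samples))
    filtered = filter_low_expression(sub, cpm_threshold, min_samples)
    norm = tmm_factors(filtered)
    phi = estimate_common_dispersion(filtered, design, norm)
    results = exact_test(filtered, design, norm, phi)
    results["fdr"] = bh_adjust(results["p_value"].to_numpy())
    degset = call_degs(results, stage, fdr_cut, lfc_cut)
    results["is_de"] = [g in degset.genes for g in results["gene"]]
    return results, degset, phi
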