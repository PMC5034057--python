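"""Normalisation, FPKM and negative-binomial differential expression calling.

Each treatment condition is contrasted against the normoxic reference with a
transparent NB Wald test: median-of-ratios size factors, method-of-moments
dispersion estimates shrunk toward a trimmed global mean, a delta-method
variance for the log2 ratio of group means, a two-sided normal p-value and
Benjamini-Hochberg adjustment. Regulated genes are called at q < 0.05 and
linear fold change > 2 (directionally), the conventional thresholds for this
kind of contrast design.

The implementation is deliberately simple and fully vectorised: no GLM
covariates, no fold-change shrinkage, no exact tests. It is intended to be
auditable and deterministic, and is sufficient for set-level downstream
analyses (overlap, clustering, enrichment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, GeneSet, SampleTable

__all__ = [
    "NormalizationResult",
    "ExpressionMatrix",
    "estimate_size_factors",
    "compute_fpkm",
    "log_expression",
    "estimate_dispersions",
    "nb_contrast_test",
    "bh_adjust",
    "call_regulated",
    "de_analysis",
]

_LN2_SQ = math.log(2.0) ** 2


@dataclass(frozen=True)
class NormalizationResult:
    """Per-sample size factors (geometric mean 1) plus a method tag."""

    size_factors: pd.Series
    method: str = "median-of-ratios"

    def __post_init__(self) -> None:
        s = self.size_factors.to_numpy(dtype=float)
        if np.any(s <= 0):
            raise ValueError("size factors must be positive")
        log_gmean = np.mean(np.log(s))
        if abs(log_gmean) > 1e-6:
            raise ValueError("size factors must have geometric mean 1")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued expression (FPKM or log2(FPKM + c)) per gene x sample."""

    values: pd.DataFrame
    unit: str = "FPKM"
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if self.unit == "FPKM" and np.any(v < 0):
            raise ValueError("FPKM values must be non-negative")
        if not np.all(np.isfinite(v)):
            raise ValueError("expression values must be finite")


def estimate_size_factors(counts: CountMatrix) -> NormalizationResult:
    """Median-of-ratios size factors.

    For genes with a positive geometric mean across samples (i.e. no zero
    count), s_j is the median over genes of count_gj / geomean_g; the factors
    are then rescaled to geometric mean 1.
    """
    x = counts.counts.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "cannot compute median-of-ratios size factors"
        )
    logx = np.log(x[all_positive])
    log_gmean = logx.mean(axis=1)
    ratios = np.exp(logx - log_gmean[:, None])
    s = np.median(ratios, axis=0)
    if np.any(s <= 0):
        bad = counts.sample_ids[np.flatnonzero(s <= 0)].tolist()
        raise ValueError(f"non-positive size factor for samples: {bad}")
    s = s / np.exp(np.mean(np.log(s)))
    return NormalizationResult(pd.Series(s, index=counts.sample_ids, name="size_factor"))


def compute_fpkm(
    counts: CountMatrix, mapped_totals: pd.Series | Mapping[str, float] | None = None
) -> ExpressionMatrix:
    """FPKM_gj = count_gj * 1e9 / (length_g * total_j).

    ``mapped_totals`` defaults to per-sample column sums.
    """
    if counts.gene_lengths is None:
        raise ValueError("gene lengths are required to compute FPKM")
    if mapped_totals is None:
        totals = counts.counts.sum(axis=0).astype(float)
    else:
        totals = pd.Series(mapped_totals, dtype=float).reindex(counts.sample_ids)
        if totals.isna().any():
            raise ValueError("mapped_totals missing for some samples")
    if (totals <= 0).any():
        raise ValueError("mapped totals must be positive")
    fpkm = (
        counts.counts.to_numpy(dtype=float)
        * 1e9
        / (counts.gene_lengths.to_numpy()[:, None] * totals.to_numpy()[None, :])
    )
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.gene_ids, columns=counts.sample_ids), unit="FPKM"
    )


def log_expression(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(FPKM + pseudocount), the transform used for sample clustering."""
    if expr.unit != "FPKM":
        raise ValueError(f"expected FPKM input, got unit {expr.unit!r}")
    return ExpressionMatrix(
        np.log2(expr.values + pseudocount),
        unit=f"log2(FPKM+{pseudocount:g})",
        pseudocount=pseudocount,
    )


def estimate_dispersions(
    counts: CountMatrix,
    norm: NormalizationResult,
    samples: SampleTable,
    alpha_floor: float = 1e-4,
    genewise_weight: float = 0.3,
    trim: float = 0.01,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments with conservative sharing.

    The raw estimate is max(alpha_floor, (v - m) / m^2) where v is the pooled
    within-condition variance of normalised counts and m their mean over the
    replicated conditions. Because at 2-3 replicates the per-gene estimate is
    nearly information-free, it keeps only ``genewise_weight`` of the weight,
    the remainder going to the trimmed global mean of the raw estimates — and
    the result is never allowed below that global value (per-gene information
    can raise a dispersion, not lower it). This asymmetric sharing removes
    the anticonservative coupling between a by-chance small within-group
    spread and the Wald statistic at low replication. ``genewise_weight=1``
    disables sharing entirely. The trim is light (1% per tail) because the
    sampling distribution of the raw estimator is strongly right-skewed and
    heavier trimming biases its centre down.
    """
    if not 0.0 <= genewise_weight <= 1.0:
        raise ValueError("genewise_weight must be in [0, 1]")
    samples.validate_against(counts)
    x = counts.counts[samples.sample_ids].to_numpy(dtype=float)
    x = x / norm.size_factors.reindex(samples.sample_ids).to_numpy()[None, :]
    condition = samples.table["condition"].to_numpy()

    ss = np.zeros(counts.n_genes)  # pooled within-condition sum of squares
    total = np.zeros(counts.n_genes)
    df = 0
    n_used = 0
    for cond in dict.fromkeys(condition):
        cols = np.flatnonzero(condition == cond)
        if cols.size < 2:
            continue
        sub = x[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        total += sub.sum(axis=1)
        df += cols.size - 1
        n_used += cols.size
    if df == 0:
        raise ValueError("dispersion estimation requires >= 2 replicates in some condition")
    v = ss / df
    m = total / n_used
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - m) / m**2
    raw = np.where(m > 0, raw, alpha_floor)
    raw = np.maximum(raw, alpha_floor)
    global_alpha = float(stats.trim_mean(raw, trim))
    alpha = genewise_weight * raw + (1.0 - genewise_weight) * global_alpha
    if genewise_weight < 1.0:
        alpha = np.maximum(alpha, global_alpha)
    alpha = np.maximum(alpha, alpha_floor)
    return pd.Series(alpha, index=counts.gene_ids, name="alpha")


def nb_contrast_test(
    counts: CountMatrix,
    norm: NormalizationResult,
    dispersions: pd.Series,
    samples: SampleTable,
    condition: str,
    reference: str = "normoxia",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Wald test of one condition against the reference.

    log2FC = log2((m_t + c) / (m_r + c)) from normalised group means with
    pseudocount c. The variance of each group's log2 mean is delta-method:
    (m + alpha*m^2) / (n * (m + c)^2 * ln^2 2); the Wald statistic is referred
    to a standard normal. Identical groups give log2FC = 0 and p = 1 exactly.
    """
    samples.validate_against(counts)
    t_cols = samples.samples_for(condition)
    r_cols = samples.samples_for(reference)
    s = norm.size_factors
    xt = (counts.counts[t_cols] / s[t_cols]).to_numpy(dtype=float)
    xr = (counts.counts[r_cols] / s[r_cols]).to_numpy(dtype=float)
    mt, mr = xt.mean(axis=1), xr.mean(axis=1)
    alpha = dispersions.reindex(counts.gene_ids).to_numpy(dtype=float)

    log2fc = np.log2((mt + pseudocount) / (mr + pseudocount))

    def var_log2_mean(m: np.ndarray, n: int) -> np.ndarray:
        return (m + alpha * m**2) / (n * (m + pseudocount) ** 2 * _LN2_SQ)

    se = np.sqrt(var_log2_mean(mt, len(t_cols)) + var_log2_mean(mr, len(r_cols)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "baseMean": np.concatenate([xt, xr], axis=1).mean(axis=1),
            "log2FC": log2fc,
            "alpha": alpha,
            "stat": z,
            "pvalue": p,
            "condition": condition,
            "reference": reference,
        },
        index=counts.gene_ids,
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_regulated(
    de: pd.DataFrame,
    fdr: float = 0.05,
    min_fc: float = 2.0,
    direction: str = "up",
    name: str | None = None,
) -> GeneSet:
    """Genes passing the q < fdr and linear |FC| > min_fc gates, one direction.

    ``direction`` is "up" (log2FC > log2 min_fc), "down" (log2FC < -log2
    min_fc) or "both" (the union).
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"invalid direction {direction!r}; use 'up', 'down' or 'both'")
    if "qvalue" not in de.columns:
        raise ValueError("DE table lacks a 'qvalue' column; run bh_adjust first")
    cut = math.log2(min_fc)
    sig = de["qvalue"] < fdr
    if direction == "up":
        sel = sig & (de["log2FC"] > cut)
    elif direction == "down":
        sel = sig & (de["log2FC"] < -cut)
    else:
        sel = sig & (de["log2FC"].abs() > cut)
    if name is None:
        cond = de["condition"].iloc[0] if "condition" in de.columns and len(de) else "contrast"
        name = f"{cond}_{direction}"
    return GeneSet(name, de.index[sel])


def de_analysis(
    counts: CountMatrix,
    samples: SampleTable,
    conditions: Sequence[str] | None = None,
    reference: str = "normoxia",
    fdr: float = 0.05,
    min_fc: float = 2.0,
    pseudocount: float = 0.5,
    alpha_floor: float = 1e-4,
    genewise_weight: float = 0.3,
) -> dict[str, pd.DataFrame]:
    """Run every condition-vs-reference contrast: normalise, estimate
    dispersions, test, BH-adjust per contrast and flag calls.

    Returns a mapping from condition label to a complete DE table with
    columns baseMean, log2FC, alpha, stat, pvalue, qvalue, significant.
    """
    samples.validate_against(counts)
    if conditions is None:
        conditions = [c for c in samples.conditions if c != reference]
    if reference not in samples.conditions:
        raise ValueError(f"reference condition {reference!r} not in sample table")
    norm = estimate_size_factors(counts)
    alpha = estimate_dispersions(
        counts, norm, samples, alpha_floor=alpha_floor, genewise_weight=genewise_weight
    )
    cut = math.log2(min_fc)
    out: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        de = nb_contrast_test(
            counts, norm, alpha, samples, cond, reference=reference, pseudocount=pseudocount
        )
        de["qvalue"] = bh_adjust(de["pvalue"].to_numpy())
        de["significant"] = (de["qvalue"] < fdr) & (de["log2FC"].abs() > cut)
        out[cond] = de
    return out
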