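"""Negative-binomial differential-expression engine.

A self-contained analog of the standard count-based DE pipeline: per-sample
size factors by the median-of-ratios estimator, per-gene NB dispersion by
method of moments, a Wald test on the log2 fold change between two
condition levels, and Benjamini-Hochberg adjustment of the raw p values.

The model for the count of gene g in sample j is

    c_gj ~ NB(mean = s_j * q_g(level(j)),  variance = mu + alpha_g * mu^2)

where ``s_j`` is the sample's size factor, ``q_g(level)`` the normalized
level mean and ``alpha_g`` the gene-wise dispersion.  This is deliberately
a simplified engine: no dispersion-trend shrinkage, no fold-change
shrinkage, no independent filtering and no outlier refitting.  Results
from an external DE tool can be substituted anywhere downstream through
:func:`read_de_result` (the TSV column names are DESeq2-compatible).

Because the gene-wise dispersion is estimated from the handful of samples
of a single experiment and plugged into the Wald standard error, the Wald
statistic is referred to a t distribution with the residual degrees of
freedom (n - number of levels) rather than a standard normal; with a
normal reference the plug-in noise makes small-sample p values visibly
anti-conservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegreesOfFreedomError, DesignError, DomainError
from .matrix import CountMatrix

__all__ = [
    "DesignSpec",
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "adjust_bh",
    "select_genes",
    "read_de_result",
    "write_de_result",
]

#: Column order of a DE result table (DESeq2-compatible names).
DE_COLUMNS = ["baseMean", "log2FoldChange", "dispersion", "pvalue", "padj"]


@dataclass(frozen=True)
class DesignSpec:
    """A one-factor design: which label each sample carries.

    ``factor`` names the modelled factor — ``"condition"`` for the
    two-group comparison (biological variance), ``"replicate_id"`` when
    technical replicates of the same biological samples are the levels
    (technical variance).  A condition design must have exactly two levels.
    """

    factor: str
    levels: tuple[str, ...]

    def __init__(self, factor: str, levels: Sequence[str]):
        object.__setattr__(self, "factor", factor)
        object.__setattr__(self, "levels", tuple(str(x) for x in levels))
        uniq = self.unique_levels()
        if len(uniq) < 2:
            raise DesignError(f"design needs >= 2 levels, got {uniq}")
        if factor == "condition" and len(uniq) != 2:
            raise DesignError(
                f"condition design must have exactly 2 levels, got {uniq}"
            )

    def unique_levels(self) -> list[str]:
        """Distinct levels in sorted order; the first is the reference
        level (alphabetical, as in DESeq2's default factor ordering)."""
        return sorted(set(self.levels))

    @classmethod
    def condition(cls, matrix: CountMatrix) -> "DesignSpec":
        """The two-group condition design read off a matrix's group labels."""
        return cls("condition", tuple(matrix.groups))


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, one positive real per sample.

    For each sample, the factor is the median over genes (restricted to
    genes with positive counts in every sample, so the geometric mean is
    positive) of count / geometric-mean-across-samples.  If no gene is
    positive everywhere the estimator falls back to total-count scaling
    (column sums divided by their geometric mean) with a warning.
    """
    values = matrix.values.astype(float)
    all_positive = (values > 0).all(axis=1)
    if all_positive.any():
        pos = values[all_positive]
        geo_mean = np.exp(np.log(pos).mean(axis=1, keepdims=True))
        sf = np.median(pos / geo_mean, axis=0)
    else:
        warnings.warn(
            "no gene has positive counts in all samples; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = values.sum(axis=0)
        if (totals <= 0).any():
            raise DomainError("a sample has zero total counts")
        sf = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(sf, index=matrix.sample_ids, name="size_factor")


def _level_design(matrix: CountMatrix, design: DesignSpec) -> list[np.ndarray]:
    if len(design.levels) != matrix.n_samples:
        raise DesignError(
            f"design has {len(design.levels)} labels for "
            f"{matrix.n_samples} samples"
        )
    codes = np.asarray(design.levels)
    masks = [codes == lvl for lvl in design.unique_levels()]
    for lvl, mask in zip(design.unique_levels(), masks):
        if not mask.any():
            raise DesignError(f"design level {lvl!r} has zero samples")
    return masks


def estimate_dispersions(matrix: CountMatrix, design: DesignSpec) -> pd.Series:
    """Gene-wise NB dispersion alpha (variance = mu + alpha * mu^2).

    Method of moments on size-factor-normalized counts with level means
    removed: the pooled within-level variance ``s^2`` minus the expected
    shot-noise contribution ``xi * mu`` (``xi`` = mean reciprocal size
    factor) is divided by ``mu^2``, then truncated at zero.  Genes with
    all-zero counts get NaN.
    """
    masks = _level_design(matrix, design)
    n, n_levels = matrix.n_samples, len(masks)
    if n < n_levels + 1:
        raise DegreesOfFreedomError(
            f"need at least {n_levels + 1} samples for {n_levels} levels, have {n}"
        )
    sf = size_factors(matrix).to_numpy()
    q = matrix.values.astype(float) / sf
    ss_within = np.zeros(matrix.n_genes)
    for mask in masks:
        sub = q[:, mask]
        level_mean = sub.mean(axis=1, keepdims=True)
        ss_within += ((sub - level_mean) ** 2).sum(axis=1)
    s2 = ss_within / (n - n_levels)
    mu = q.mean(axis=1)
    xi = np.mean(1.0 / sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - xi * mu) / mu**2
    alpha = np.clip(alpha, 0.0, None)
    alpha[mu == 0] = np.nan
    return pd.Series(alpha, index=matrix.gene_ids, name="dispersion")


def nb_wald_test(
    matrix: CountMatrix, design: DesignSpec | None = None
) -> pd.DataFrame:
    """Two-group NB Wald test; returns the per-gene DE result table.

    The log2 fold change is the log2 ratio of normalized level means
    (second sorted level over the first; the alphabetically first level
    is the reference), moderated by a pseudocount of 0.5 on both level
    means whenever one of them is zero.  The standard error
    comes from the NB GLM Fisher information at the fitted means with the
    gene's plug-in dispersion; the two-sided p value uses a t reference
    with n - 2 degrees of freedom.  Genes with zero counts in every sample
    get NaN p values and are excluded from the BH adjustment.

    Columns: ``baseMean, log2FoldChange, dispersion, pvalue, padj``.
    """
    if design is None:
        design = DesignSpec.condition(matrix)
    if design.factor != "condition":
        raise DesignError("nb_wald_test requires a two-level condition design")
    masks = _level_design(matrix, design)
    mask_a, mask_b = masks
    sf = size_factors(matrix).to_numpy()
    q = matrix.values.astype(float) / sf
    mean_a = q[:, mask_a].mean(axis=1)
    mean_b = q[:, mask_b].mean(axis=1)
    base_mean = q.mean(axis=1)
    alpha = estimate_dispersions(matrix, design).to_numpy()

    # log2FC is the plain ratio of normalized level means (exactly
    # invariant to sequencing-depth rescaling); the 0.5 pseudocount is
    # applied only where a level mean is zero.
    has_zero = (mean_a == 0) | (mean_b == 0)
    safe_a = np.where(has_zero, mean_a + 0.5, mean_a)
    safe_b = np.where(has_zero, mean_b + 0.5, mean_b)
    log2fc = np.log2(safe_b) - np.log2(safe_a)

    # Fisher information per sample: w = mu / (1 + alpha * mu), with level
    # means moderated by the same 0.5 pseudocount so empty levels keep a
    # finite standard error.
    alpha_safe = np.nan_to_num(alpha, nan=0.0)
    info = np.zeros((matrix.n_genes, 2))
    for col, (mask, lvl_mean) in enumerate(
        [(mask_a, mean_a), (mask_b, mean_b)]
    ):
        mu = np.outer(lvl_mean + 0.5, sf[mask])
        w = mu / (1.0 + alpha_safe[:, None] * mu)
        info[:, col] = w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_ln = 1.0 / info[:, 0] + 1.0 / info[:, 1]
    se_log2 = np.sqrt(var_ln) / np.log(2.0)

    df = matrix.n_samples - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se_log2
    pvalue = 2.0 * stats.t.sf(np.abs(z), df=df)

    all_zero = base_mean == 0
    pvalue[all_zero] = np.nan
    log2fc[all_zero] = 0.0

    result = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "dispersion": alpha,
            "pvalue": pvalue,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    result["padj"] = adjust_bh(result["pvalue"].to_numpy())
    return result


def adjust_bh(pvalues: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    ``padj_(i) = min_{j >= i} p_(j) * m / j`` capped at 1, where ``m``
    counts the testable (non-NaN) entries; NaN entries stay NaN and do not
    count toward ``m``.  The output is order-preserving and elementwise
    >= the input.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise DomainError("p values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    unsorted = np.empty(m)
    unsorted[order] = adj
    out[ok] = unsorted
    return out


def select_genes(
    result: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 2.0
) -> set[str]:
    """Differentially expressed genes: padj < alpha and |log2FC| > threshold.

    Genes whose p value could not be computed (NaN padj) are never selected.
    """
    padj = result["padj"]
    lfc = result["log2FoldChange"]
    keep = (padj < alpha) & (lfc.abs() > lfc_threshold) & padj.notna()
    return set(result.index[keep])


def write_de_result(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index_label="gene_id")


def read_de_result(path: str | Path) -> pd.DataFrame:
    """Load a DE result TSV (e.g. exported from DESeq2) for downstream use."""
    result = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in ("log2FoldChange", "pvalue", "padj") if c not in result]
    if missing:
        raise DomainError(f"{path}: missing DE result columns {missing}")
    return result
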