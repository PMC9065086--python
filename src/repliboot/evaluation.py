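"""Comparison layer: how close are artificial replicates to real ones?

Given labeled per-gene result vectors (raw p values or absolute log2 fold
changes) from the original replicates and from each artificial replicate,
this module computes

* Spearman-correlation distances ``1 - rho`` and Ward cluster trees of
  the result lists (with Newick export),
* asymmetric percentage overlap matrices of selected gene (or gene-set)
  lists — entry (row A, column B) is the share of the reference list A
  recovered by comparison list B,
* gene-wise dispersion distributions per data set with pairwise
  Kolmogorov-Smirnov distances (biological or technical variance), and
* selection-frequency stability reports: for each gene, in how many of B
  artificial runs it was selected, cross-tabulated against the reference
  selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .de import DesignSpec, estimate_dispersions
from .errors import DomainError, InsufficientDataError
from .matrix import CountMatrix

__all__ = [
    "spearman_distance",
    "ward_tree",
    "ClusterTree",
    "overlap_matrix",
    "dispersion_comparison",
    "pool_replicates",
    "stability_report",
    "StabilityReport",
]


def spearman_distance(catalog: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Pairwise distance ``1 - rho`` between labeled per-gene result vectors.

    ``rho`` is Spearman's rank correlation with average ranks for ties.
    Genes carrying a NaN in *any* vector are dropped listwise so all
    correlations use one shared complete-case gene index.  The result is
    symmetric with a zero diagonal and entries in [0, 2].
    """
    if len(catalog) < 2:
        raise DomainError("need at least 2 labeled result vectors")
    labels = list(catalog)
    frame = pd.DataFrame({lab: catalog[lab] for lab in labels})
    frame = frame.dropna(axis=0, how="any")
    if frame.shape[0] < 3:
        raise InsufficientDataError(
            f"only {frame.shape[0]} genes complete in every vector; need >= 3"
        )
    rho = stats.spearmanr(frame.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly 2 vectors
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=labels, columns=labels)


@dataclass(frozen=True)
class ClusterTree:
    """Ward merge tree over labeled items; linkage in scipy format."""

    linkage: np.ndarray
    labels: tuple[str, ...]

    def to_newick(self) -> str:
        """Serialize as a Newick string with branch lengths.

        Branch lengths are differences of merge heights, so root-to-leaf
        path length equals the root merge height.
        """
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        inner = (
            f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)})"
            if not tree.is_leaf()
            else self.labels[tree.id]
        )
        return inner + ";"

    def merge_order(self) -> list[tuple[frozenset[str], float]]:
        """Clusters in merge order with their heights (for inspection)."""
        n = len(self.labels)
        clusters: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        for i, (a, b, height, _) in enumerate(self.linkage):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[n + i] = merged
            out.append((merged, float(height)))
        return out


def ward_tree(distance: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> ClusterTree:
    """Agglomerative Ward clustering of a precomputed distance matrix.

    Uses the Ward.D2 convention (squared-distance Lance-Williams update
    applied to the given dissimilarities), matching scipy's ``ward`` and
    R's ``hclust(..., method="ward.D2")``.  Merge heights are
    non-decreasing; the input must be symmetric with a zero diagonal.
    """
    if isinstance(distance, pd.DataFrame):
        if labels is None:
            labels = list(distance.index)
        distance = distance.to_numpy()
    distance = np.asarray(distance, dtype=float)
    if distance.ndim != 2 or distance.shape[0] != distance.shape[1]:
        raise DomainError("distance matrix must be square")
    if not np.allclose(distance, distance.T, atol=1e-12):
        raise DomainError("distance matrix must be symmetric")
    if not np.allclose(np.diag(distance), 0.0, atol=1e-12):
        raise DomainError("distance matrix must have a zero diagonal")
    if labels is None:
        labels = [str(i) for i in range(distance.shape[0])]
    condensed = squareform(distance, checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    return ClusterTree(linkage=linkage, labels=tuple(labels))


def overlap_matrix(selections: Mapping[str, set]) -> pd.DataFrame:
    """Asymmetric percentage overlap of labeled selections.

    Entry (row A, column B) = ``100 * |A & B| / |A|`` — the percentage of
    the *reference* list A (rows) recovered by the comparison list B
    (columns).  The diagonal is 100 for non-empty sets.  An empty
    reference set yields a zero row and a warning.
    """
    if len(selections) < 2:
        raise DomainError("need at least 2 labeled selections")
    labels = list(selections)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in labels:
        ref = selections[a]
        if not ref:
            warnings.warn(f"reference selection {a!r} is empty", stacklevel=2)
            continue
        for b in labels:
            out.loc[a, b] = 100.0 * len(ref & selections[b]) / len(ref)
    return out


def pool_replicates(
    replicates: Mapping[str, CountMatrix], sample_key: Mapping[str, str] | None = None
) -> tuple[CountMatrix, DesignSpec]:
    """Bind replicate data sets column-wise for technical-variance analysis.

    All matrices must share the gene index and the biological sample ids.
    The pooled matrix has one column per (replicate, sample); the returned
    design puts the biological sample id as the factor, so dispersions
    estimated under it reflect the variance *between* replicates of the
    same sample (the technical variance).
    """
    items = list(replicates.items())
    if len(items) < 2:
        raise DomainError("need >= 2 replicate data sets to pool")
    genes = items[0][1].gene_ids
    base_samples = items[0][1].sample_ids
    blocks, ids, factor, groups = [], [], [], []
    for rep_label, m in items:
        if m.gene_ids != genes:
            raise DomainError(f"replicate {rep_label!r} has a different gene index")
        if m.n_samples != len(base_samples):
            raise DomainError(f"replicate {rep_label!r} has a different sample count")
        blocks.append(m.counts.to_numpy())
        for pos, sid in enumerate(m.sample_ids):
            ids.append(f"{rep_label}.{sid}")
            key = sample_key[sid] if sample_key else base_samples[pos]
            factor.append(key)
            groups.append(m.groups.iloc[pos])
    pooled = CountMatrix(
        pd.DataFrame(np.hstack(blocks), index=genes, columns=ids),
        pd.Series(groups, index=ids),
    )
    return pooled, DesignSpec("replicate_id", factor)


def dispersion_comparison(
    datasets: Mapping[str, CountMatrix],
    mode: str = "biological",
    reference: str | None = None,
) -> tuple[dict[str, pd.Series], pd.DataFrame]:
    """Gene-wise dispersion distributions per data set plus pairwise KS distances.

    ``mode="biological"``: each matrix is analysed under its own two-group
    condition design, so dispersions capture variability between
    biological samples.  ``mode="technical"``: each entry must be a pooled
    matrix (see :func:`pool_replicates`) analysed with the biological
    sample as factor, so dispersions capture variability between
    replicates of the same sample; pass such matrices pre-pooled and use
    ``mode="biological"`` semantics via the design — here each value of
    ``datasets`` is a ``(CountMatrix, DesignSpec)`` pair.

    Returns ``(dispersions, ks)`` where ``ks[a, b]`` is the two-sample
    Kolmogorov-Smirnov statistic between the (finite) dispersion
    distributions of data sets a and b.  ``reference`` is accepted for
    caller convenience (e.g. to slice the KS column of the truth) but does
    not change the computation.
    """
    if mode not in ("biological", "technical"):
        raise DomainError(f"unknown mode {mode!r}")
    dispersions: dict[str, pd.Series] = {}
    for label, entry in datasets.items():
        if mode == "technical":
            m, design = entry
        else:
            m = entry
            design = DesignSpec.condition(m)
        dispersions[label] = estimate_dispersions(m, design)
    labels = list(dispersions)
    ks = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        va = dispersions[a].dropna().to_numpy()
        for b in labels[i + 1 :]:
            vb = dispersions[b].dropna().to_numpy()
            stat = stats.ks_2samp(va, vb).statistic if len(va) and len(vb) else np.nan
            ks.loc[a, b] = ks.loc[b, a] = stat
    return dispersions, ks


@dataclass(frozen=True)
class StabilityReport:
    """How stably each gene is re-selected across B artificial replicates.

    ``frequency`` maps every gene in the universe to the number of runs
    (0..B) that selected it; ``crosstab`` has rows TRUE/FALSE (selected in
    the reference analysis or not) and one column per frequency 0..B;
    ``reference_pvalues`` aligns the reference raw p values for
    scatter-style inspection of rank vs stability.
    """

    frequency: pd.Series
    crosstab: pd.DataFrame
    reference_pvalues: pd.Series | None

    @property
    def n_runs(self) -> int:
        return self.crosstab.shape[1] - 1


def stability_report(
    reference_selection: set,
    replicate_selections: Sequence[set],
    universe: Sequence[str],
    reference_pvalues: pd.Series | None = None,
) -> StabilityReport:
    """Cross-tabulate the reference gene selection against re-selection counts.

    All selections must be subsets of ``universe``.  The cross-tab counts
    sum to the universe size; row sums equal the reference TRUE/FALSE
    totals.
    """
    universe_index = pd.Index(universe)
    if universe_index.has_duplicates:
        raise DomainError("gene universe contains duplicates")
    uni = set(universe_index)
    for i, sel in enumerate([reference_selection, *replicate_selections]):
        stray = set(sel) - uni
        if stray:
            which = "reference" if i == 0 else f"replicate {i}"
            raise DomainError(
                f"{which} selection has genes outside the universe, "
                f"e.g. {sorted(stray)[:3]}"
            )
    B = len(replicate_selections)
    freq = pd.Series(0, index=universe_index, dtype=int, name="n_selected")
    for sel in replicate_selections:
        if sel:
            freq[list(sel)] += 1
    in_ref = universe_index.isin(reference_selection)
    crosstab = pd.DataFrame(
        0, index=["TRUE", "FALSE"], columns=list(range(B + 1)), dtype=int
    )
    for row, mask in (("TRUE", in_ref), ("FALSE", ~in_ref)):
        counts = np.bincount(freq.to_numpy()[mask], minlength=B + 1)
        crosstab.loc[row] = counts[: B + 1]
    pvals = None
    if reference_pvalues is not None:
        pvals = reference_pvalues.reindex(universe_index)
    return StabilityReport(frequency=freq, crosstab=crosstab, reference_pvalues=pvals)
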