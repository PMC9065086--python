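"""Count-matrix container plus the CB and MO replicate generators.

After mapping, an RNA-seq experiment is summarized as a matrix of read
counts with ``d`` genes in rows and ``n`` samples in columns.  Two
strategies generate artificial replicates of the *whole experiment* from
this matrix:

* column bootstrap (CB) — resample columns with replacement; no new
  expression values are created, only a new arrangement of existing ones;
* mixing observations (MO) — each new column is a weighted mean
  ``x_new = sum_i w_i x_i`` of existing columns with non-negative weights
  summing to one, a data-augmentation technique borrowed from machine
  learning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

__all__ = [
    "CountMatrix",
    "MixSpec",
    "column_bootstrap",
    "mix_observations",
    "read_counts_tsv",
    "write_counts_tsv",
]


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    ``counts`` is indexed by gene id (rows) and sample id (columns);
    ``groups`` maps each sample id to its condition label ("infected" /
    "control" or similar).
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise FormatError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise FormatError("counts must be integer-valued")
            self.counts = self.counts.round().astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise FormatError("counts must be non-negative")
        self.groups = pd.Series(self.groups)
        if list(self.groups.index) != list(self.counts.columns):
            # allow groups given in any order but covering exactly the samples
            if set(self.groups.index) != set(self.counts.columns):
                raise FormatError("group labels must cover exactly the sample ids")
            self.groups = self.groups.reindex(self.counts.columns)

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        groups: Sequence[str],
    ) -> "CountMatrix":
        counts = pd.DataFrame(
            np.asarray(values), index=list(gene_ids), columns=list(sample_ids)
        )
        return cls(counts, pd.Series(list(groups), index=list(sample_ids)))

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

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def group_levels(self) -> list[str]:
        """Condition labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.groups.copy())


@dataclass(frozen=True)
class MixSpec:
    """How to mix columns when building MO replicates.

    Either ``weights`` gives one fixed weight vector (applied to every
    output sample; its length must match the mixing pool) or fresh weights
    are drawn per output sample from a symmetric Dirichlet with
    concentration ``dirichlet_alpha``.  ``within_group`` restricts the
    mixing pool to columns sharing a condition label, which preserves the
    treatment effect for downstream differential expression.
    """

    weights: tuple[float, ...] | None = None
    dirichlet_alpha: float = 1.0
    within_group: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if (w < 0).any():
                raise DomainError("mixing weights must be non-negative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise DomainError(f"mixing weights must sum to 1, got {w.sum()!r}")
            object.__setattr__(self, "weights", tuple(float(x) for x in w))
        if self.dirichlet_alpha <= 0:
            raise DomainError("dirichlet_alpha must be positive")


def column_bootstrap(
    matrix: CountMatrix, stratify: bool = True, seed: int = 0
) -> CountMatrix:
    """Resample matrix columns with replacement (the CB strategy).

    With ``stratify=True`` (default) columns are resampled within each
    condition group, so per-group sample counts are preserved and every
    artificial experiment retains both conditions; ``stratify=False``
    draws from all columns jointly.  Every output column is an exact copy
    of some input column, with its source's group label; output sample ids
    get a ``.b<position>`` suffix to stay unique.  A singleton group under
    stratification is copied unchanged with a warning.
    """
    n = matrix.n_samples
    if n < 2:
        raise DomainError("column bootstrap needs at least 2 samples")
    rng = np.random.default_rng(seed)
    positions = np.arange(n)
    if stratify:
        draws = np.empty(n, dtype=int)
        group_codes = matrix.groups.to_numpy()
        for level in matrix.group_levels():
            idx = positions[group_codes == level]
            if len(idx) == 1:
                warnings.warn(
                    f"group {level!r} has a single sample; copied unchanged",
                    stacklevel=2,
                )
                draws[idx] = idx
            else:
                draws[idx] = rng.choice(idx, size=len(idx), replace=True)
    else:
        draws = rng.integers(0, n, size=n)

    src_ids = [matrix.sample_ids[j] for j in draws]
    new_ids = [f"{sid}.b{pos + 1}" for pos, sid in enumerate(src_ids)]
    counts = matrix.counts.iloc[:, draws]
    counts.columns = new_ids
    groups = pd.Series(
        [matrix.groups.iloc[j] for j in draws], index=new_ids
    )
    return CountMatrix(counts, groups)


def mix_observations(
    matrix: CountMatrix, spec: MixSpec, n_out: int | None = None
) -> CountMatrix:
    """Build an MO replicate: each output column is a weighted column mean.

    Output column ``i`` uses input column ``i % n`` as its template: it
    inherits that column's group label and, when ``spec.within_group``,
    mixes only columns of that group.  Weights come from ``spec`` (fixed,
    or Dirichlet-drawn per output sample).  Mixed values are rounded
    half-to-even to integers so the result is again a valid count matrix.
    """
    n = matrix.n_samples
    if n < 2:
        raise DomainError("mixing observations needs at least 2 samples")
    if n_out is None:
        n_out = n
    rng = np.random.default_rng(spec.seed)
    values = matrix.values.astype(float)
    group_codes = matrix.groups.to_numpy()
    positions = np.arange(n)

    cols = np.empty((matrix.n_genes, n_out))
    out_ids: list[str] = []
    out_groups: list[str] = []
    for i in range(n_out):
        template = i % n
        label = group_codes[template]
        pool = positions[group_codes == label] if spec.within_group else positions
        if spec.weights is not None:
            w = np.asarray(spec.weights, dtype=float)
            if len(w) != len(pool):
                raise DomainError(
                    f"weights length {len(w)} != mixing pool size {len(pool)}"
                )
        else:
            w = rng.dirichlet(np.full(len(pool), spec.dirichlet_alpha))
        cols[:, i] = values[:, pool] @ w
        out_ids.append(f"mix{i + 1}.{matrix.sample_ids[template]}")
        out_groups.append(label)

    counts = pd.DataFrame(
        np.round(cols).astype(np.int64), index=matrix.gene_ids, columns=out_ids
    )
    return CountMatrix(counts, pd.Series(out_groups, index=out_ids))


def read_counts_tsv(counts_path: str | Path, groups_path: str | Path) -> CountMatrix:
    """Read a gene x sample counts TSV plus a (sample_id, group) sidecar TSV.

    The counts file has gene ids in the first column and sample ids in the
    header row.  Duplicate ids or non-integer cells are format errors.
    """
    with open(counts_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{counts_path}: duplicate sample ids {dups}")
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = None
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique()
        raise FormatError(f"{counts_path}: duplicate gene ids {list(dups)[:5]}")
    numeric = counts.apply(pd.to_numeric, errors="coerce")
    missing = numeric.isna()
    if missing.to_numpy().any():
        g, s = np.argwhere(missing.to_numpy())[0]
        raise FormatError(
            f"{counts_path}: non-numeric cell at gene {counts.index[g]!r}, "
            f"sample {counts.columns[s]!r}"
        )
    counts = numeric
    values = counts.to_numpy()
    frac = values - np.round(values)
    if np.abs(frac).max(initial=0) > 0:
        g, s = np.argwhere(np.abs(frac) > 0)[0]
        raise FormatError(
            f"{counts_path}: non-integer count {values[g, s]!r} at "
            f"gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
        )
    groups_df = pd.read_csv(
        groups_path, sep="\t", header=None, names=["sample_id", "group"],
        dtype=str, comment="#",
    )
    groups = pd.Series(
        groups_df["group"].to_numpy(), index=groups_df["sample_id"].to_numpy()
    )
    return CountMatrix(counts.astype(np.int64), groups)


def write_counts_tsv(
    matrix: CountMatrix, counts_path: str | Path, groups_path: str | Path
) -> None:
    """Write the counts TSV and group sidecar; round-trips losslessly."""
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    with open(groups_path, "w") as out:
        for sid, grp in matrix.groups.items():
            out.write(f"{sid}\t{grp}\n")
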