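"""Gene-set over-representation analysis (ORA).

An offline, deterministic set-level selector: for each gene set, the
overlap between a selected gene list and the set (both intersected with
the tested universe) is scored with the one-sided hypergeometric upper
tail — equivalent to one-tailed Fisher's exact test — and p values are
BH-adjusted across the tested sets.  Gene sets come from standard GMT
files (tab-separated: set id, description, member genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

from .de import adjust_bh
from .errors import DomainError, FormatError

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "fisher_ora"]


@dataclass(frozen=True)
class GeneSetCollection:
    """Mapping of set id -> (description, member gene ids); sets non-empty."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; gene ids are whitespace-trimmed, case preserved."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            set_id, desc = fields[0].strip(), fields[1].strip()
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            if not members:
                raise FormatError(f"{path}:{lineno}: set {set_id!r} has no members")
            sets[set_id] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as out:
        for set_id, (desc, members) in collection.sets.items():
            out.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def fisher_ora(
    selected: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation test for every set in a collection.

    With ``N`` genes in the universe, ``K`` of them in the set, and ``n``
    selected genes of which ``x`` fall in the set, the p value is the
    upper-tail probability ``P(X >= x)`` for ``X ~ Hypergeom(N, K, n)``.
    Set members outside the universe are ignored.  Returns a table with
    columns ``description, overlap, set_size, p, padj, enriched`` indexed
    by set id; ``enriched`` means padj < alpha.
    """
    universe = frozenset(universe)
    if not universe:
        raise DomainError("empty gene universe")
    selected = frozenset(selected)
    stray = selected - universe
    if stray:
        raise DomainError(
            f"{len(stray)} selected genes not in universe, e.g. {sorted(stray)[:3]}"
        )
    N, n = len(universe), len(selected)
    rows = []
    for set_id in collection:
        members = collection.members(set_id) & universe
        K = len(members)
        x = len(selected & members)
        # upper tail P(X >= x); survival function is P(X > x-1)
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if K else 1.0
        p = min(p, 1.0)
        rows.append((set_id, collection.description(set_id), x, K, p))
    table = pd.DataFrame(
        rows, columns=["set_id", "description", "overlap", "set_size", "p"]
    ).set_index("set_id")
    table["padj"] = adjust_bh(table["p"].to_numpy())
    table["enriched"] = table["padj"] < alpha
    return table
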