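"""Synthetic experiments with paired technical replicates.

The generator emulates the structure of a two-condition bulk RNA-seq
study in which every biological sample was sequenced twice: two groups of
biological samples (default 5 infected vs 4 control), negative-binomial
counts around group means, a subset of truly differentially expressed
genes with a known log2 fold change, and for each biological sample two
correlated technical draws R1 and R2 from the *same* latent expression
level.  Because the technical pair shares its latent level, counts of the
same sample correlate more strongly across R1/R2 than counts of different
samples — the defining property of technical replicates.

A toy transcriptome plus an exact-substring read quantifier close the
loop at the FASTQ level: simulated counts can be realized as reads,
bootstrap-resampled, and re-quantified without any external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DomainError
from .fastq import _iter_raw, _open_write
from .matrix import CountMatrix

__all__ = [
    "SimDesign",
    "simulate_counts",
    "build_toy_transcriptome",
    "load_transcriptome",
    "simulate_fastq",
    "quantify_exact",
    "ExactQuantifier",
    "QuantifyResult",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimDesign:
    """Parameters of a synthetic two-condition experiment.

    Defaults mirror the emulated study design: groups of 5 ("infected")
    and 4 ("control") biological samples, each sequenced as two technical
    replicates, with ~10% of genes truly differentially expressed at
    |log2FC| = 3.  Baseline expression means are drawn log2-uniform over
    ``mean_log2_range`` (default 4 to 1024 counts), and biological
    variability follows an NB dispersion of ``dispersion_alpha``.
    ``technical_model`` chooses how the two technical draws are generated
    from the latent per-sample level: independent Poisson resampling
    (default) or binomial thinning of a shared deeper count.
    """

    d: int = 2000
    n_per_group: tuple[int, int] = (5, 4)
    de_fraction: float = 0.1
    log2fc_magnitude: float = 3.0
    mean_log2_range: tuple[float, float] = (2.0, 10.0)
    dispersion_alpha: float = 0.1
    technical_model: str = "poisson_resample"
    group_labels: tuple[str, str] = ("infected", "control")
    seed: int = 0

    def __post_init__(self) -> None:
        n1, n2 = self.n_per_group
        if n1 < 2 or n2 < 2:
            raise DomainError("each group needs at least 2 biological samples")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise DomainError("de_fraction must lie in [0, 1]")
        if 0 < self.de_fraction and self.de_fraction * self.d < 1:
            raise DomainError("de_fraction * d must be >= 1 when positive")
        if self.log2fc_magnitude <= 0:
            raise DomainError("log2fc_magnitude must be positive")
        if self.dispersion_alpha < 0:
            raise DomainError("dispersion_alpha must be non-negative")
        if self.technical_model not in ("poisson_resample", "multinomial_thin"):
            raise DomainError(f"unknown technical model {self.technical_model!r}")


def simulate_counts(
    design: SimDesign,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Draw one synthetic experiment with two technical replicates.

    Returns ``(R1, R2, truth)``.  R1 and R2 share sample ids and group
    labels (they are re-sequencings of the same biological samples);
    ``truth`` is a per-gene table with columns ``is_de`` and
    ``true_log2fc`` (signed; the second group is shifted relative to the
    first).
    """
    rng = np.random.default_rng(design.seed)
    d = design.d
    n1, n2 = design.n_per_group
    lo, hi = design.mean_log2_range

    base_mean = 2.0 ** rng.uniform(lo, hi, size=d)
    n_de = int(round(design.de_fraction * d))
    de_idx = rng.choice(d, size=n_de, replace=False) if n_de else np.array([], int)
    lfc = np.zeros(d)
    if n_de:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        lfc[de_idx] = signs * design.log2fc_magnitude

    labels = [design.group_labels[0]] * n1 + [design.group_labels[1]] * n2
    mu = np.empty((d, n1 + n2))
    mu[:, :n1] = base_mean[:, None]
    mu[:, n1:] = (base_mean * 2.0**lfc)[:, None]

    alpha = design.dispersion_alpha
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    else:
        lam = mu

    if design.technical_model == "poisson_resample":
        r1 = rng.poisson(lam)
        r2 = rng.poisson(lam)
    else:  # multinomial_thin: split a shared deep count between replicates
        deep = rng.poisson(2.0 * lam)
        r1 = rng.binomial(deep, 0.5)
        r2 = rng.binomial(deep, 0.5)

    gene_ids = [f"gene{i + 1}" for i in range(d)]
    sample_ids = [
        f"{lab[:3]}{i + 1}" for i, lab in enumerate(labels)
    ]
    m1 = CountMatrix.from_arrays(r1, gene_ids, sample_ids, labels)
    m2 = CountMatrix.from_arrays(r2, gene_ids, sample_ids, labels)
    truth = pd.DataFrame(
        {"is_de": lfc != 0.0, "true_log2fc": lfc},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return m1, m2, truth


def build_toy_transcriptome(
    n_transcripts: int,
    length: int,
    seed: int = 0,
    path: str | Path | None = None,
) -> dict[str, str]:
    """Random transcript sequences with unique ids, optionally written as FASTA.

    Sequences are pairwise distinct (astronomically likely for random
    draws; enforced by redrawing on collision).
    """
    if n_transcripts < 1:
        raise DomainError("need at least one transcript")
    rng = np.random.default_rng(seed)
    seen: dict[str, str] = {}
    transcripts: dict[str, str] = {}
    for i in range(n_transcripts):
        while True:
            seq = "".join(rng.choice(_BASES, size=length))
            if seq not in seen:
                break
        tx_id = f"tx{i + 1}"
        seen[seq] = tx_id
        transcripts[tx_id] = seq
    if path is not None:
        records = [
            SeqRecord(Seq(seq), id=tx_id, description="")
            for tx_id, seq in transcripts.items()
        ]
        SeqIO.write(records, str(path), "fasta")
    return transcripts


def load_transcriptome(path: str | Path) -> dict[str, str]:
    """Read a FASTA transcriptome into an id -> sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def simulate_fastq(
    transcriptome: Mapping[str, str] | str | Path,
    counts: Mapping[str, int],
    path: str | Path,
    read_length: int = 50,
    error_rate: float = 0.0,
    seed: int = 0,
    sample_id: str = "S",
) -> int:
    """Realize per-transcript counts as a FASTQ file of uniform-start reads.

    Each transcript contributes exactly ``counts[transcript]`` reads with
    uniformly random start positions (forward strand).  With
    ``error_rate > 0`` every base is substituted independently at that
    rate.  Read ids encode the sample and a serial number only — not the
    source transcript — and reads are emitted in shuffled order, so a
    downstream quantifier cannot cheat.  Qualities are constant high
    (Q40).  Returns the number of reads written.
    """
    if isinstance(transcriptome, (str, Path)):
        transcriptome = load_transcriptome(transcriptome)
    if not (0.0 <= error_rate <= 0.2):
        raise DomainError("error_rate must lie in [0, 0.2]")
    unknown = set(counts) - set(transcriptome)
    if unknown:
        raise DomainError(f"counts reference unknown transcripts {sorted(unknown)[:3]}")
    rng = np.random.default_rng(seed)
    reads: list[str] = []
    for tx_id, c in counts.items():
        if c < 0:
            raise DomainError(f"negative count for transcript {tx_id!r}")
        if c == 0:
            continue
        seq = transcriptome[tx_id]
        if read_length > len(seq):
            raise DomainError(
                f"read length {read_length} exceeds transcript {tx_id!r} "
                f"length {len(seq)}"
            )
        starts = rng.integers(0, len(seq) - read_length + 1, size=c)
        reads.extend(seq[s : s + read_length] for s in starts)

    order = rng.permutation(len(reads))
    quality = "I" * read_length
    if error_rate > 0:
        base_index = {b: i for i, b in enumerate("ACGT")}

        def corrupt(read: str) -> str:
            hits = rng.random(len(read)) < error_rate
            if not hits.any():
                return read
            chars = list(read)
            for pos in np.flatnonzero(hits):
                # substitute with one of the three other bases
                shift = rng.integers(1, 4)
                chars[pos] = "ACGT"[(base_index.get(chars[pos], 0) + shift) % 4]
            return "".join(chars)

    else:
        def corrupt(read: str) -> str:
            return read

    with _open_write(path) as out:
        write = out.write
        for serial, j in enumerate(order):
            write(f"@{sample_id}.{serial + 1}\n{corrupt(reads[j])}\n+\n{quality}\n")
    return len(reads)


@dataclass(frozen=True)
class QuantifyResult:
    """Per-transcript read counts plus the ambiguous/unassigned remainder."""

    counts: dict[str, int]
    n_ambiguous: int
    n_unassigned: int

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def n_total(self) -> int:
        return self.n_assigned + self.n_ambiguous + self.n_unassigned


_AMBIGUOUS = "__ambiguous__"


def _substring_index(
    transcriptome: Mapping[str, str], read_length: int
) -> dict[str, str]:
    """Map every read_length-mer of every transcript to its transcript id
    (or an ambiguity sentinel if several transcripts share the k-mer)."""
    index: dict[str, str] = {}
    for tx_id, seq in transcriptome.items():
        for start in range(0, len(seq) - read_length + 1):
            kmer = seq[start : start + read_length]
            prev = index.get(kmer)
            if prev is None:
                index[kmer] = tx_id
            elif prev != tx_id:
                index[kmer] = _AMBIGUOUS
    return index


class ExactQuantifier:
    """Assigns reads to transcripts by exact substring match (forward strand).

    A toy quantifier for synthetic benchmarks: reads matching exactly one
    transcript are counted for it; reads matching several transcripts or
    none go to the ambiguous / unassigned buckets.  Substring indexes are
    built per observed read length and cached, so one instance can
    quantify many FASTQ files cheaply.
    """

    def __init__(self, transcriptome: Mapping[str, str] | str | Path):
        if isinstance(transcriptome, (str, Path)):
            transcriptome = load_transcriptome(transcriptome)
        self.transcriptome = dict(transcriptome)
        self._indexes: dict[int, dict[str, str]] = {}

    def _index_for(self, read_length: int) -> dict[str, str]:
        idx = self._indexes.get(read_length)
        if idx is None:
            idx = _substring_index(self.transcriptome, read_length)
            self._indexes[read_length] = idx
        return idx

    def quantify(self, fastq_path: str | Path) -> QuantifyResult:
        counts = {tx_id: 0 for tx_id in self.transcriptome}
        n_ambiguous = n_unassigned = 0
        index_for = self._index_for
        for _title, seq, _qual in _iter_raw(fastq_path):
            seq = seq.upper()
            hit = index_for(len(seq)).get(seq)
            if hit is None:
                n_unassigned += 1
            elif hit == _AMBIGUOUS:
                n_ambiguous += 1
            else:
                counts[hit] += 1
        return QuantifyResult(counts, n_ambiguous, n_unassigned)


def quantify_exact(
    fastq_path: str | Path, transcriptome: Mapping[str, str] | str | Path
) -> QuantifyResult:
    """One-shot exact-substring quantification (see :class:`ExactQuantifier`).

    Assigned + ambiguous + unassigned equals the total read count.
    """
    quantifier = (
        transcriptome
        if isinstance(transcriptome, ExactQuantifier)
        else ExactQuantifier(transcriptome)
    )
    return quantifier.quantify(fastq_path)
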