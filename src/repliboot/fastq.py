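"""FASTQ I/O and the FASTQ read bootstrap (FB) replicate generator.

A FASTQ file lists sequencing reads together with per-base quality keys.
An artificial technical replicate is generated by drawing ``m = round(pi * k)``
reads *with replacement* from the original file of ``k`` reads, where ``pi``
is a user-chosen fraction (``pi = 1`` yields a replicate with as many reads
as the original).  Drawing with replacement means a read can appear several
times in the bootstrap file, and some original reads will be absent.

The sampler is a constant-memory two-pass stream: pass one counts the
records, then ``m`` uniform indices are drawn with a seeded generator, and
pass two re-streams the file emitting each record as many times as its index
was drawn.  Reads are therefore emitted in input-file order, never loaded
into memory all at once, and the whole operation is reproducible from the
seed alone.  For paired-end data one shared index sample is applied to both
mate files so that read pairing is preserved.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np

from .errors import DomainError, FastqFormatError, PairingError

__all__ = [
    "FastqRecord",
    "BootstrapManifest",
    "read_fastq",
    "count_reads",
    "write_fastq",
    "bootstrap_reads",
]

_VALID_BASES = frozenset("ACGTNacgtn")


@dataclass(frozen=True)
class FastqRecord:
    """One sequencing read: identifier, base sequence, Phred+33 quality string.

    Invariants checked on construction: sequence and quality have equal
    length, and the sequence alphabet is a subset of ``{A, C, G, T, N}``
    (case-insensitive).
    """

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise DomainError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )
        invalid = set(self.sequence) - _VALID_BASES
        if invalid:
            raise DomainError(
                f"read {self.read_id!r}: invalid bases {sorted(invalid)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BootstrapManifest:
    """Provenance record of one FASTQ bootstrap run.

    ``k`` is the number of reads in the original file, ``pi`` the sampled
    fraction and ``m = round(pi * k)`` the number of reads drawn (at least 1
    whenever the input is non-empty).
    """

    input_paths: tuple[str, ...]
    output_paths: tuple[str, ...]
    k: int
    pi: float
    m: int
    seed: int
    paired: bool
    strategy: str = "FB"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_paths"] = list(self.input_paths)
        d["output_paths"] = list(self.output_paths)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _open_read(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _open_write(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "wt")


def _iter_raw(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) tuples from a strict 4-line-record
    FASTQ file; wrap parse failures with the 1-based record index.

    Internal fast path: records must occupy exactly four lines (the
    common case for raw sequencer output and everything this package
    writes).  Multi-line FASTQ is rejected as malformed.
    """
    index = 0
    with _open_read(path) as handle:
        readline = handle.readline
        while True:
            header = readline()
            if not header:
                return
            index += 1
            if header[0] != "@":
                if not header.strip():
                    # tolerate trailing blank line(s) at end of file
                    if not handle.read().strip():
                        return
                raise FastqFormatError(
                    f"{path}: malformed FASTQ at record {index}: "
                    f"header does not start with '@'"
                )
            seq = readline()
            plus = readline()
            qual = readline()
            if not qual:
                raise FastqFormatError(
                    f"{path}: malformed FASTQ at record {index}: "
                    f"truncated record (line count not a multiple of 4)"
                )
            if plus[0] != "+":
                raise FastqFormatError(
                    f"{path}: malformed FASTQ at record {index}: "
                    f"separator line does not start with '+'"
                )
            seq = seq.rstrip("\n")
            qual = qual.rstrip("\n")
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"{path}: malformed FASTQ at record {index}: "
                    f"sequence and quality lengths differ"
                )
            yield header[1:].rstrip("\n"), seq, qual


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream records from a plain or gzip-compressed FASTQ file.

    Raises :class:`FastqFormatError` naming the 1-based record index at
    which parsing failed (truncated record, header not starting with '@',
    missing '+' line, length mismatch, invalid base).
    """
    for index, (title, seq, qual) in enumerate(_iter_raw(path), start=1):
        try:
            yield FastqRecord(title, seq, qual)
        except DomainError as exc:
            raise FastqFormatError(
                f"{path}: malformed FASTQ at record {index}: {exc}"
            ) from exc


def count_reads(path: str | Path) -> int:
    """Return the number of records ``k`` in a FASTQ file (plain or gzip)."""
    k = 0
    for _ in _iter_raw(path):
        k += 1
    return k


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    """Write records as standard 4-line FASTQ; gzip-compresses for ``.gz`` paths.

    The output round-trips losslessly through :func:`read_fastq`.
    """
    try:
        with _open_write(path) as out:
            for rec in records:
                out.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
    except OSError as exc:
        raise OSError(f"failed writing FASTQ to {path}: {exc}") from exc


def _suffix_read_id(read_id: str, occurrence: int) -> str:
    """Append /bsN to the id token (before any whitespace comment)."""
    if occurrence < 2:
        return read_id
    head, sep, tail = read_id.partition(" ")
    return f"{head}/bs{occurrence}{sep}{tail}"


def _emit_bootstrap(
    in_path: str | Path,
    out_path: str | Path,
    draw_counts: np.ndarray,
    rename_duplicates: bool,
) -> None:
    n_records = 0
    k = len(draw_counts)
    with _open_write(out_path) as out:
        write = out.write
        for i, (title, seq, qual) in enumerate(_iter_raw(in_path)):
            n_records += 1
            if i >= k:
                raise DomainError(
                    f"{in_path}: file has more than the stated k={k} records"
                )
            c = int(draw_counts[i])
            if c == 0:
                continue
            write(f"@{title}\n{seq}\n+\n{qual}\n")
            if rename_duplicates:
                for occ in range(2, c + 1):
                    write(f"@{_suffix_read_id(title, occ)}\n{seq}\n+\n{qual}\n")
            elif c > 1:
                write(f"@{title}\n{seq}\n+\n{qual}\n" * (c - 1))
    if n_records != k:
        raise DomainError(
            f"{in_path}: file has {n_records} records but k={k} was stated"
        )


def bootstrap_reads(
    input_path: str | Path,
    pi: float,
    seed: int,
    output_path: str | Path,
    *,
    mate_path: str | Path | None = None,
    mate_output_path: str | Path | None = None,
    rename_duplicates: bool = True,
    k: int | None = None,
) -> BootstrapManifest:
    """Generate one artificial technical replicate by bootstrapping reads.

    Draws ``m = round(pi * k)`` reads with replacement (``m >= 1`` for
    non-empty input; rounding is half-to-even) and streams them to
    ``output_path`` in input-file order.  Quality strings are carried
    verbatim.  When a read is drawn more than once, every occurrence after
    the first gets a ``/bsN`` suffix on its id so downstream tools that
    require unique read names keep working; pass
    ``rename_duplicates=False`` to emit verbatim copies.

    For paired-end input give both ``mate_path`` and ``mate_output_path``:
    a single index sample is applied to both files, which keeps mates
    synchronized.  Both mates must contain the same number of reads.

    Identical ``(input, pi, seed)`` produce byte-identical output.

    ``k`` may be passed when the input's read count is already known
    (e.g. from a previous manifest) to skip the counting pass; it is
    verified against the file during emission.
    """
    if not (0.0 < pi <= 1.0):
        raise DomainError(f"pi must be in (0, 1], got {pi}")
    if (mate_path is None) != (mate_output_path is None):
        raise PairingError("paired mode needs both mate_path and mate_output_path")

    if k is None:
        k = count_reads(input_path)
    elif k < 0:
        raise DomainError(f"k must be non-negative, got {k}")
    paired = mate_path is not None
    if paired:
        k2 = count_reads(mate_path)
        if k2 != k:
            raise PairingError(
                f"mate files differ in length: {input_path} has {k} reads, "
                f"{mate_path} has {k2}"
            )

    m = int(round(pi * k))
    if k >= 1:
        m = max(1, m)

    rng = np.random.default_rng(seed)
    if k > 0:
        draws = rng.integers(0, k, size=m)
        draw_counts = np.bincount(draws, minlength=k)
    else:
        m = 0
        draw_counts = np.zeros(0, dtype=int)

    _emit_bootstrap(input_path, output_path, draw_counts, rename_duplicates)
    outputs = [str(output_path)]
    inputs = [str(input_path)]
    if paired:
        _emit_bootstrap(mate_path, mate_output_path, draw_counts, rename_duplicates)
        outputs.append(str(mate_output_path))
        inputs.append(str(mate_path))

    return BootstrapManifest(
        input_paths=tuple(inputs),
        output_paths=tuple(outputs),
        k=k,
        pi=float(pi),
        m=m,
        seed=int(seed),
        paired=paired,
    )
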