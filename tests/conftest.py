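import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from repliboot import CountMatrix, FastqRecord, write_fastq


@pytest.fixture
def make_fastq(tmp_path):
    """Factory writing n deterministic synthetic records to a FASTQ file."""

    def _make(n, path=None, read_length=20, seed=0, compress=False):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        records = [
            FastqRecord(
                f"read{i + 1}",
                "".join(rng.choice(bases, size=read_length)),
                "I" * read_length,
            )
            for i in range(n)
        ]
        if path is None:
            name = "reads.fastq.gz" if compress else "reads.fastq"
            path = tmp_path / name
        write_fastq(records, path)
        return path, records

    return _make


@pytest.fixture
def small_matrix():
    """5 genes x 6 samples, two groups of 3, strictly positive counts."""
    rng = np.random.default_rng(42)
    values = rng.integers(1, 200, size=(5, 6))
    return CountMatrix.from_arrays(
        values,
        [f"g{i}" for i in range(1, 6)],
        [f"s{j}" for j in range(1, 7)],
        ["infected"] * 3 + ["control"] * 3,
    )


def nb_matrix(d, n1, n2, alpha=0.1, mean=100.0, lfc=None, seed=0):
    """NB count matrix helper: gamma-Poisson draws around group means."""
    rng = np.random.default_rng(seed)
    mu = np.full((d, n1 + n2), float(mean))
    if lfc is not None:
        mu[:, n1:] *= 2.0 ** np.asarray(lfc)[:, None]
    lam = rng.gamma(1.0 / alpha, alpha * mu) if alpha > 0 else mu
    counts = rng.poisson(lam)
    return CountMatrix.from_arrays(
        counts,
        [f"g{i}" for i in range(d)],
        [f"s{j}" for j in range(n1 + n2)],
        ["A"] * n1 + ["B"] * n2,
    )
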