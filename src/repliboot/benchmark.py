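"""Synthetic benchmark: which strategy best mimics a true technical replicate?

One benchmark run simulates an experiment with two technical replicates
R1/R2, realizes R1 as FASTQ read sets over a toy transcriptome, generates
B artificial replicates from R1 with each strategy (FB at the read level,
CB and MO at the count level), runs differential expression on
everything, and scores each strategy two ways:

* agreement of p-value rankings with the held-out true replicate R2 —
  mean Spearman rho between each artificial replicate's p-value list and
  R2's list (artificial replicates built from R1 should reproduce R2);
* fidelity of the biological dispersion distribution — mean
  Kolmogorov-Smirnov distance between each artificial replicate's
  gene-wise dispersion distribution and R2's.

The benchmark is intentionally smaller than a real experiment (a few
hundred genes, ~50-mer reads over a 300-base toy transcriptome) so the
full read-level FB loop stays cheap; the qualitative contrasts between
strategies are what it measures.
"""

from __future__ import annotations

import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .de import DesignSpec, estimate_dispersions, nb_wald_test
from .fastq import bootstrap_reads
from .matrix import CountMatrix, MixSpec, column_bootstrap, mix_observations
from .simulate import (
    ExactQuantifier,
    SimDesign,
    build_toy_transcriptome,
    simulate_counts,
    simulate_fastq,
)

__all__ = ["BenchmarkResult", "run_benchmark"]

#: transcript length (bases) and read length for the read-level FB loop
TRANSCRIPT_LENGTH = 300
READ_LENGTH = 50


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-strategy scores of one benchmark run (one seed)."""

    rho_with_r2: dict[str, float]  # mean Spearman rho of p-value lists vs R2
    ks_dispersion: dict[str, float]  # mean KS distance of dispersions vs R2
    rho_r1_r2: float  # Spearman rho between the true replicates themselves


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    return float(stats.spearmanr(a[ok], b[ok]).statistic)


def _fb_replicate(
    fastq_paths: dict[str, Path],
    read_counts: dict[str, int],
    quantifier: ExactQuantifier,
    template: CountMatrix,
    tx_to_gene: dict[str, str],
    pi: float,
    seed: int,
    workdir: Path,
) -> CountMatrix:
    import pandas as pd

    columns = {}
    for j, (sample_id, fq) in enumerate(fastq_paths.items()):
        boot = workdir / f"boot.{sample_id}.fastq"
        bootstrap_reads(fq, pi, seed + j, boot, k=read_counts[sample_id])
        counts = quantifier.quantify(boot).counts
        boot.unlink()
        columns[sample_id] = {tx_to_gene[tx]: c for tx, c in counts.items()}

    frame = pd.DataFrame(columns, columns=list(fastq_paths)).fillna(0).astype(int)
    frame = frame.reindex(template.gene_ids, fill_value=0)
    return CountMatrix(frame, template.groups.copy())


def run_benchmark(
    seed: int,
    d: int = 250,
    b: int = 10,
    pi: float = 1.0,
    mean_log2_range: tuple[float, float] = (4.0, 10.0),
    workdir: str | Path | None = None,
) -> BenchmarkResult:
    """Run one seeded benchmark comparing the FB, CB and MO strategies.

    ``d`` genes (default 250) with baseline means of 16..1024 counts —
    the deep-coverage regime of a bulk experiment, where biological
    variability dominates sequencing shot noise for most genes (alpha*mu
    above 1), which is the regime the strategies are meant for; ``b``
    artificial replicates per strategy, FB at read fraction ``pi``.  All
    randomness derives from ``seed``.  Returns per-strategy mean Spearman
    rho of p-value lists with R2 and mean KS distance of dispersion
    distributions to R2.
    """
    own_tmp = workdir is None
    workdir = Path(tempfile.mkdtemp(prefix="repliboot-bench-")) if own_tmp else Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    try:
        design = SimDesign(d=d, mean_log2_range=mean_log2_range, seed=seed)
        r1, r2, _truth = simulate_counts(design)

        transcriptome = build_toy_transcriptome(
            d, TRANSCRIPT_LENGTH, seed=seed * 7 + 1
        )
        gene_to_tx = dict(zip(r1.gene_ids, transcriptome))
        tx_to_gene = {tx: g for g, tx in gene_to_tx.items()}

        fastq_paths: dict[str, Path] = {}
        read_counts: dict[str, int] = {}
        for j, sample_id in enumerate(r1.sample_ids):
            counts = {
                gene_to_tx[g]: int(c)
                for g, c in r1.counts[sample_id].items()
            }
            path = workdir / f"R1.{sample_id}.fastq"
            read_counts[sample_id] = simulate_fastq(
                transcriptome, counts, path,
                read_length=READ_LENGTH, seed=seed * 101 + j, sample_id=sample_id,
            )
            fastq_paths[sample_id] = path
        quantifier = ExactQuantifier(transcriptome)

        replicates: dict[str, dict[str, CountMatrix]] = {"FB": {}, "CB": {}, "MO": {}}
        for i in range(1, b + 1):
            rep_seed = seed * 1009 + i * 13
            replicates["FB"][f"FB{i}"] = _fb_replicate(
                fastq_paths, read_counts, quantifier, r1, tx_to_gene, pi,
                rep_seed * 100, workdir,
            )
            replicates["CB"][f"CB{i}"] = column_bootstrap(r1, seed=rep_seed)
            replicates["MO"][f"MO{i}"] = mix_observations(
                r1, MixSpec(seed=rep_seed)
            )

        p_r2 = nb_wald_test(r2)["pvalue"].to_numpy()
        disp_r2 = (
            estimate_dispersions(r2, DesignSpec.condition(r2)).dropna().to_numpy()
        )
        p_r1 = nb_wald_test(r1)["pvalue"].to_numpy()

        rho_with_r2: dict[str, float] = {}
        ks_dispersion: dict[str, float] = {}
        for strategy, reps in replicates.items():
            rhos, kss = [], []
            for m in reps.values():
                res = nb_wald_test(m)
                rhos.append(_spearman(res["pvalue"].to_numpy(), p_r2))
                disp = res["dispersion"].dropna().to_numpy()
                kss.append(float(stats.ks_2samp(disp, disp_r2).statistic))
            rho_with_r2[strategy] = float(np.mean(rhos))
            ks_dispersion[strategy] = float(np.mean(kss))

        return BenchmarkResult(
            rho_with_r2=rho_with_r2,
            ks_dispersion=ks_dispersion,
            rho_r1_r2=_spearman(p_r1, p_r2),
        )
    finally:
        if own_tmp:
            shutil.rmtree(workdir, ignore_errors=True)
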