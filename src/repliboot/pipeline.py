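"""End-to-end orchestration: generate replicates -> DE -> ORA -> compare.

One :func:`run_pipeline` call reproduces the full workflow for one
strategy: B artificial replicates are generated from the original data
(with deterministic per-replicate seeds ``base_seed + i``), each is
pushed through differential expression, gene selection and (optionally)
gene-set over-representation, and the comparison layer writes distance
matrices, cluster trees, overlap matrices and the stability report into
the run directory together with a provenance manifest.

For the FB strategy the default is the storage-frugal sequential loop:
each bootstrap FASTQ set is quantified and then deleted before the next
replicate is generated (``reclaim_space``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .de import (
    DesignSpec,
    nb_wald_test,
    read_de_result,
    select_genes,
    write_de_result,
)
from .enrichment import fisher_ora, read_gmt
from .errors import DomainError, ReplibootError
from .evaluation import (
    overlap_matrix,
    spearman_distance,
    stability_report,
    ward_tree,
)
from .fastq import bootstrap_reads
from .matrix import (
    CountMatrix,
    MixSpec,
    column_bootstrap,
    mix_observations,
    read_counts_tsv,
    write_counts_tsv,
)
from .simulate import ExactQuantifier, load_transcriptome

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

STRATEGIES = ("FB", "CB", "MO")


class PipelineError(ReplibootError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Count-level strategies (CB, MO) need ``counts_path`` + ``groups_path``.
    The read-level strategy (FB) needs per-sample FASTQ files
    (``fastq_paths``), a toy transcriptome for the built-in exact-match
    quantifier (``transcriptome_path``) and ``groups_path``; the reference
    count matrix is quantified from the original FASTQ files.
    """

    strategy: str
    out_dir: str | Path
    b: int = 10
    seed: int = 0
    counts_path: str | Path | None = None
    groups_path: str | Path | None = None
    fastq_paths: dict[str, str] | None = None
    transcriptome_path: str | Path | None = None
    pi: float = 1.0
    stratify: bool = True
    dirichlet_alpha: float = 1.0
    mix_across_groups: bool = False
    alpha: float = 0.05
    lfc_threshold: float = 2.0
    gmt_path: str | Path | None = None
    de_backend: str = "builtin"
    external_de_dir: str | Path | None = None
    reclaim_space: bool = True
    reference_label: str = "R1"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise DomainError(f"strategy must be one of {STRATEGIES}")
        if self.b < 1:
            raise DomainError("b (number of artificial replicates) must be >= 1")
        if self.strategy == "FB":
            if not self.fastq_paths or not self.transcriptome_path:
                raise DomainError("FB strategy needs fastq_paths and transcriptome_path")
        elif self.counts_path is None:
            raise DomainError(f"{self.strategy} strategy needs counts_path")
        if self.groups_path is None:
            raise DomainError("groups_path is required")
        if self.de_backend not in ("builtin", "external"):
            raise DomainError("de_backend must be 'builtin' or 'external'")
        if self.de_backend == "external" and self.external_de_dir is None:
            raise DomainError("external DE backend needs external_de_dir")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_groups(path: str | Path) -> pd.Series:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["sample_id", "group"], dtype=str,
        comment="#",
    )
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"].to_numpy())


def _quantify_samples(
    fastq_paths: Mapping[str, str],
    quantifier: ExactQuantifier,
    groups: pd.Series,
) -> CountMatrix:
    columns = {}
    for sample_id, path in fastq_paths.items():
        columns[sample_id] = quantifier.quantify(path).counts
    counts = pd.DataFrame(columns, columns=list(fastq_paths)).fillna(0).astype(int)
    return CountMatrix(counts, groups.reindex(list(fastq_paths)))


def _de_for(
    config: PipelineConfig, label: str, matrix: CountMatrix
) -> pd.DataFrame:
    if config.de_backend == "external":
        path = Path(config.external_de_dir) / f"{label}.tsv"
        if not path.exists():
            raise PipelineError(f"stage de: external DE result {path} not found")
        return read_de_result(path)
    return nb_wald_test(matrix, DesignSpec.condition(matrix))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured workflow; returns the run directory.

    Any stage failure aborts with :class:`PipelineError` naming the stage
    (partial runs are not resumable).  Reruns with the same config and
    builtin DE backend are bit-identical.
    """
    out = Path(config.out_dir)
    for sub in ("replicates", "de", "evaluation"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # --- stage: load original data -------------------------------------
    try:
        groups = _read_groups(config.groups_path)
        quantifier = None
        if config.strategy == "FB":
            quantifier = ExactQuantifier(load_transcriptome(config.transcriptome_path))
            reference = _quantify_samples(config.fastq_paths, quantifier, groups)
        else:
            reference = read_counts_tsv(config.counts_path, config.groups_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage load: {exc}") from exc

    ref_label = config.reference_label

    # --- stage: generate replicates ------------------------------------
    replicate_matrices: dict[str, CountMatrix] = {}
    seeds: dict[str, int] = {}
    try:
        for i in range(1, config.b + 1):
            label = f"{config.strategy}{i}"
            rep_seed = config.seed + i
            seeds[label] = rep_seed
            if config.strategy == "CB":
                rep = column_bootstrap(reference, stratify=config.stratify, seed=rep_seed)
            elif config.strategy == "MO":
                spec = MixSpec(
                    dirichlet_alpha=config.dirichlet_alpha,
                    within_group=not config.mix_across_groups,
                    seed=rep_seed,
                )
                rep = mix_observations(reference, spec)
            else:  # FB: bootstrap each sample's FASTQ, re-quantify, clean up
                columns = {}
                for j, (sample_id, fq) in enumerate(config.fastq_paths.items()):
                    boot = out / "replicates" / f"{label}.{sample_id}.fastq"
                    bootstrap_reads(fq, config.pi, rep_seed * 10_000 + j, boot)
                    columns[sample_id] = quantifier.quantify(boot).counts
                    if config.reclaim_space:
                        boot.unlink()
                counts = pd.DataFrame(columns, columns=list(config.fastq_paths))
                rep = CountMatrix(
                    counts.fillna(0).astype(int),
                    groups.reindex(list(config.fastq_paths)),
                )
            replicate_matrices[label] = rep
            cpath = out / "replicates" / f"{label}.counts.tsv"
            gpath = out / "replicates" / f"{label}.groups.tsv"
            write_counts_tsv(rep, cpath, gpath)
            written += [cpath, gpath]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage generate: {exc}") from exc

    # --- stage: differential expression + selection --------------------
    try:
        de_results = {ref_label: _de_for(config, ref_label, reference)}
        for label, rep in replicate_matrices.items():
            de_results[label] = _de_for(config, label, rep)
        selections = {
            label: select_genes(res, config.alpha, config.lfc_threshold)
            for label, res in de_results.items()
        }
        for label, res in de_results.items():
            path = out / "de" / f"{label}.tsv"
            write_de_result(res, path)
            written.append(path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage de: {exc}") from exc

    # --- stage: gene-set over-representation (optional) ----------------
    enriched_sets: dict[str, set] = {}
    if config.gmt_path is not None:
        try:
            collection = read_gmt(config.gmt_path)
            for label, res in de_results.items():
                universe = res.index[res["pvalue"].notna()]
                sel = selections[label] & set(universe)
                ora = fisher_ora(sel, universe, collection, alpha=config.alpha)
                path = out / "de" / f"{label}.ora.tsv"
                ora.to_csv(path, sep="\t")
                written.append(path)
                enriched_sets[label] = set(ora.index[ora["enriched"]])
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage ora: {exc}") from exc

    # --- stage: evaluation ----------------------------------------------
    try:
        eval_dir = out / "evaluation"
        for metric, extract in (
            ("pvalue", lambda res: res["pvalue"]),
            ("abs_log2fc", lambda res: res["log2FoldChange"].abs()),
        ):
            catalog = {label: extract(res) for label, res in de_results.items()}
            dist = spearman_distance(catalog)
            dist.to_csv(eval_dir / f"distance.{metric}.tsv", sep="\t")
            tree = ward_tree(dist)
            (eval_dir / f"tree.{metric}.nwk").write_text(tree.to_newick() + "\n")
            written += [eval_dir / f"distance.{metric}.tsv", eval_dir / f"tree.{metric}.nwk"]

        ov = overlap_matrix(selections)
        ov.round(1).to_csv(eval_dir / "overlap.genes.tsv", sep="\t")
        written.append(eval_dir / "overlap.genes.tsv")
        if enriched_sets:
            ov_sets = overlap_matrix(enriched_sets)
            ov_sets.round(1).to_csv(eval_dir / "overlap.sets.tsv", sep="\t")
            written.append(eval_dir / "overlap.sets.tsv")

        universe = list(de_results[ref_label].index)
        report = stability_report(
            selections[ref_label],
            [selections[f"{config.strategy}{i}"] for i in range(1, config.b + 1)],
            universe,
            reference_pvalues=de_results[ref_label]["pvalue"],
        )
        report.crosstab.to_csv(eval_dir / "stability.crosstab.tsv", sep="\t")
        freq = pd.DataFrame(
            {
                "n_selected": report.frequency,
                "reference_pvalue": report.reference_pvalues,
            }
        )
        freq.to_csv(eval_dir / "stability.frequency.tsv", sep="\t", index_label="gene_id")
        written += [eval_dir / "stability.crosstab.tsv", eval_dir / "stability.frequency.tsv"]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage evaluate: {exc}") from exc

    # --- stage: manifest -------------------------------------------------
    manifest = {
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "replicate_seeds": seeds,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
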