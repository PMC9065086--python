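"""Synthetic experiment generator, toy transcriptome, read simulation."""

import numpy as np
import pytest
from scipy import stats

from repliboot import (
    SimDesign,
    bootstrap_reads,
    build_toy_transcriptome,
    count_reads,
    quantify_exact,
    read_fastq,
    simulate_counts,
    simulate_fastq,
    write_fastq,
)
from repliboot.simulate import ExactQuantifier, load_transcriptome
from repliboot.errors import DomainError


class TestSimDesign:
    def test_defaults_mirror_study_structure(self):
        design = SimDesign()
        assert design.n_per_group == (5, 4)
        assert design.group_labels == ("infected", "control")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_per_group": (1, 4)},
            {"de_fraction": 1.5},
            {"d": 5, "de_fraction": 0.01},
            {"dispersion_alpha": -0.1},
            {"technical_model": "other"},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(DomainError):
            SimDesign(**kwargs)


class TestSimulateCounts:
    def test_shapes_and_truth(self):
        design = SimDesign(d=100, seed=5)
        r1, r2, truth = simulate_counts(design)
        assert r1.n_genes == r2.n_genes == 100
        assert r1.n_samples == 9
        assert r1.sample_ids == r2.sample_ids
        assert truth["is_de"].sum() == 10
        assert (truth.loc[truth["is_de"], "true_log2fc"].abs() == 3.0).all()

    @pytest.mark.parametrize("alpha", [0.1, 0.02])
    def test_null_design_group_ratio_matches_analytic_spread(self, alpha):
        """Without DE genes the estimated |log2FC| of well-expressed genes
        concentrates near zero; its median matches the analytic null
        spread 0.674 * sqrt(alpha * (1/n1 + 1/n2)) / ln 2 (the count-level
        shot noise is negligible for means >= 50)."""
        medians = []
        for seed in range(20):
            design = SimDesign(
                d=300, de_fraction=0.0, dispersion_alpha=alpha,
                mean_log2_range=(6.0, 9.0), seed=seed,
            )
            r1, _, _ = simulate_counts(design)
            vals = r1.values.astype(float)
            grp = r1.groups.to_numpy()
            mean_a = vals[:, grp == "infected"].mean(axis=1)
            mean_b = vals[:, grp == "control"].mean(axis=1)
            well = (vals.mean(axis=1) >= 50) & (mean_a > 0) & (mean_b > 0)
            medians.append(
                np.median(np.abs(np.log2(mean_b[well] / mean_a[well])))
            )
        expected = 0.674 * np.sqrt(alpha * (1 / 5 + 1 / 4)) / np.log(2)
        assert np.median(medians) == pytest.approx(expected, rel=0.25)

    @pytest.mark.parametrize("model", ["poisson_resample", "multinomial_thin"])
    def test_technical_pairs_correlate_more_than_samples(self, model):
        """R1/R2 counts of the same biological sample share a latent level,
        so their rank correlation beats the between-sample correlation."""
        for seed in range(20):
            design = SimDesign(d=300, technical_model=model, seed=seed)
            r1, r2, _ = simulate_counts(design)
            l1 = np.log1p(r1.values.astype(float))
            l2 = np.log1p(r2.values.astype(float))
            within = np.mean(
                [
                    stats.spearmanr(l1[:, j], l2[:, j]).statistic
                    for j in range(r1.n_samples)
                ]
            )
            between = np.mean(
                [
                    stats.spearmanr(l1[:, j], l2[:, (j + 1) % r1.n_samples]).statistic
                    for j in range(r1.n_samples)
                ]
            )
            assert within > between

    def test_poisson_limit_mean_converges(self):
        """alpha=0: counts are Poisson(mu); the average over many draws
        approaches mu."""
        mu = 2.0**6
        totals = []
        for seed in range(150):
            design = SimDesign(
                d=1, de_fraction=0.0, dispersion_alpha=0.0,
                mean_log2_range=(6.0, 6.0), seed=seed,
            )
            r1, _, _ = simulate_counts(design)
            totals.extend(r1.values.ravel().tolist())
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - mu) < 4 * se

    def test_determinism(self):
        a = simulate_counts(SimDesign(d=50, seed=9))
        b = simulate_counts(SimDesign(d=50, seed=9))
        assert (a[0].values == b[0].values).all()
        assert (a[1].values == b[1].values).all()


class TestToyTranscriptome:
    def test_sizes_and_ids(self, tmp_path):
        path = tmp_path / "tx.fasta"
        tx = build_toy_transcriptome(5, 300, seed=1, path=path)
        assert len(tx) == 5
        assert all(len(seq) == 300 for seq in tx.values())
        assert load_transcriptome(path) == tx

    def test_determinism(self):
        assert build_toy_transcriptome(4, 100, seed=2) == build_toy_transcriptome(
            4, 100, seed=2
        )

    def test_pairwise_distinct(self):
        tx = build_toy_transcriptome(2, 50, seed=3)
        a, b = tx.values()
        assert sum(x != y for x, y in zip(a, b)) > 0


class TestSimulateFastq:
    def test_read_count_matches(self, tmp_path):
        tx = build_toy_transcriptome(2, 120, seed=0)
        path = tmp_path / "s.fastq"
        n = simulate_fastq(tx, {"tx1": 3, "tx2": 0}, path, seed=1)
        assert n == 3
        assert count_reads(path) == 3

    def test_reads_are_exact_substrings(self, tmp_path):
        tx = build_toy_transcriptome(3, 200, seed=4)
        path = tmp_path / "s.fastq"
        simulate_fastq(tx, {t: 20 for t in tx}, path, read_length=40, seed=5)
        for rec in read_fastq(path):
            assert any(rec.sequence in seq for seq in tx.values())

    def test_determinism(self, tmp_path):
        tx = build_toy_transcriptome(2, 100, seed=0)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        simulate_fastq(tx, {"tx1": 10, "tx2": 5}, p1, seed=7)
        simulate_fastq(tx, {"tx1": 10, "tx2": 5}, p2, seed=7)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_transcript_rejected(self, tmp_path):
        tx = build_toy_transcriptome(1, 100, seed=0)
        with pytest.raises(DomainError, match="unknown"):
            simulate_fastq(tx, {"nope": 3}, tmp_path / "s.fastq")

    def test_error_rate_corrupts_reads(self, tmp_path):
        tx = build_toy_transcriptome(1, 200, seed=1)
        path = tmp_path / "s.fastq"
        simulate_fastq(tx, {"tx1": 50}, path, read_length=50, error_rate=0.1, seed=2)
        seq = tx["tx1"]
        mismatched = sum(rec.sequence not in seq for rec in read_fastq(path))
        assert mismatched > 25  # P(clean 50-mer) = 0.9^50 ~ 0.005


class TestQuantifyExact:
    def test_roundtrip_recovers_counts(self, tmp_path):
        tx = build_toy_transcriptome(8, 250, seed=11)
        rng = np.random.default_rng(0)
        for seed in range(3):
            counts = {t: int(rng.integers(0, 60)) for t in tx}
            path = tmp_path / f"s{seed}.fastq"
            simulate_fastq(tx, counts, path, seed=seed)
            result = quantify_exact(path, tx)
            assert result.counts == counts
            assert result.n_ambiguous == result.n_unassigned == 0

    def test_empty_fastq_gives_zero_counts(self, tmp_path):
        tx = build_toy_transcriptome(3, 100, seed=0)
        path = tmp_path / "empty.fastq"
        path.write_text("")
        result = quantify_exact(path, tx)
        assert result.counts == {t: 0 for t in tx}

    def test_foreign_read_goes_unassigned_and_totals_conserve(self, tmp_path):
        from repliboot import FastqRecord

        tx = build_toy_transcriptome(2, 100, seed=1)
        path = tmp_path / "mix.fastq"
        recs = [
            FastqRecord("r1", tx["tx1"][:30], "I" * 30),
            FastqRecord("r2", "N" * 30, "I" * 30),
        ]
        write_fastq(recs, path)
        result = quantify_exact(path, tx)
        assert result.n_unassigned == 1
        assert result.n_total == 2
        assert result.n_assigned == 1

    def test_shared_kmer_counts_as_ambiguous(self, tmp_path):
        from repliboot import FastqRecord

        # two transcripts sharing a 30-base block
        block = "ACGT" * 10
        tx = {"t1": block + "A" * 30, "t2": "C" * 30 + block}
        path = tmp_path / "amb.fastq"
        write_fastq([FastqRecord("r1", block[:30], "I" * 30)], path)
        result = quantify_exact(path, tx)
        assert result.n_ambiguous == 1


class TestFbEndToEnd:
    def test_bootstrap_expectation_matches_original_counts(self, tmp_path):
        """pi=1 bootstrap + requantification conserves the total read
        count exactly and the per-transcript counts in expectation."""
        tx = build_toy_transcriptome(5, 200, seed=21)
        counts = {"tx1": 30, "tx2": 20, "tx3": 25, "tx4": 15, "tx5": 10}
        total = sum(counts.values())
        src = tmp_path / "src.fastq"
        simulate_fastq(tx, counts, src, seed=1)
        quantifier = ExactQuantifier(tx)

        n_runs = 200
        sums = {t: 0.0 for t in tx}
        boot = tmp_path / "boot.fastq"
        for seed in range(n_runs):
            bootstrap_reads(src, 1.0, seed, boot, k=total)
            result = quantifier.quantify(boot)
            assert result.n_total == total
            for t, c in result.counts.items():
                sums[t] += c
        for t, expected in counts.items():
            mean = sums[t] / n_runs
            p = expected / total
            se = np.sqrt(total * p * (1 - p)) / np.sqrt(n_runs)
            assert abs(mean - expected) <= 3 * se + 1e-9
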