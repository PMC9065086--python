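"""FASTQ I/O and read-bootstrap (FB) behaviour."""

import gzip
from collections import Counter

import numpy as np
import pytest

from repliboot import (
    FastqRecord,
    bootstrap_reads,
    count_reads,
    read_fastq,
    write_fastq,
)
from repliboot.errors import DomainError, FastqFormatError, PairingError


def _records(path):
    return list(read_fastq(path))


def _stem(read_id):
    return read_id.split(" ")[0].split("/bs")[0]


class TestRecordInvariants:
    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError, match="length"):
            FastqRecord("r1", "ACGT", "III")

    def test_invalid_base_rejected(self):
        with pytest.raises(DomainError, match="invalid bases"):
            FastqRecord("r1", "ACXT", "IIII")

    def test_case_insensitive_alphabet(self):
        rec = FastqRecord("r1", "acgtN", "IIIII")
        assert len(rec) == 5


class TestIO:
    def test_count_reads(self, make_fastq):
        path, _ = make_fastq(4)
        assert count_reads(path) == 4

    def test_count_reads_empty(self, tmp_path):
        path = tmp_path / "empty.fastq"
        write_fastq([], path)
        assert count_reads(path) == 0

    def test_count_reads_gzip_1000(self, make_fastq):
        path, _ = make_fastq(1000, compress=True)
        assert path.suffix == ".gz"
        # independent check: gzip line count / 4
        with gzip.open(path, "rt") as fh:
            n_lines = sum(1 for _ in fh)
        assert n_lines == 4000
        assert count_reads(path) == 1000

    def test_roundtrip_identity(self, make_fastq, tmp_path):
        path, records = make_fastq(3)
        out = tmp_path / "copy.fastq"
        write_fastq(_records(path), out)
        assert _records(out) == records

    @pytest.mark.parametrize(
        "lines, message",
        [
            (["X bad header", "ACGT", "+", "IIII"], "header"),
            (["@r1", "ACGT", "+", "IIII", "@r2", "ACGT"], "truncated"),
            (["@r1", "ACGT", "-", "IIII"], r"\+"),
            (["@r1", "ACGTA", "+", "III"], "length"),
        ],
    )
    def test_malformed_file_names_record(self, tmp_path, lines, message):
        path = tmp_path / "bad.fastq"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FastqFormatError, match=message) as err:
            count_reads(path)
        assert "record" in str(err.value)

    def test_malformed_reports_correct_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\nnot-a-header\nACGT\n+\nIIII\n")
        with pytest.raises(FastqFormatError, match="record 2"):
            count_reads(path)


class TestBootstrap:
    @pytest.mark.parametrize("pi", [1.0, 0.8, 0.75, 0.5])
    def test_size_law(self, make_fastq, tmp_path, pi):
        path, _ = make_fastq(100)
        out = tmp_path / "boot.fastq"
        manifest = bootstrap_reads(path, pi, seed=7, output_path=out)
        expected = int(round(pi * 100))
        assert manifest.m == expected
        assert count_reads(out) == expected

    def test_pi_one_preserves_read_count(self, make_fastq, tmp_path):
        path, _ = make_fastq(100)
        out = tmp_path / "boot.fastq"
        manifest = bootstrap_reads(path, 1.0, seed=3, output_path=out)
        assert manifest.k == manifest.m == 100

    def test_small_draw_contained_in_input(self, make_fastq, tmp_path):
        path, records = make_fastq(10)
        out = tmp_path / "boot.fastq"
        bootstrap_reads(path, 0.5, seed=11, output_path=out)
        input_pairs = {(r.sequence, r.quality) for r in records}
        drawn = _records(out)
        assert len(drawn) == 5
        assert all((r.sequence, r.quality) in input_pairs for r in drawn)

    def test_multiset_containment(self, make_fastq, tmp_path):
        path, records = make_fastq(50, seed=5)
        out = tmp_path / "boot.fastq"
        manifest = bootstrap_reads(path, 1.0, seed=23, output_path=out)
        in_counts = Counter((r.sequence, r.quality) for r in records)
        out_counts = Counter((r.sequence, r.quality) for r in _records(out))
        for key, n_out in out_counts.items():
            assert n_out <= in_counts[key] * manifest.m

    def test_seed_determinism(self, make_fastq, tmp_path):
        path, _ = make_fastq(200)
        out1, out2, out3 = (tmp_path / f"b{i}.fastq" for i in range(3))
        bootstrap_reads(path, 0.8, seed=5, output_path=out1)
        bootstrap_reads(path, 0.8, seed=5, output_path=out2)
        bootstrap_reads(path, 0.8, seed=6, output_path=out3)
        assert out1.read_bytes() == out2.read_bytes()
        assert out1.read_bytes() != out3.read_bytes()

    def test_duplicate_renaming_flag(self, make_fastq, tmp_path):
        path, _ = make_fastq(3)
        out = tmp_path / "boot.fastq"
        # find a seed whose draw repeats at least one read
        for seed in range(50):
            bootstrap_reads(path, 1.0, seed=seed, output_path=out)
            stems = [_stem(r.read_id) for r in _records(out)]
            if len(set(stems)) < len(stems):
                break
        else:  # pragma: no cover - probability ~ (2/9)^50
            pytest.fail("no duplicating draw found")
        ids = [r.read_id for r in _records(out)]
        assert len(set(ids)) == len(ids)  # /bsN disambiguates
        assert any("/bs" in i for i in ids)
        out2 = tmp_path / "boot2.fastq"
        bootstrap_reads(path, 1.0, seed=seed, output_path=out2, rename_duplicates=False)
        raw_ids = [r.read_id for r in _records(out2)]
        assert all("/bs" not in i for i in raw_ids)
        assert [_stem(i) for i in raw_ids] == stems

    def test_emission_preserves_input_order(self, make_fastq, tmp_path):
        path, records = make_fastq(100)
        out = tmp_path / "boot.fastq"
        bootstrap_reads(path, 0.5, seed=2, output_path=out)
        order = {r.read_id: i for i, r in enumerate(records)}
        emitted = [order[_stem(r.read_id)] for r in _records(out)]
        assert emitted == sorted(emitted)

    def test_paired_synchronization(self, make_fastq, tmp_path):
        r1, recs1 = make_fastq(60, path=tmp_path / "R1.fastq", seed=1)
        # mate file: same ids, different sequences
        r2path = tmp_path / "R2.fastq"
        write_fastq(
            [FastqRecord(r.read_id, r.sequence[::-1], r.quality) for r in recs1],
            r2path,
        )
        o1, o2 = tmp_path / "o1.fastq", tmp_path / "o2.fastq"
        manifest = bootstrap_reads(
            r1, 0.75, seed=9, output_path=o1, mate_path=r2path, mate_output_path=o2
        )
        assert manifest.paired
        stems1 = [_stem(r.read_id) for r in _records(o1)]
        stems2 = [_stem(r.read_id) for r in _records(o2)]
        assert stems1 == stems2

    def test_paired_unequal_length_rejected(self, make_fastq, tmp_path):
        r1, _ = make_fastq(10, path=tmp_path / "R1.fastq")
        r2, _ = make_fastq(9, path=tmp_path / "R2.fastq")
        with pytest.raises(PairingError, match="differ in length"):
            bootstrap_reads(
                r1, 1.0, seed=0,
                output_path=tmp_path / "o1.fastq",
                mate_path=r2, mate_output_path=tmp_path / "o2.fastq",
            )

    @pytest.mark.parametrize("pi", [0.0, -0.5, 1.0001])
    def test_pi_domain_error(self, make_fastq, tmp_path, pi):
        path, _ = make_fastq(5)
        with pytest.raises(DomainError, match="pi"):
            bootstrap_reads(path, pi, seed=0, output_path=tmp_path / "o.fastq")

    def test_nonempty_input_draws_at_least_one(self, make_fastq, tmp_path):
        path, _ = make_fastq(1)
        out = tmp_path / "o.fastq"
        manifest = bootstrap_reads(path, 0.25, seed=0, output_path=out)
        assert manifest.m == 1
        assert count_reads(out) == 1

    def test_stated_k_mismatch_detected(self, make_fastq, tmp_path):
        path, _ = make_fastq(10)
        with pytest.raises(DomainError, match="records"):
            bootstrap_reads(path, 1.0, seed=0, output_path=tmp_path / "o.fastq", k=8)

    def test_manifest_roundtrip(self, make_fastq, tmp_path):
        import json

        path, _ = make_fastq(20)
        out = tmp_path / "o.fastq"
        manifest = bootstrap_reads(path, 0.5, seed=4, output_path=out)
        mpath = tmp_path / "manifest.json"
        manifest.save(mpath)
        data = json.loads(mpath.read_text())
        assert data["strategy"] == "FB"
        assert data["k"] == 20 and data["m"] == 10 and data["seed"] == 4

    def test_expected_distinct_read_fraction(self, make_fastq, tmp_path):
        """With pi=1 and k reads, the expected fraction of distinct input
        reads appearing at least once is 1 - (1 - 1/k)^k."""
        k = 10
        path, records = make_fastq(k)
        input_seqs = [r.sequence for r in records]
        out = tmp_path / "boot.fastq"
        n_runs = 1500
        fractions = np.empty(n_runs)
        for s in range(n_runs):
            bootstrap_reads(path, 1.0, seed=s, output_path=out)
            seen = {r.sequence for r in _records(out)}
            fractions[s] = sum(seq in seen for seq in input_seqs) / k
        expected = 1.0 - (1.0 - 1.0 / k) ** k
        se = fractions.std(ddof=1) / np.sqrt(n_runs)
        assert abs(fractions.mean() - expected) < max(3 * se, 0.01)
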