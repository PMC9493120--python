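"""Filter cascade semantics: strict thresholds, adapter handling, accounting."""
import numpy as np
import pytest

from pirnakit.io import ReadRecord, ValidationError
from pirnakit.qc import (
    QCReport,
    filter_N,
    filter_low_quality,
    filter_polyX,
    flag_5p_adapter,
    length_select,
    run_qc,
    trim_3p_adapter,
)
from pirnakit.io import Tag
from pirnakit.synth import SimConfig, emit_raw_fastq, random_clean_tags

ADAPTER3 = "AGATCGGAAGAGCACACGTCT"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


def _read(seq, quals=None):
    return ReadRecord("r", seq, tuple(quals) if quals is not None else None)


class TestLowQuality:
    def test_strictly_more_than_half_drops(self):
        read = _read("A" * 40, [2] * 21 + [30] * 19)
        assert filter_low_quality(read) is False  # 52.5% > 50%

    def test_exactly_half_keeps(self):
        read = _read("A" * 40, [2] * 20 + [30] * 20)
        assert filter_low_quality(read) is True  # 50% is not "more than 50%"

    def test_high_quality_keeps(self):
        assert filter_low_quality(_read("ACGT" * 10, [30] * 40)) is True

    def test_missing_quality_is_an_error(self):
        with pytest.raises(ValidationError, match="FASTA"):
            filter_low_quality(_read("ACGT"))


class TestNContent:
    def test_boundary(self):
        assert filter_N("N" * 6 + "A" * 44) is False  # 12% > 10%
        assert filter_N("N" * 5 + "A" * 45) is True  # exactly 10%
        assert filter_N("ACGT" * 10) is True


class TestPolyX:
    def test_homopolymer_drops(self):
        assert filter_polyX("A" * 24) is False

    def test_balanced_keeps(self):
        assert filter_polyX("ACGT" * 6) is True

    def test_composition_oracle_on_24mer(self):
        seq = "T" * 20 + "ACGA"  # 20/24 = 83% >= 80%
        top = max(seq.count(b) for b in "ACGT")
        assert top / len(seq) >= 0.8
        assert filter_polyX(seq) is False


class TestTrim3p:
    def test_full_adapter(self):
        insert = "TACGTACGTACGTACGTACGTACG"
        assert trim_3p_adapter(insert + ADAPTER3, ADAPTER3) == insert

    def test_no_adapter_flags(self):
        assert trim_3p_adapter("TACG" * 12, ADAPTER3) is None

    def test_truncated_prefix_with_one_mismatch_at_read_end(self):
        insert = "TACGTACGTACGTACGTACGTACG"
        prefix = list(ADAPTER3[:7])
        prefix[3] = "A" if prefix[3] != "A" else "C"
        assert trim_3p_adapter(insert + "".join(prefix), ADAPTER3) == insert

    def test_matches_exhaustive_offset_oracle(self, rng):
        def oracle(seq, adapter, min_overlap=6, max_mismatch=1):
            hits = []
            for i in range(len(seq)):
                k = min(len(adapter), len(seq) - i)
                if k < min_overlap:
                    break
                mm = sum(a != b for a, b in zip(seq[i : i + k], adapter[:k]))
                if mm <= max_mismatch:
                    hits.append(i)
            return seq[: hits[0]] if hits else None

        for _ in range(300):
            n = int(rng.integers(10, 60))
            seq = "".join(rng.choice(list("ACGT"), n))
            if rng.random() < 0.5:  # plant an adapter prefix
                pos = int(rng.integers(0, n))
                seq = seq[:pos] + ADAPTER3[: n - pos]
            assert trim_3p_adapter(seq, ADAPTER3) == oracle(seq, ADAPTER3)


class TestFlag5p:
    def test_read_starting_with_adapter_drops(self):
        assert flag_5p_adapter(ADAPTER5 + "ACGTACGT", ADAPTER5) is True

    def test_adapter_beyond_window_keeps(self):
        read = "TACG" * 10 + ADAPTER5
        assert flag_5p_adapter(read, ADAPTER5) is False


def test_length_select_inclusive_bounds():
    tags = [Tag(f"t{n}", "A" * n, {"s": 1}) for n in (23, 24, 33, 34)]
    kept = length_select(tags)
    assert sorted(len(t) for t in kept) == [24, 33]
    assert length_select([]) == []


class TestRunQC:
    def test_accounting_identity_and_attribution(self, rng):
        cfg = SimConfig(
            seed=11,
            qc_defect_fractions={
                "low_quality": 0.05, "high_n": 0.05, "adapter5": 0.05,
                "no_adapter3": 0.05, "polyx": 0.05,
            },
        )
        tags = random_clean_tags(60, rng, cfg)
        for t in tags:
            t.counts["s"] = 20
        reads, truth = emit_raw_fastq(tags, "s", cfg, rng=np.random.default_rng(1))
        _, report = run_qc(reads, cfg.adapter3, cfg.adapter5)
        report.validate()
        counts = truth["label"].value_counts().to_dict()
        assert report.clean_reads == counts.get("clean", 0)
        for label in (
            "removed_low_quality", "removed_high_N", "removed_5p_adapter",
            "removed_no_3p_adapter", "removed_polyACGT",
        ):
            assert getattr(report, label) == counts.get(label, 0), label

    def test_zero_defects_removes_nothing(self, rng):
        cfg = SimConfig(seed=12, qc_defect_fractions={k: 0.0 for k in ("low_quality", "high_n", "adapter5", "no_adapter3", "polyx")})
        tags = random_clean_tags(40, rng, cfg)
        for t in tags:
            t.counts["s"] = 5
        reads, truth = emit_raw_fastq(tags, "s", cfg, rng=np.random.default_rng(2))
        clean, report = run_qc(reads, cfg.adapter3, cfg.adapter5)
        assert report.removed_total() == 0 and report.clean_reads == len(reads) == 200
        assert (truth["label"] == "clean").all()

    def test_trimmed_insert_equals_planted_tag(self, rng):
        cfg = SimConfig(seed=13, qc_defect_fractions={k: 0.0 for k in ("low_quality", "high_n", "adapter5", "no_adapter3", "polyx")})
        tags = random_clean_tags(10, rng, cfg)
        for t in tags:
            t.counts["s"] = 1
        reads, truth = emit_raw_fastq(tags, "s", cfg, rng=np.random.default_rng(3))
        clean, _ = run_qc(reads, cfg.adapter3, cfg.adapter5)
        by_id = dict(zip(truth["read_id"], truth["tag_id"]))
        seq_of = {t.tag_id: t.sequence for t in tags}
        for rec in clean:
            assert rec.sequence == seq_of[by_id[rec.read_id]]

    def test_report_identity_is_enforced(self):
        rep = QCReport(input_reads=5, clean_reads=5)
        rep.validate()
        rep.clean_reads = 4
        with pytest.raises(ValidationError):
            rep.validate()
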