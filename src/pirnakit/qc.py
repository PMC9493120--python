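"""Raw-read quality control, adapter handling and length selection.

The filter cascade reproduces the standard small-RNA pre-processing rules:

1. low-quality reads (bases with Q <= 5 make up more than 50% of the read),
2. reads with N content > 10%,
3. reads with 5' adapter contamination,
4. reads without a 3' adapter (or with an empty insert after trimming),
5. poly-A/T/C/G reads (one base >= 80% of the trimmed insert),
6. inserts outside the candidate length window (24-33 nt inclusive).

Filters are applied in this order and each removed read is attributed to
the *first* filter that drops it, so the accounting identity
``input = clean + sum(removed)`` always holds. Percentage thresholds are
strict ("more than 50%", "> 10%"); length bounds are inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

from pirnakit.io import ReadRecord, Tag, ValidationError


@dataclass
class QCReport:
    """Per-filter removal accounting for one QC run."""

    input_reads: int = 0
    removed_low_quality: int = 0
    removed_high_N: int = 0
    removed_5p_adapter: int = 0
    removed_no_3p_adapter: int = 0
    removed_polyACGT: int = 0
    removed_length: int = 0
    clean_reads: int = 0

    def removed_total(self) -> int:
        return (
            self.removed_low_quality
            + self.removed_high_N
            + self.removed_5p_adapter
            + self.removed_no_3p_adapter
            + self.removed_polyACGT
            + self.removed_length
        )

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValidationError(f"QCReport: negative {f.name}")
        if self.input_reads != self.clean_reads + self.removed_total():
            raise ValidationError(
                f"QCReport accounting broken: {self.input_reads} input != "
                f"{self.clean_reads} clean + {self.removed_total()} removed"
            )

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def filter_low_quality(read: ReadRecord, qmax: int = 5, frac: float = 0.5) -> bool:
    """Keep unless bases with Q <= ``qmax`` make up more than ``frac`` of the read."""
    if read.quality is None:
        raise ValidationError(
            f"read {read.read_id!r} has no quality scores; FASTA input should skip "
            "quality-based QC"
        )
    n_low = sum(q <= qmax for q in read.quality)
    return not (n_low / len(read) > frac)


def filter_N(sequence: str, frac: float = 0.10) -> bool:
    """Keep unless the N fraction exceeds ``frac`` (strict)."""
    return not (sequence.count("N") / len(sequence) > frac)


def filter_polyX(sequence: str, frac: float = 0.8) -> bool:
    """Keep unless any single base (A/C/G/T) composes >= ``frac`` of the sequence."""
    if not sequence:
        return False
    top = max(sequence.count(b) for b in "ACGT")
    return top / len(sequence) < frac


def trim_3p_adapter(
    sequence: str, adapter: str, min_overlap: int = 6, max_mismatch: int = 1
) -> str | None:
    """Locate the 3' adapter and return the insert, or ``None`` if absent.

    The leftmost position where a prefix of ``adapter`` (at least
    ``min_overlap`` bases, at most ``max_mismatch`` mismatches) aligns to the
    read is taken as the insert boundary. At the read's 3' end the adapter
    may be truncated, so the comparison window shrinks with the offset.
    """
    if len(adapter) < min_overlap:
        raise ValidationError("adapter shorter than min_overlap")
    for i in range(0, len(sequence) - min_overlap + 1):
        k = min(len(adapter), len(sequence) - i)
        if _hamming(sequence[i : i + k], adapter[:k]) <= max_mismatch:
            return sequence[:i]
    return None


def flag_5p_adapter(
    sequence: str, adapter5: str, min_overlap: int = 6, max_mismatch: int = 1
) -> bool:
    """Return ``True`` (drop) if the 5' adapter occurs within the first
    ``len(adapter5)`` bases of the read.

    A match is a prefix of ``adapter5`` of at least ``min_overlap`` bases
    with at most ``max_mismatch`` mismatches, starting inside the window.
    """
    if len(adapter5) < min_overlap:
        raise ValidationError("5' adapter shorter than min_overlap")
    window = len(adapter5)
    for i in range(0, window - min_overlap + 1):
        k = min(len(adapter5), window - i, len(sequence) - i)
        if k < min_overlap:
            break
        if _hamming(sequence[i : i + k], adapter5[:k]) <= max_mismatch:
            return True
    return False


def length_select(tags: Iterable[Tag], lo: int = 24, hi: int = 33) -> list[Tag]:
    """Retain tags whose length is within [lo, hi] inclusive."""
    return [t for t in tags if lo <= len(t) <= hi]


def run_qc(
    records: Iterable[ReadRecord],
    adapter3: str,
    adapter5: str | None = None,
    qmax: int = 5,
    q_frac: float = 0.5,
    n_frac: float = 0.10,
    polyx_frac: float = 0.8,
    min_len: int = 24,
    max_len: int = 33,
    min_overlap: int = 6,
    max_mismatch: int = 1,
) -> tuple[list[ReadRecord], QCReport]:
    """Run the full filter cascade and return (clean trimmed reads, report).

    Reads without quality scores (FASTA input) skip the low-quality filter;
    all other filters operate on the sequence alone.
    """
    report = QCReport()
    clean: list[ReadRecord] = []
    for read in records:
        report.input_reads += 1
        if read.quality is not None and not filter_low_quality(read, qmax, q_frac):
            report.removed_low_quality += 1
            continue
        if not filter_N(read.sequence, n_frac):
            report.removed_high_N += 1
            continue
        if adapter5 and flag_5p_adapter(read.sequence, adapter5, min_overlap, max_mismatch):
            report.removed_5p_adapter += 1
            continue
        insert = trim_3p_adapter(read.sequence, adapter3, min_overlap, max_mismatch)
        if insert is None or len(insert) == 0:
            # "without 3' adapter sequence and insert"
            report.removed_no_3p_adapter += 1
            continue
        if not filter_polyX(insert, polyx_frac):
            report.removed_polyACGT += 1
            continue
        if not (min_len <= len(insert) <= max_len):
            report.removed_length += 1
            continue
        quality = read.quality[: len(insert)] if read.quality is not None else None
        clean.append(ReadRecord(read.read_id, insert, quality))
        report.clean_reads += 1
    report.validate()
    return clean, report
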