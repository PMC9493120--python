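"""Readers, writers and core domain types for small-RNA tag pipelines.

Conventions
-----------
* All genomic intervals are **0-based half-open** internally. BED is native;
  GFF3 (1-based inclusive) is converted at the I/O boundary.
* Sequences are stored as uppercase DNA; ``U`` is normalized to ``T`` on
  read, so "starts with uracil" is tested as ``sequence[0] == 'T'``.
* FASTQ quality is Phred+33 (no offset autodetection).
* Collapsed FASTA headers follow the ``>id_xCOUNT`` dialect common in
  small-RNA work, e.g. ``>t000001_x52`` for a tag seen in 52 reads.
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

PHRED_OFFSET = 33

#: Closed vocabulary of annotation classes.
FEATURE_CLASSES = (
    "CDS",
    "UTR5",
    "UTR3",
    "intron",
    "lncRNA",
    "repeat",
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
)

#: Structural ncRNA classes removed by the exclusion cascade.
NCRNA_CLASSES = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_COLLAPSED_HEADER_RE = re.compile(r"^(?P<tag_id>.+)_x(?P<count>\d+)$")

_GFF_TYPE_TO_CLASS = {
    "CDS": "CDS",
    "five_prime_UTR": "UTR5",
    "three_prime_UTR": "UTR3",
    "intron": "intron",
    "lnc_RNA": "lncRNA",
    "lncRNA": "lncRNA",
    "repeat_region": "repeat",
    "miRNA": "miRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
}
_CLASS_TO_GFF_TYPE = {
    "CDS": "CDS",
    "UTR5": "five_prime_UTR",
    "UTR3": "three_prime_UTR",
    "intron": "intron",
    "lncRNA": "lnc_RNA",
    "repeat": "repeat_region",
    "miRNA": "miRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
}


class ParseError(ValueError):
    """An on-disk record violates its file dialect."""


class ValidationError(ValueError):
    """Coordinates or container invariants are inconsistent."""


def revcomp(sequence: str) -> str:
    """Reverse complement of an uppercase DNA string (N-safe)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def normalize_sequence(sequence: str) -> str:
    """Uppercase, RNA->DNA (U->T), and validate the alphabet {A,C,G,T,N}."""
    seq = sequence.strip().upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ParseError(f"sequence contains non-DNA characters: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ReadRecord:
    """A single sequencing read (quality optional for FASTA input)."""

    read_id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if not self.sequence:
            raise ParseError(f"read {self.read_id!r}: empty sequence")
        if self.quality is not None:
            self.quality = tuple(self.quality)
            if len(self.quality) != len(self.sequence):
                raise ParseError(
                    f"read {self.read_id!r}: quality length {len(self.quality)} "
                    f"!= sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Tag:
    """A unique small-RNA sequence with per-sample read counts.

    Tags are the pipeline's central unit: identical reads are fused into a
    single tag whose ``counts`` map sample identifiers to read counts.
    """

    tag_id: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError(f"tag {self.tag_id!r}: negative count")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def count_in(self, samples: Iterable[str]) -> int:
        return sum(self.counts.get(s, 0) for s in samples)


@dataclass(frozen=True)
class Alignment:
    """A perfect genomic placement of a tag (0-based half-open interval)."""

    tag_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_loci: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"alignment {self.tag_id}: bad interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"alignment {self.tag_id}: bad strand {self.strand!r}")
        if self.n_loci < 1:
            raise ValidationError(f"alignment {self.tag_id}: n_loci must be >= 1")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (strand-aware, 0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Feature:
    """An annotated genomic interval from the closed class vocabulary."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_class: str = "repeat"
    subfamily: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"feature: start {self.start} >= end {self.end}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class PiCluster:
    """A merged genomic region with >= threshold distinct candidate piRNAs."""

    chrom: str
    start: int
    end: int
    n_distinct_tags: int
    total_count: int
    plus_count: int
    minus_count: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("cluster: start >= end")
        if self.plus_count + self.minus_count != self.total_count:
            raise ValidationError("cluster: strand counts do not sum to total")


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a strict 4-line-per-record Phred+33 FASTQ file.

    Yields records in file order, preserving N bases. Malformed records
    raise :class:`ParseError` naming the offending line number.
    """
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(f"{path}: line {lineno}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n")
            if not seq:
                raise ParseError(f"{path}: line {lineno + 1}: missing sequence line")
            plus = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ParseError(f"{path}: line {lineno + 2}: expected '+' separator")
            qual = fh.readline().rstrip("\n")
            if len(qual) != len(seq):
                raise ParseError(
                    f"{path}: line {lineno + 3}: quality length {len(qual)} "
                    f"!= sequence length {len(seq)}"
                )
            lineno += 3
            scores = tuple(ord(c) - PHRED_OFFSET for c in qual)
            if any(q < 0 or q > 93 for q in scores):
                raise ParseError(f"{path}: line {lineno}: quality characters outside Phred+33 range")
            yield ReadRecord(header[1:].split()[0], seq, scores)


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.quality is None:
                raise ValidationError(f"read {rec.read_id!r}: cannot write FASTQ without quality")
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.quality)
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")


def read_collapsed_fasta(path: str | Path, sample_id: str) -> list[Tag]:
    """Read a collapsed FASTA (``>id_xCOUNT`` headers) for one sample."""
    tags: list[Tag] = []
    seen: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COLLAPSED_HEADER_RE.match(rec.id)
        if m is None:
            raise ParseError(
                f"{path}: header {rec.id!r} lacks the '_x<integer>' count suffix"
            )
        seq = normalize_sequence(str(rec.seq))
        if seq in seen:
            raise ParseError(
                f"{path}: records {seen[seq]!r} and {rec.id!r} share one sequence; "
                "input is not collapsed -- use collapse_reads() first"
            )
        seen[seq] = rec.id
        tags.append(Tag(m["tag_id"], seq, {sample_id: int(m["count"])}))
    return tags


def write_collapsed_fasta(tags: Iterable[Tag], sample_id: str, path: str | Path) -> None:
    """Write one sample's tags as collapsed FASTA; zero-count tags are skipped."""
    with open(path, "w") as fh:
        for tag in tags:
            count = tag.counts.get(sample_id, 0)
            if count <= 0:
                continue
            fh.write(f">{tag.tag_id}_x{count}\n{tag.sequence}\n")


def collapse_reads(records: Iterable[ReadRecord], sample_id: str) -> list[Tag]:
    """Fuse identical read sequences into unique tags with summed counts.

    Output order is deterministic: descending count, then lexicographic
    sequence. Tag ids are assigned ``t000001, t000002, ...`` in that order.
    """
    counter: Counter[str] = Counter(rec.sequence for rec in records)
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        Tag(f"t{i + 1:06d}", seq, {sample_id: n}) for i, (seq, n) in enumerate(ordered)
    ]


def merge_tag_sets(tag_lists: Iterable[Sequence[Tag]]) -> list[Tag]:
    """Merge per-sample tag lists into one dataset keyed by sequence.

    Counts for identical sequences are summed per sample; tag ids are
    reassigned deterministically (descending total count, then sequence).
    """
    by_seq: dict[str, dict[str, int]] = {}
    for tags in tag_lists:
        for tag in tags:
            dest = by_seq.setdefault(tag.sequence, {})
            for sample, n in tag.counts.items():
                dest[sample] = dest.get(sample, 0) + n
    ordered = sorted(by_seq.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    return [Tag(f"t{i + 1:06d}", seq, counts) for i, (seq, counts) in enumerate(ordered)]


def read_fasta_genome(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into an in-memory {chrom: sequence} dict."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ParseError(f"{path}: duplicate chromosome id {rec.id!r}")
        genome[rec.id] = normalize_sequence(str(rec.seq))
    return genome


def write_fasta_genome(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------


def _feature_from_bed_name(chrom: str, start: int, end: int, strand: str, name: str) -> Feature:
    # Known class names map directly; anything else is treated as a repeat
    # subfamily (the repeat-annotation convention, e.g. "LINE/L1").
    if name in FEATURE_CLASSES:
        return Feature(chrom, start, end, strand, name, "")
    return Feature(chrom, start, end, strand, "repeat", name)


def read_bed(path: str | Path, chrom_sizes: Mapping[str, int] | None = None) -> list[Feature]:
    """Read a BED6 annotation file (0-based half-open, native convention).

    The name field is interpreted as a feature class when it is one of the
    closed vocabulary, otherwise as a repeat class/family string.
    """
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else "."
            strand = cols[5] if len(cols) > 5 else "."
            if chrom_sizes is not None:
                size = chrom_sizes.get(chrom)
                if size is None or start < 0 or end > size:
                    raise ValidationError(
                        f"{path}: line {lineno}: interval [{start},{end}) outside {chrom!r}"
                    )
            feats.append(_feature_from_bed_name(chrom, start, end, strand, name))
    return feats


def write_bed(items: Sequence[Feature | PiCluster], path: str | Path) -> None:
    """Write features or clusters as BED6.

    Features carry their class (or repeat subfamily) in the name column;
    clusters carry a running id in the name column and the distinct-tag
    count in the score column.
    """
    with open(path, "w") as fh:
        for i, item in enumerate(items, start=1):
            if isinstance(item, PiCluster):
                fh.write(
                    f"{item.chrom}\t{item.start}\t{item.end}\tpicluster_{i}"
                    f"\t{item.n_distinct_tags}\t.\n"
                )
            else:
                name = item.subfamily if item.feature_class == "repeat" and item.subfamily else item.feature_class
                fh.write(f"{item.chrom}\t{item.start}\t{item.end}\t{name}\t0\t{item.strand}\n")


def read_gff3(path: str | Path, chrom_sizes: Mapping[str, int] | None = None) -> list[Feature]:
    """Read a GFF3 annotation; 1-based inclusive coordinates are converted
    to the internal 0-based half-open convention. Unrecognized feature
    types are skipped."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ParseError(f"{path}: line {lineno}: fewer than 8 GFF3 columns")
            cls = _GFF_TYPE_TO_CLASS.get(cols[2])
            if cls is None:
                continue
            start = int(cols[3]) - 1  # 1-based inclusive -> 0-based half-open
            end = int(cols[4])
            strand = cols[6] if cols[6] in ("+", "-") else "."
            subfamily = ""
            if len(cols) > 8:
                m = re.search(r"(?:Family|family)=([^;]+)", cols[8])
                if m:
                    subfamily = m.group(1)
            if chrom_sizes is not None:
                size = chrom_sizes.get(cols[0])
                if size is None or start < 0 or end > size:
                    raise ValidationError(
                        f"{path}: line {lineno}: interval outside chromosome {cols[0]!r}"
                    )
            feats.append(Feature(cols[0], start, end, strand, cls, subfamily))
    return feats


def write_gff3(features: Sequence[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features, start=1):
            attrs = f"ID=feat{i}"
            if f.subfamily:
                attrs += f";Family={f.subfamily}"
            fh.write(
                f"{f.chrom}\tpirnakit\t{_CLASS_TO_GFF_TYPE[f.feature_class]}\t"
                f"{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# SAM ingest
# ---------------------------------------------------------------------------


def read_sam(path: str | Path) -> tuple[list[Alignment], int]:
    """Ingest pre-computed alignments from a SAM file.

    Only perfect placements are kept: mapped records whose CIGAR is pure
    match and whose edit distance (``NM`` tag, 0 when absent) is zero.
    Everything else is rejected and tallied. ``n_loci`` is the number of
    accepted placements per query name within the file.

    Returns ``(alignments, n_rejected)``.
    """
    accepted: list[tuple[str, str, int, int, str]] = []
    rejected = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                rejected += 1
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            pure_match = all(op in (0, 7, 8) for op, _ in (rec.cigartuples or []))
            if nm != 0 or not pure_match:
                rejected += 1
                continue
            accepted.append(
                (
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
            )
    loci = Counter(name for name, *_ in accepted)
    alignments = [
        Alignment(name, chrom, start, end, strand, loci[name])
        for name, chrom, start, end, strand in accepted
    ]
    return alignments, rejected


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    """Write a TSV with an optional ``# key=value`` metadata block on top."""
    with open(path, "w") as fh:
        if meta:
            for key, value in meta.items():
                fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
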