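"""Exact genomic placement, ncRNA exclusion cascade, 1U/10A candidate
calling, and genomic-region / transposable-element origin attribution.

Only structural ncRNAs (miRNA, rRNA, tRNA, snRNA, snoRNA) are *excluded*;
overlap with CDS, UTRs, introns, lncRNAs and repeats is *annotated* as the
tag's genomic origin, since candidate piRNAs are expected to derive from
intron, CDS and repeat sequence.

Multi-mapping tags keep all perfect placements; proportion statistics
weight each placement 1/n_loci so total tag mass is conserved, while
cluster membership (see :mod:`pirnakit.clusters`) uses unweighted presence.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from pirnakit.io import (
    NCRNA_CLASSES,
    Alignment,
    Feature,
    Tag,
    ValidationError,
    revcomp,
)

#: Assignment priority when an alignment overlaps several feature classes.
REGION_PRIORITY = ("CDS", "UTR5", "UTR3", "intron", "lncRNA", "repeat")
REGION_CLASSES = REGION_PRIORITY + ("intergenic",)

#: Class I retrotransposon orders and Class II DNA transposons.
TE_CLASS_I = ("LINE", "SINE", "LTR")
TE_CLASS_II = ("DNA",)
TE_CLASSES = TE_CLASS_I + TE_CLASS_II + ("other",)


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    """All (possibly overlapping) start offsets of needle in haystack."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def align_exact(
    tags: Sequence[Tag], genome: Mapping[str, str]
) -> tuple[dict[str, list[Alignment]], list[str]]:
    """Place each tag at every exact occurrence on either genome strand.

    Returns ``(alignments_by_tag, unplaced_tag_ids)``. ``n_loci`` on each
    alignment is the tag's total number of perfect placements genome-wide.
    A reverse-complement occurrence at ``[s, s+L)`` is reported as a
    minus-strand alignment on that interval.
    """
    result: dict[str, list[Alignment]] = {}
    unplaced: list[str] = []
    for tag in tags:
        hits: list[tuple[str, int, int, str]] = []
        rc = revcomp(tag.sequence)
        for chrom, seq in genome.items():
            for s in _find_all(seq, tag.sequence):
                hits.append((chrom, s, s + len(tag), "+"))
            for s in _find_all(seq, rc):
                hits.append((chrom, s, s + len(tag), "-"))
        if not hits:
            unplaced.append(tag.tag_id)
            continue
        n = len(hits)
        result[tag.tag_id] = [
            Alignment(tag.tag_id, chrom, s, e, strand, n) for chrom, s, e, strand in hits
        ]
    return result, unplaced


def build_interval_index(features: Iterable[Feature]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees holding Feature payloads."""
    index: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for f in features:
        index[f.chrom].addi(f.start, f.end, f)
    return dict(index)


def _overlapping(
    index: Mapping[str, IntervalTree], aln: Alignment
) -> list[Feature]:
    tree = index.get(aln.chrom)
    if tree is None:
        return []
    return [iv.data for iv in tree.overlap(aln.start, aln.end)]


@dataclass
class AnnotationCascade:
    """Ordered exclusion steps: (label, feature list) pairs.

    A tag is removed when any of its alignments overlaps (>= 1 bp, either
    strand) a feature of any step; the removal is attributed to the first
    matching step, so tallies depend on the order while the surviving set
    does not.
    """

    steps: list[tuple[str, list[Feature]]]

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.steps]
        if len(set(labels)) != len(labels):
            raise ValidationError("cascade labels must be unique")

    @classmethod
    def from_ncrna(cls, ncrna: Iterable[Feature]) -> "AnnotationCascade":
        """Standard cascade in the fixed order miRNA, rRNA, tRNA, snRNA, snoRNA."""
        by_class: dict[str, list[Feature]] = defaultdict(list)
        for f in ncrna:
            by_class[f.feature_class].append(f)
        return cls([(label, by_class.get(label, [])) for label in NCRNA_CLASSES])


def exclude_known(
    tags: Sequence[Tag],
    alignments: Mapping[str, Sequence[Alignment]],
    cascade: AnnotationCascade,
) -> tuple[list[Tag], dict[str, int]]:
    """Remove tags overlapping cascade features; tally removals per class."""
    indexes = [(label, build_interval_index(feats)) for label, feats in cascade.steps]
    tally = {label: 0 for label, _ in cascade.steps}
    kept: list[Tag] = []
    for tag in tags:
        removed = False
        for label, index in indexes:
            if any(_overlapping(index, aln) for aln in alignments.get(tag.tag_id, [])):
                tally[label] += 1
                removed = True
                break
        if not removed:
            kept.append(tag)
    return kept, tally


def is_candidate(sequence: str) -> bool:
    """The 1U-or-10A signature: U at position 1 or A at position 10."""
    return sequence[0] == "T" or sequence[9] == "A"


def call_candidates(tags: Sequence[Tag]) -> list[Tag]:
    """Retain candidate piRNAs: tags with 1U or 10A.

    Tags are expected to be length-selected (24-33 nt) already; anything
    shorter than 10 bases indicates a pipeline error upstream.
    """
    for tag in tags:
        if len(tag) < 10:
            raise ValidationError(
                f"tag {tag.tag_id!r} is {len(tag)} nt; candidate calling requires "
                ">= 10 nt (length selection missing?)"
            )
    return [t for t in tags if is_candidate(t.sequence)]


def region_of_alignment(aln: Alignment, index: Mapping[str, IntervalTree]) -> str:
    """Highest-priority feature class overlapping the alignment, else intergenic."""
    classes = {f.feature_class for f in _overlapping(index, aln)}
    for cls in REGION_PRIORITY:
        if cls in classes:
            return cls
    return "intergenic"


def assign_region(
    alignments: Mapping[str, Sequence[Alignment]],
    features: Iterable[Feature],
    tag_weights: Mapping[str, float] | None = None,
) -> tuple[dict[str, str], pd.Series]:
    """Genomic-region origin per tag plus the region proportion table.

    Each alignment is assigned the highest-priority overlapping class
    (CDS > UTR5 > UTR3 > intron > lncRNA > repeat > intergenic). A tag's
    single reported region is its highest-priority class across loci; the
    proportion table spreads each tag's mass 1/n_loci over its placements
    (optionally scaled by ``tag_weights``, e.g. read counts).
    """
    index = build_interval_index(features)
    per_tag: dict[str, str] = {}
    mass = pd.Series(0.0, index=list(REGION_CLASSES))
    for tag_id, alns in alignments.items():
        w = 1.0 if tag_weights is None else float(tag_weights.get(tag_id, 0.0))
        best = "intergenic"
        for aln in alns:
            cls = region_of_alignment(aln, index)
            mass[cls] += w / aln.n_loci
            if REGION_CLASSES.index(cls) < REGION_CLASSES.index(best):
                best = cls
        per_tag[tag_id] = best
    total = mass.sum()
    proportions = mass / total if total > 0 else mass
    return per_tag, proportions


def te_class_of_family(subfamily: str) -> str:
    """Map a repeat class/family string (e.g. 'LINE/L1') to its TE class."""
    order = subfamily.split("/")[0].upper()
    if order in TE_CLASS_I or order in TE_CLASS_II:
        return order
    return "other"


def assign_te_class(
    alignments: Mapping[str, Sequence[Alignment]],
    repeats: Iterable[Feature],
    tag_weights: Mapping[str, float] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """TE-origin per tag and the TE-class tally.

    Only repeat-overlapping alignments contribute. The tally carries one
    row per TE order (LINE/SINE/LTR/DNA/other) with its 1/n_loci-weighted
    mass and the Class I / Class II grouping.
    """
    index = build_interval_index(f for f in repeats if f.feature_class == "repeat")
    mass = {cls: 0.0 for cls in TE_CLASSES}
    per_tag: dict[str, str] = {}
    priority = {cls: i for i, cls in enumerate(TE_CLASSES)}
    for tag_id, alns in alignments.items():
        w = 1.0 if tag_weights is None else float(tag_weights.get(tag_id, 0.0))
        best: str | None = None
        for aln in alns:
            overlapping = _overlapping(index, aln)
            if not overlapping:
                continue
            cls = min((te_class_of_family(f.subfamily) for f in overlapping), key=priority.get)
            mass[cls] += w / aln.n_loci
            if best is None or priority[cls] < priority[best]:
                best = cls
        if best is not None:
            per_tag[tag_id] = best
    table = pd.DataFrame(
        {
            "te_class": list(TE_CLASSES),
            "mass": [mass[c] for c in TE_CLASSES],
            "te_group": ["Class I" if c in TE_CLASS_I else "Class II" if c in TE_CLASS_II else "other" for c in TE_CLASSES],
        }
    )
    total = table["mass"].sum()
    table["proportion"] = table["mass"] / total if total > 0 else 0.0
    return per_tag, table


@dataclass
class CandidateSet:
    """Candidate piRNAs with their alignments and origin annotations."""

    tags: list[Tag]
    alignments: dict[str, list[Alignment]]
    region_by_tag: dict[str, str] = field(default_factory=dict)
    te_by_tag: dict[str, str] = field(default_factory=dict)

    def table(self, samples: Sequence[str] | None = None) -> pd.DataFrame:
        rows = []
        for tag in self.tags:
            alns = self.alignments.get(tag.tag_id, [])
            row = {
                "tag_id": tag.tag_id,
                "sequence": tag.sequence,
                "length": len(tag),
                "total_count": tag.total_count,
                "n_loci": alns[0].n_loci if alns else 0,
                "first_base": tag.sequence[0],
                "base10": tag.sequence[9],
                "region": self.region_by_tag.get(tag.tag_id, ""),
                "te_class": self.te_by_tag.get(tag.tag_id, ""),
            }
            if samples:
                for s in samples:
                    row[s] = tag.counts.get(s, 0)
            rows.append(row)
        return pd.DataFrame(rows)


def annotate_candidates(
    tags: Sequence[Tag],
    genome: Mapping[str, str],
    features: Iterable[Feature],
    repeats: Iterable[Feature],
    ncrna: Iterable[Feature],
) -> tuple[CandidateSet, dict[str, int], list[str]]:
    """Full cascade: align, exclude known ncRNAs, call 1U/10A candidates,
    and annotate genomic/TE origin.

    Returns ``(candidate_set, exclusion_tally, unplaced_tag_ids)``.
    """
    alignments, unplaced = align_exact(tags, genome)
    placed = [t for t in tags if t.tag_id in alignments]
    cascade = AnnotationCascade.from_ncrna(ncrna)
    survivors, tally = exclude_known(placed, alignments, cascade)
    candidates = call_candidates(survivors)
    cand_alns = {t.tag_id: alignments[t.tag_id] for t in candidates}
    all_features = list(features) + [f for f in repeats if f.feature_class == "repeat"]
    region_by_tag, _ = assign_region(cand_alns, all_features)
    te_by_tag, _ = assign_te_class(cand_alns, repeats)
    return CandidateSet(candidates, cand_alns, region_by_tag, te_by_tag), tally, unplaced
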