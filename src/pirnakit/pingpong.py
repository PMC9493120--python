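"""The ping-pong 5'-overlap signature.

Secondary piRNA biogenesis (the ping-pong cycle) leaves a footprint:
opposite-strand read pairs whose 5' ends overlap by exactly 10 nt, with
uracil at position 1 of one mate and adenine at position 10 of the other.
This module computes the distribution of 5'-overlap lengths between
plus/minus alignment pairs, an enrichment z-score for the 10-nt bin, and
the base composition of bin-10 partners.

Overlap geometry: for a plus-strand alignment ``p`` and a minus-strand
alignment ``m`` on the same chromosome with intersecting intervals, the
overlap is the number of bases from p's 5' end to m's 5' end inclusive,
i.e. ``m.end - p.start``.
"""
from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pirnakit.io import Alignment, ValidationError

MAX_OVERLAP = 30


@dataclass
class OverlapHistogram:
    """Weights per 5'-overlap length (1..30) plus the bin-10 z-score."""

    weights: np.ndarray  # index 0 <-> overlap 1
    z10: float | None
    zero_variance: bool
    pairs10: list[tuple[str, str, float]] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"overlap": np.arange(1, MAX_OVERLAP + 1), "weight": self.weights}
        )


def pingpong_zscore(weights: np.ndarray) -> tuple[float | None, bool]:
    """Enrichment of the 10-nt bin against all other bins.

    z10 = (w10 - mean(w_k, k != 10)) / sd(w_k, k != 10). A perfectly flat
    histogram scores 0 by symmetry; otherwise, when the non-10 bins have
    zero variance, the score is undefined and flagged.
    """
    if len(weights) != MAX_OVERLAP:
        raise ValidationError(f"expected {MAX_OVERLAP} bins, got {len(weights)}")
    others = np.delete(weights, 9)
    sd = float(np.std(others, ddof=1))
    if sd == 0.0:
        if weights[9] == others.mean():
            return 0.0, False
        return None, True
    return float((weights[9] - others.mean()) / sd), False


def overlap_histogram(
    alignments: Sequence[Alignment],
    tag_counts: Mapping[str, int] | None = None,
    weight: str = "product",
) -> OverlapHistogram:
    """All opposite-strand overlapping pairs, binned by 5'-overlap length.

    ``weight="product"`` accumulates the product of the two tags' read
    counts per pair; ``weight="unique"`` counts each pair once. Pairs whose
    overlap is exactly 10 are retained (tag ids + weight) for partner base
    composition.
    """
    if weight not in ("product", "unique"):
        raise ValidationError("weight must be 'product' or 'unique'")

    def count_of(tag_id: str) -> float:
        if weight == "unique" or tag_counts is None:
            return 1.0
        return float(tag_counts.get(tag_id, 0))

    plus_by_chrom: dict[str, list[Alignment]] = defaultdict(list)
    minus_by_chrom: dict[str, list[Alignment]] = defaultdict(list)
    for aln in alignments:
        (plus_by_chrom if aln.strand == "+" else minus_by_chrom)[aln.chrom].append(aln)

    weights = np.zeros(MAX_OVERLAP)
    pairs10: list[tuple[str, str, float]] = []
    for chrom, plus in plus_by_chrom.items():
        minus = minus_by_chrom.get(chrom)
        if not minus:
            continue
        plus.sort(key=lambda a: a.start)
        starts = [a.start for a in plus]
        for m in minus:
            # overlap = m.end - p.start in [1, 30] => p.start in [m.end-30, m.end-1]
            lo = bisect_left(starts, m.end - MAX_OVERLAP)
            hi = bisect_right(starts, m.end - 1)
            for p in plus[lo:hi]:
                if m.start >= p.end:  # intervals must intersect
                    continue
                overlap = m.end - p.start
                wgt = count_of(p.tag_id) * count_of(m.tag_id) if weight == "product" else 1.0
                weights[overlap - 1] += wgt
                if overlap == 10:
                    pairs10.append((p.tag_id, m.tag_id, wgt))
    z10, flag = pingpong_zscore(weights)
    return OverlapHistogram(weights, z10, flag, pairs10)


def partner_base_freq(
    hist: OverlapHistogram, sequences: Mapping[str, str]
) -> pd.DataFrame:
    """Base composition at positions 1 and 10 of bin-10 overlap partners.

    Both mates of every 10-nt-overlap pair contribute with the pair's
    weight. Returns a frequency table (rows: positions 1 and 10; columns
    A/C/G/T); empty when no bin-10 pairs exist.
    """
    bases = ("A", "C", "G", "T")
    if not hist.pairs10:
        return pd.DataFrame(columns=bases, index=pd.Index([], name="position"))
    counts = {1: dict.fromkeys(bases, 0.0), 10: dict.fromkeys(bases, 0.0)}
    for p_tag, m_tag, wgt in hist.pairs10:
        for tag_id in (p_tag, m_tag):
            seq = sequences[tag_id]
            for pos in (1, 10):
                base = seq[pos - 1]
                if base in counts[pos]:
                    counts[pos][base] += wgt
    df = pd.DataFrame(counts).T
    df.index.name = "position"
    return df.div(df.sum(axis=1), axis=0)
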