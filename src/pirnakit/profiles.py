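"""Descriptive sequence statistics of candidate piRNAs.

Length distributions, positional nucleotide frequencies and the
first-base uracil fraction, each in two weightings: ``"reads"``
(count-weighted, one unit per sequenced read) and ``"tags"`` (one unit
per unique sequence). Positions are 1-based from the 5' end, matching
the field convention that "10A" means adenine at position 10.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pirnakit.io import Tag, ValidationError

BASES = ("A", "C", "G", "T")


def _weight(tag: Tag, weighting: str, samples: Sequence[str] | None) -> float:
    if weighting == "tags":
        return 1.0
    if weighting == "reads":
        return float(tag.total_count if samples is None else tag.count_in(samples))
    raise ValidationError(f"unknown weighting {weighting!r}; use 'reads' or 'tags'")


def length_distribution(
    tags: Iterable[Tag],
    lo: int = 24,
    hi: int = 33,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Histogram of tag lengths over [lo, hi], in both weightings.

    Returns a DataFrame indexed by length with columns ``read_count``
    (sum of per-read counts) and ``tag_count`` (unique sequences).
    """
    idx = range(lo, hi + 1)
    reads = pd.Series(0.0, index=idx)
    uniq = pd.Series(0, index=idx)
    for tag in tags:
        n = len(tag)
        if lo <= n <= hi:
            reads[n] += tag.total_count if samples is None else tag.count_in(samples)
            uniq[n] += 1
    out = pd.DataFrame({"length": list(idx), "read_count": reads.values, "tag_count": uniq.values})
    return out.set_index("length")


def positional_base_freq(
    tags: Iterable[Tag],
    weighting: str = "tags",
    max_position: int = 33,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-position base frequencies over the 5'->3' read.

    Position ``p`` (1-based) only receives contributions from tags at
    least ``p`` bases long, so every row sums to 1 wherever any tag
    reaches that position. N bases are excluded from the denominator.
    """
    counts = np.zeros((max_position, len(BASES)))
    base_idx = {b: i for i, b in enumerate(BASES)}
    for tag in tags:
        w = _weight(tag, weighting, samples)
        if w == 0:
            continue
        for p, base in enumerate(tag.sequence[:max_position]):
            j = base_idx.get(base)
            if j is not None:
                counts[p, j] += w
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, counts / totals, 0.0)
    return pd.DataFrame(freq, index=pd.RangeIndex(1, max_position + 1, name="position"), columns=BASES)


def first_base_u_fraction(
    tags: Iterable[Tag],
    weighting: str = "tags",
    samples: Sequence[str] | None = None,
) -> float:
    """Fraction of tags (or reads) whose first base is U (stored as T)."""
    num = 0.0
    den = 0.0
    for tag in tags:
        w = _weight(tag, weighting, samples)
        den += w
        if tag.sequence[0] == "T":
            num += w
    return num / den if den > 0 else float("nan")
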