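"""Seeded synthetic data emulating a two-phase ovarian small-RNA study.

The generator plants every statistical structure the downstream analyses
are built to detect, with full determinism under a fixed seed:

* a random genome with piRNA clusters placed in configurable genomic
  region classes (intron/CDS/repeat/UTR/lncRNA/intergenic) and, for
  repeats, transposable-element families (LINE/SINE/LTR/DNA/other);
* cluster tags with a 1U bias at a configurable rate (non-1U tags receive
  a 10A rescue so the candidate rule is informative, mirroring primary
  vs. secondary piRNA signatures);
* antisense ping-pong partner tags whose 5' ends overlap the primary tag
  by exactly 10 nt (the partner's signature base falls out of the
  complementarity: a 1U primary implies a 10A partner and vice versa);
* negative-binomial per-sample counts for two phases (FP = follicular,
  LP = luteal) x n replicates, with a planted fold change in a chosen
  fraction of clusters;
* structural-ncRNA and non-genomic contaminant tags so the exclusion
  cascade has true positives to remove;
* optional raw FASTQ with a 3' adapter and planted QC defects
  (low-quality, high-N, 5'-adapter contamination, missing 3' adapter,
  poly-X), each read's class recorded in a truth table.

Truth tables (cluster level and tag level) accompany every dataset so
recovery can be scored exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from pirnakit import qc as qc_mod
from pirnakit.io import (
    Feature,
    ReadRecord,
    Tag,
    revcomp,
    write_bed,
    write_collapsed_fasta,
    write_fasta_genome,
    write_tsv,
)

PHASES = ("FP", "LP")

DEFAULT_LENGTH_DIST = {
    24: 0.20, 25: 0.06, 26: 0.07, 27: 0.14, 28: 0.15,
    29: 0.13, 30: 0.08, 31: 0.07, 32: 0.05, 33: 0.05,
}
DEFAULT_REGION_MIX = {
    "intron": 0.30, "CDS": 0.20, "repeat": 0.20, "intergenic": 0.15,
    "UTR5": 0.05, "UTR3": 0.05, "lncRNA": 0.05,
}
DEFAULT_TE_MIX = {"LINE": 0.45, "SINE": 0.15, "LTR": 0.20, "DNA": 0.12, "other": 0.08}
DEFAULT_BACKGROUND = {
    "miRNA": 20, "rRNA": 15, "tRNA": 15, "snRNA": 8, "snoRNA": 8, "nongenomic": 20,
}
DEFAULT_QC_DEFECTS = {
    "low_quality": 0.02, "high_n": 0.01, "adapter5": 0.01,
    "no_adapter3": 0.03, "polyx": 0.01,
}

#: Representative repeat class/family string per TE order.
TE_FAMILY = {
    "LINE": "LINE/L1",
    "SINE": "SINE/MIR",
    "LTR": "LTR/ERV1",
    "DNA": "DNA/hAT",
    "other": "Unknown",
}

#: ncRNA annotation plan per chromosome-independent dataset: (count, length).
NCRNA_PLAN = {"miRNA": (8, 90), "rRNA": (3, 1500), "tRNA": (10, 75), "snRNA": (5, 150), "snoRNA": (5, 120)}

_REGION_CLASSES = ("CDS", "UTR5", "UTR3", "intron", "lncRNA", "repeat", "intergenic")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """A simulation configuration violates its constraints."""


def _check_probs(name: str, dist: Mapping[object, float], allowed: Iterable[object] | None = None) -> None:
    total = float(sum(dist.values()))
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {total!r}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ConfigError(f"{name}: negative probability")
    if allowed is not None:
        extra = set(dist) - set(allowed)
        if extra:
            raise ConfigError(f"{name}: unknown keys {sorted(map(str, extra))}")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic two-phase dataset.

    Defaults emulate the target study: 6 replicates per phase, candidate
    lengths 24-33 nt with peaks at 24 and 27-29 nt, >75% first-base U
    (``frac_1U=0.8``), clusters mainly in intron/CDS/repeat regions,
    LINE-dominated TE origins, and a ping-pong partner rate high enough to
    produce a clear 10-nt overlap peak.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 500_000
    n_clusters: int = 30
    cluster_span: tuple[int, int] = (2000, 8000)
    tags_per_cluster: tuple[int, int] = (15, 40)
    frac_1U: float = 0.8
    pingpong_rate: float = 0.5
    length_dist: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    region_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REGION_MIX))
    te_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TE_MIX))
    n_samples_per_phase: int = 6
    de_fraction: float = 0.2
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    tag_mean_count: float = 30.0
    partner_mean_scale: float = 0.7
    background: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    background_mean_count: float = 20.0
    repeat_copies: int = 1
    cluster_chrom_weights: tuple[float, ...] | None = None
    cluster_min_separation: int = 25_000
    adapter3: str = "AGATCGGAAGAGCACACGTCT"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    read_length: int = 50
    qc_defect_fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_QC_DEFECTS))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        if self.n_chroms < 1 or self.chrom_length < 10_000:
            raise ConfigError("need at least one chromosome of >= 10 kb")
        _check_probs("length_dist", self.length_dist)
        if any(not (24 <= length <= 33) for length in self.length_dist):
            raise ConfigError("length_dist keys must lie in 24..33")
        _check_probs("region_mix", self.region_mix, _REGION_CLASSES)
        _check_probs("te_mix", self.te_mix, TE_FAMILY)
        for name, pair in (("cluster_span", self.cluster_span), ("tags_per_cluster", self.tags_per_cluster)):
            lo, hi = pair
            if not (0 < lo <= hi):
                raise ConfigError(f"{name}: need 0 < lo <= hi")
        for name, value in (("frac_1U", self.frac_1U), ("pingpong_rate", self.pingpong_rate), ("de_fraction", self.de_fraction)):
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.n_samples_per_phase < 1:
            raise ConfigError("n_samples_per_phase must be >= 1")
        if self.repeat_copies < 1:
            raise ConfigError("repeat_copies must be >= 1")
        if self.cluster_chrom_weights is not None and len(self.cluster_chrom_weights) != self.n_chroms:
            raise ConfigError("cluster_chrom_weights must have one weight per chromosome")
        bad = set(self.qc_defect_fractions) - set(DEFAULT_QC_DEFECTS)
        if bad:
            raise ConfigError(f"unknown QC defect classes: {sorted(bad)}")
        if any(f < 0 for f in self.qc_defect_fractions.values()):
            raise ConfigError("QC defect fractions must be >= 0")
        if sum(self.qc_defect_fractions.values()) > 1.0 + 1e-12:
            raise ConfigError("QC defect fractions sum above 1")
        if not self.adapter3:
            raise ConfigError("adapter3 must be non-empty")

    @property
    def samples(self) -> list[str]:
        return [f"{ph}{i}" for ph in PHASES for i in range(1, self.n_samples_per_phase + 1)]

    @property
    def samples_by_phase(self) -> dict[str, list[str]]:
        return {ph: [s for s in self.samples if s.startswith(ph)] for ph in PHASES}


@dataclass
class SyntheticDataset:
    """A generated genome + annotations + planted truth (+ counts)."""

    config: SimConfig
    genome: dict[str, str]
    features: list[Feature]
    repeats: list[Feature]
    ncrna: list[Feature]
    cluster_truth: pd.DataFrame
    tag_truth: pd.DataFrame
    counts: pd.DataFrame | None = None

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def sample_tags(self, sample: str) -> list[Tag]:
        """Collapsed tags (by sequence) expressed in one sample."""
        if self.counts is None:
            raise ConfigError("counts not simulated yet; run simulate_reads()")
        by_seq: dict[str, int] = {}
        for uid, seq in zip(self.tag_truth["tag_uid"], self.tag_truth["sequence"]):
            c = int(self.counts.at[uid, sample])
            if c > 0:
                by_seq[seq] = by_seq.get(seq, 0) + c
        ordered = sorted(by_seq.items(), key=lambda kv: (-kv[1], kv[0]))
        return [Tag(f"t{i + 1:06d}", seq, {sample: n}) for i, (seq, n) in enumerate(ordered)]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
        write_fasta_genome(self.genome, outdir / "genome.fa")
        write_bed([f for f in self.features if f.feature_class != "repeat"], outdir / "features.bed")
        write_bed(self.repeats, outdir / "repeats.bed")
        write_bed(self.ncrna, outdir / "ncrna.bed")
        write_tsv(self.cluster_truth, outdir / "truth" / "clusters.tsv")
        write_tsv(self.tag_truth.drop(columns=["sequence"]).assign(sequence=self.tag_truth["sequence"]), outdir / "truth" / "tags.tsv")
        if self.counts is not None:
            write_tsv(self.counts.rename_axis("tag_uid").reset_index(), outdir / "truth" / "counts.tsv")
            for sample in self.config.samples:
                write_collapsed_fasta(self.sample_tags(sample), sample, outdir / f"sample_{sample}.fa")
        sheet = pd.DataFrame({"sample": self.config.samples, "phase": [s[:2] for s in self.config.samples]})
        write_tsv(sheet, outdir / "samplesheet.tsv")


# ---------------------------------------------------------------------------
# genome + structural truth
# ---------------------------------------------------------------------------


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _overlaps(iv: tuple[int, int], existing: list[tuple[int, int]]) -> bool:
    s, e = iv
    return any(s < oe and os_ < e for os_, oe in existing)


def _reserve(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    chrom: str,
    chrom_len: int,
    length: int,
    expand: int = 0,
    edge_margin: int = 200,
) -> int:
    """Reserve an unoccupied interval; returns its (unexpanded) start.

    Placement samples directly from the free gaps (weighted by the number
    of valid start positions), so dense configurations pack reliably
    instead of failing by rejection-sampling fragmentation.
    """
    need = length + 2 * expand
    gaps: list[tuple[int, int]] = []
    prev = edge_margin
    for s, e in sorted(occupied[chrom]):
        if s - prev >= need:
            gaps.append((prev, s))
        prev = max(prev, e)
    if (chrom_len - edge_margin) - prev >= need:
        gaps.append((prev, chrom_len - edge_margin))
    if not gaps:
        raise ConfigError(
            f"no room left on {chrom} for a {length} bp interval; increase "
            "chrom_length or reduce n_clusters/cluster_min_separation"
        )
    weights = np.array([hi - lo - need + 1 for lo, hi in gaps], dtype=float)
    lo, hi = gaps[int(rng.choice(len(gaps), p=weights / weights.sum()))]
    start = int(rng.integers(lo, hi - need + 1))
    occupied[chrom].append((start, start + need))
    return start + expand


def _reserve_any(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    preferred: str,
    chrom_names: list[str],
    chrom_len: int,
    length: int,
    expand: int = 0,
) -> tuple[str, int]:
    """Reserve on the preferred chromosome, falling back to the others in
    order when it has no gap left (dense configurations)."""
    for chrom in [preferred] + [c for c in chrom_names if c != preferred]:
        try:
            return chrom, _reserve(rng, occupied, chrom, chrom_len, length, expand)
        except ConfigError:
            continue
    raise ConfigError(
        f"no chromosome has room for a {length} bp interval; increase "
        "chrom_length or reduce n_clusters/cluster_min_separation"
    )


def simulate_genome(config: SimConfig) -> SyntheticDataset:
    """Generate the genome, annotations, and structural truth tables.

    Planted base edits (1U/10A signatures) are applied before the genome is
    finalized, so tag sequences recorded in the truth table align to the
    emitted genome exactly. Repeat-unit copies (multi-mapping) are pasted
    after all edits so every copy carries the signature bases.
    """
    rng = np.random.default_rng([config.seed, 11])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    arrays = {c: _BASE_BYTES[rng.integers(0, 4, config.chrom_length)] for c in chrom_names}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    lengths = np.array(sorted(config.length_dist))
    length_p = np.array([config.length_dist[int(k)] for k in lengths], dtype=float)
    length_p = length_p / length_p.sum()

    region_names = list(config.region_mix)
    region_p = np.array([config.region_mix[r] for r in region_names], dtype=float)
    region_p = region_p / region_p.sum()
    te_names = list(config.te_mix)
    te_p = np.array([config.te_mix[t] for t in te_names], dtype=float)
    te_p = te_p / te_p.sum()

    chrom_w = config.cluster_chrom_weights
    chrom_p = (
        np.full(config.n_chroms, 1.0 / config.n_chroms)
        if chrom_w is None
        else np.array(chrom_w, dtype=float) / float(sum(chrom_w))
    )

    # --- clusters -----------------------------------------------------------
    cluster_rows: list[dict] = []
    sep = config.cluster_min_separation
    for i in range(config.n_clusters):
        preferred = chrom_names[int(rng.choice(config.n_chroms, p=chrom_p))]
        span = int(rng.integers(config.cluster_span[0], config.cluster_span[1] + 1))
        chrom, start = _reserve_any(
            rng, occupied, preferred, chrom_names, config.chrom_length, span, expand=(sep + 1) // 2
        )
        region = region_names[int(rng.choice(len(region_names), p=region_p))]
        te = te_names[int(rng.choice(len(te_names), p=te_p))] if region == "repeat" else ""
        cluster_rows.append(
            {
                "cluster_id": f"c{i + 1:03d}",
                "chrom": chrom,
                "start": start,
                "end": start + span,
                "region_class": region,
                "te_family": TE_FAMILY[te] if te else "",
                "te_class": te,
                "de": False,
                "up_phase": "",
                "log2fc": 0.0,
            }
        )

    n_de = round(config.de_fraction * config.n_clusters)
    if n_de > 0:
        chosen = sorted(rng.choice(config.n_clusters, size=n_de, replace=False).tolist())
        for rank, idx in enumerate(chosen):
            cluster_rows[idx]["de"] = True
            cluster_rows[idx]["up_phase"] = PHASES[rank % 2]
            cluster_rows[idx]["log2fc"] = config.de_log2fc

    # --- annotation intervals ----------------------------------------------
    features: list[Feature] = []
    repeats: list[Feature] = []
    for row in cluster_rows:
        if row["region_class"] == "intergenic":
            continue
        pad = int(rng.integers(100, 400))
        feat = Feature(
            row["chrom"],
            max(0, row["start"] - pad),
            row["end"] + pad,
            "+",
            row["region_class"],
            row["te_family"],
        )
        features.append(feat)
        if row["region_class"] == "repeat":
            repeats.append(feat)

    ncrna: list[Feature] = []
    for cls, (count, length) in NCRNA_PLAN.items():
        for _ in range(count):
            chrom = chrom_names[int(rng.integers(config.n_chroms))]
            start = _reserve(rng, occupied, chrom, config.chrom_length, length)
            ncrna.append(Feature(chrom, start, start + length, "+", cls))

    # best-effort background features exercise the priority rules; skipped when
    # a dense configuration leaves no room
    for _ in range(20):
        chrom = chrom_names[int(rng.integers(config.n_chroms))]
        length = int(rng.integers(500, 3000))
        try:
            start = _reserve(rng, occupied, chrom, config.chrom_length, length)
        except ConfigError:
            continue
        cls = ("CDS", "intron", "UTR5", "UTR3", "lncRNA", "repeat")[int(rng.integers(6))]
        fam = TE_FAMILY[te_names[int(rng.choice(len(te_names), p=te_p))]] if cls == "repeat" else ""
        feat = Feature(chrom, start, start + length, "+", cls, fam)
        features.append(feat)
        if cls == "repeat":
            repeats.append(feat)

    # --- tags ---------------------------------------------------------------
    def set_read_base(chrom: str, pos: int, strand: str, base: str) -> None:
        genome_base = base if strand == "+" else _COMP[base]
        arrays[chrom][pos] = ord(genome_base)

    tag_rows: list[dict] = []
    uid_counter = 0

    def next_uid() -> str:
        nonlocal uid_counter
        uid_counter += 1
        return f"sim{uid_counter:06d}"

    for row in cluster_rows:
        chrom, cs, ce = row["chrom"], row["start"], row["end"]
        n_tags = int(rng.integers(config.tags_per_cluster[0], config.tags_per_cluster[1] + 1))
        for _ in range(n_tags):
            length = int(rng.choice(lengths, p=length_p))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                s = int(rng.integers(cs, ce - length + 1))
                e = s + length
                pos1, pos10 = s, s + 9
            else:
                e = int(rng.integers(cs + length, ce + 1))
                s = e - length
                pos1, pos10 = e - 1, e - 10
            is_1u = bool(rng.random() < config.frac_1U)
            if is_1u:
                set_read_base(chrom, pos1, strand, "T")
            else:
                set_read_base(chrom, pos1, strand, ("A", "C", "G")[int(rng.integers(3))])
                set_read_base(chrom, pos10, strand, "A")  # 10A rescue keeps the tag a candidate
            mean = config.tag_mean_count * float(rng.lognormal(0.0, 0.5))
            primary_uid = next_uid()
            tag_rows.append(
                {
                    "tag_uid": primary_uid,
                    "cluster_id": row["cluster_id"],
                    "role": "primary",
                    "partner_of": "",
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "strand": strand,
                    "length": length,
                    "is_1u": is_1u,
                    "mean_count": mean,
                    "de": row["de"],
                    "up_phase": row["up_phase"],
                    "log2fc": row["log2fc"],
                }
            )
            if rng.random() < config.pingpong_rate:
                plen = int(rng.choice(lengths, p=length_p))
                if strand == "+":
                    # partner is antisense; its 5' end sits 10 nt into the primary
                    m_end = s + 10
                    p_iv = (m_end - plen, m_end)
                    p_strand = "-"
                else:
                    p_start = e - 10
                    p_iv = (p_start, p_start + plen)
                    p_strand = "+"
                if p_iv[0] < 0 or p_iv[1] > config.chrom_length:
                    continue
                tag_rows.append(
                    {
                        "tag_uid": next_uid(),
                        "cluster_id": row["cluster_id"],
                        "role": "partner",
                        "partner_of": primary_uid,
                        "chrom": chrom,
                        "start": p_iv[0],
                        "end": p_iv[1],
                        "strand": p_strand,
                        "length": plen,
                        "is_1u": None,
                        "mean_count": mean * config.partner_mean_scale,
                        "de": row["de"],
                        "up_phase": row["up_phase"],
                        "log2fc": row["log2fc"],
                    }
                )

    # --- repeat-unit copies (multi-mapping) ---------------------------------
    copy_plan: list[tuple[str, int, int, str, int]] = []
    if config.repeat_copies > 1:
        for row in cluster_rows:
            if row["region_class"] != "repeat":
                continue
            span = row["end"] - row["start"]
            for _ in range(config.repeat_copies - 1):
                chrom, start = _reserve_any(
                    rng, occupied, row["chrom"], chrom_names, config.chrom_length, span, expand=(sep + 1) // 2
                )
                copy_plan.append((row["chrom"], row["start"], row["end"], chrom, start))
                pad = int(rng.integers(100, 400))
                feat = Feature(chrom, max(0, start - pad), start + span + pad, "+", "repeat", row["te_family"])
                features.append(feat)
                repeats.append(feat)
    for src_chrom, src_start, src_end, dst_chrom, dst_start in copy_plan:
        span = src_end - src_start
        arrays[dst_chrom][dst_start : dst_start + span] = arrays[src_chrom][src_start:src_end]

    genome = {c: arrays[c].tobytes().decode("ascii") for c in chrom_names}

    # --- contaminants --------------------------------------------------------
    ncrna_by_class: dict[str, list[Feature]] = {}
    for f in ncrna:
        ncrna_by_class.setdefault(f.feature_class, []).append(f)
    for cls, n in config.background.items():
        for _ in range(n):
            length = int(rng.choice(lengths, p=length_p))
            mean = config.background_mean_count * float(rng.lognormal(0.0, 0.5))
            if cls == "nongenomic":
                tag_rows.append(
                    {
                        "tag_uid": next_uid(),
                        "cluster_id": "",
                        "role": "nongenomic",
                        "partner_of": "",
                        "chrom": "",
                        "start": -1,
                        "end": -1,
                        "strand": ".",
                        "length": length,
                        "is_1u": None,
                        "mean_count": mean,
                        "de": False,
                        "up_phase": "",
                        "log2fc": 0.0,
                        "sequence": _rand_seq(rng, length),
                    }
                )
                continue
            hosts = ncrna_by_class.get(cls, [])
            if not hosts:
                raise ConfigError(f"background demands {cls!r} but no such annotation was generated")
            host = hosts[int(rng.integers(len(hosts)))]
            s = int(rng.integers(host.start, host.end - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            tag_rows.append(
                {
                    "tag_uid": next_uid(),
                    "cluster_id": "",
                    "role": f"contaminant_{cls}",
                    "partner_of": "",
                    "chrom": host.chrom,
                    "start": s,
                    "end": s + length,
                    "strand": strand,
                    "length": length,
                    "is_1u": None,
                    "mean_count": mean,
                    "de": False,
                    "up_phase": "",
                    "log2fc": 0.0,
                }
            )

    # --- finalize sequences ---------------------------------------------------
    for trow in tag_rows:
        if "sequence" in trow:
            continue
        seq = genome[trow["chrom"]][trow["start"] : trow["end"]]
        trow["sequence"] = revcomp(seq) if trow["strand"] == "-" else seq

    cluster_truth = pd.DataFrame(cluster_rows)
    if cluster_truth.empty:
        cluster_truth = pd.DataFrame(
            columns=["cluster_id", "chrom", "start", "end", "region_class", "te_family", "te_class", "de", "up_phase", "log2fc"]
        )
    tag_columns = [
        "tag_uid", "cluster_id", "role", "partner_of", "chrom", "start", "end", "strand",
        "length", "is_1u", "mean_count", "de", "up_phase", "log2fc", "sequence",
    ]
    tag_truth = pd.DataFrame(tag_rows, columns=tag_columns)
    features.sort(key=lambda f: (f.chrom, f.start))
    repeats.sort(key=lambda f: (f.chrom, f.start))
    ncrna.sort(key=lambda f: (f.chrom, f.start))
    return SyntheticDataset(config, genome, features, repeats, ncrna, cluster_truth, tag_truth)


def simulate_reads(dataset: SyntheticDataset) -> pd.DataFrame:
    """Draw per-sample negative-binomial counts for every planted tag.

    Counts are gamma-Poisson draws with variance mu + alpha*mu^2. For a
    cluster with a planted fold change the up-phase keeps the base mean
    and the other phase is scaled down by 2^-log2fc, so phase-specific
    clusters are obtained with a large log2fc. Sets ``dataset.counts``
    (tag_uid x sample) and returns it.
    """
    config = dataset.config
    rng = np.random.default_rng([config.seed, 12])
    truth = dataset.tag_truth
    samples = config.samples
    n_tags = len(truth)
    if n_tags == 0:
        dataset.counts = pd.DataFrame(index=pd.Index([], name="tag_uid"), columns=samples, dtype=int)
        return dataset.counts
    base = truth["mean_count"].to_numpy(dtype=float)
    mu = np.tile(base[:, None], (1, len(samples)))
    for j, sample in enumerate(samples):
        phase = sample[:2]
        down = truth["de"].to_numpy() & (truth["up_phase"].to_numpy() != phase)
        mu[down, j] = base[down] * 2.0 ** (-truth["log2fc"].to_numpy()[down])
    alpha = config.nb_dispersion
    if alpha < 1e-12:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(1.0 / alpha, mu * alpha)
        counts = rng.poisson(lam)
    dataset.counts = pd.DataFrame(
        counts.astype(int), index=pd.Index(truth["tag_uid"], name="tag_uid"), columns=samples
    )
    return dataset.counts


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Convenience wrapper: genome + annotations + counts in one call."""
    dataset = simulate_genome(config)
    simulate_reads(dataset)
    return dataset


# ---------------------------------------------------------------------------
# raw FASTQ with planted QC defects
# ---------------------------------------------------------------------------

_DEFECT_CLASSES = ("low_quality", "high_n", "adapter5", "no_adapter3", "polyx")
_LABEL_OF_DEFECT = {
    "low_quality": "removed_low_quality",
    "high_n": "removed_high_N",
    "adapter5": "removed_5p_adapter",
    "no_adapter3": "removed_no_3p_adapter",
    "polyx": "removed_polyACGT",
}


def classify_read(read: ReadRecord, config: SimConfig) -> str:
    """First-failing-filter label for a read under the default QC cascade."""
    _, report = qc_mod.run_qc([read], config.adapter3, config.adapter5)
    for name, value in report.as_dict().items():
        if name.startswith("removed_") and value:
            return name
    return "clean"


def random_clean_tags(n: int, rng: np.random.Generator, config: SimConfig) -> list[Tag]:
    """Random 24-33 nt tags whose assembled reads verify as clean.

    Tags whose sequence would intrinsically trip a filter (e.g. a chance
    5'-adapter-like prefix) are rejection-sampled away so planted-defect
    accounting over the emitted FASTQ is exact.
    """
    lengths = np.array(sorted(config.length_dist))
    length_p = np.array([config.length_dist[int(k)] for k in lengths], dtype=float)
    tags = []
    while len(tags) < n:
        length = int(rng.choice(lengths, p=length_p / length_p.sum()))
        seq = _rand_seq(rng, length)
        read = _assemble_read("probe", seq, rng, config)
        if classify_read(read, config) == "clean":
            tags.append(Tag(f"t{len(tags) + 1:06d}", seq, {}))
    return tags


def _assemble_read(read_id: str, insert: str, rng: np.random.Generator, config: SimConfig) -> ReadRecord:
    body = insert + config.adapter3
    if len(body) < config.read_length:
        body += _rand_seq(rng, config.read_length - len(body))
    body = body[: config.read_length]
    return ReadRecord(read_id, body, (40,) * len(body))


def _make_defect_read(
    read_id: str, insert: str, defect: str, rng: np.random.Generator, config: SimConfig
) -> ReadRecord:
    L = config.read_length
    if defect == "low_quality":
        read = _assemble_read(read_id, insert, rng, config)
        n_low = math.floor(0.5 * L) + 1
        qual = list(read.quality)
        for i in range(n_low):
            qual[i] = 2
        return ReadRecord(read_id, read.sequence, tuple(qual))
    if defect == "high_n":
        read = _assemble_read(read_id, insert, rng, config)
        n_n = math.floor(0.10 * L) + 1
        positions = rng.choice(L, size=n_n, replace=False)
        seq = list(read.sequence)
        for p in positions:
            seq[p] = "N"
        return ReadRecord(read_id, "".join(seq), read.quality)
    if defect == "adapter5":
        body = (config.adapter5 + insert + config.adapter3)[:L]
        if len(body) < L:
            body += _rand_seq(rng, L - len(body))
        return ReadRecord(read_id, body, (40,) * L)
    if defect == "no_adapter3":
        body = insert + _rand_seq(rng, L - len(insert))
        return ReadRecord(read_id, body[:L], (40,) * L)
    if defect == "polyx":
        return _assemble_read(read_id, "A" * len(insert), rng, config)
    raise ConfigError(f"unknown defect class {defect!r}")


def emit_raw_fastq(
    tags: Sequence[Tag],
    sample_id: str,
    config: SimConfig,
    counts: Mapping[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Expand tags into raw 50 bp reads with the 3' adapter appended.

    Each read is independently assigned a defect class (or none) from
    ``config.qc_defect_fractions``. Every constructed read is verified
    against the QC cascade and re-drawn (fresh pad/defect positions) until
    its realized class matches the intended one; when a tag's own sequence
    makes the intended class unreachable the realized class is recorded
    instead, so the returned truth table is exact either way.

    Returns ``(reads, truth)`` with truth columns read_id, tag_id, label.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 13])
    fracs = config.qc_defect_fractions
    labels = ["clean"] + list(_DEFECT_CLASSES)
    probs = np.array([1.0 - sum(fracs.values())] + [fracs.get(c, 0.0) for c in _DEFECT_CLASSES])
    if probs[0] < -1e-12:
        raise ConfigError("QC defect fractions sum above 1")
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()

    reads: list[ReadRecord] = []
    rows: list[dict] = []
    counter = 0
    for tag in tags:
        n_reads = int(counts[tag.tag_id]) if counts is not None else tag.counts.get(sample_id, tag.total_count)
        for _ in range(n_reads):
            counter += 1
            read_id = f"{sample_id}_r{counter:06d}"
            intent = labels[int(rng.choice(len(labels), p=probs))]
            expected = "clean" if intent == "clean" else _LABEL_OF_DEFECT[intent]
            read = realized = None
            for _attempt in range(50):
                read = (
                    _assemble_read(read_id, tag.sequence, rng, config)
                    if intent == "clean"
                    else _make_defect_read(read_id, tag.sequence, intent, rng, config)
                )
                realized = classify_read(read, config)
                if realized == expected:
                    break
            reads.append(read)
            rows.append({"read_id": read_id, "tag_id": tag.tag_id, "label": realized})
    return reads, pd.DataFrame(rows, columns=["read_id", "tag_id", "label"])


# ---------------------------------------------------------------------------
# direct count-matrix simulation (for DE calibration/recovery studies)
# ---------------------------------------------------------------------------


def simulate_counts(
    n_tags: int,
    n_per_group: int = 6,
    dispersion: float = 0.1,
    de_fraction: float = 0.0,
    de_log2fc: float = 2.0,
    base_mean_median: float = 150.0,
    base_mean_sigma: float = 0.6,
    seed: int = 0,
    group_labels: tuple[str, str] = ("FP", "LP"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Two-group NB count matrix with an optional planted fold change.

    Base means are lognormal around ``base_mean_median``. A fraction
    ``de_fraction`` of tags receives a true |log2FC| of ``de_log2fc`` with
    random direction (the down group's mean is scaled by 2^-log2fc).

    Returns ``(counts, truth, groups)``; truth carries ``de`` and the
    signed ``true_log2fc`` (group A over group B).
    """
    rng = np.random.default_rng([seed, 21])
    a, b = group_labels
    samples = [f"{a}{i + 1}" for i in range(n_per_group)] + [f"{b}{i + 1}" for i in range(n_per_group)]
    groups = pd.Series([a] * n_per_group + [b] * n_per_group, index=samples)
    base = rng.lognormal(math.log(base_mean_median), base_mean_sigma, n_tags)
    true_lfc = np.zeros(n_tags)
    n_de = round(de_fraction * n_tags)
    if n_de > 0:
        idx = rng.choice(n_tags, size=n_de, replace=False)
        signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
        true_lfc[idx] = signs * de_log2fc
    mu = np.tile(base[:, None], (1, 2 * n_per_group))
    down_in_b = true_lfc > 0
    down_in_a = true_lfc < 0
    mu[np.ix_(down_in_b, np.arange(n_per_group, 2 * n_per_group))] *= 2.0 ** (-de_log2fc)
    mu[np.ix_(down_in_a, np.arange(n_per_group))] *= 2.0 ** (-de_log2fc)
    if dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        counts = rng.poisson(rng.gamma(1.0 / dispersion, mu * dispersion))
    index = pd.Index([f"tag{i + 1:05d}" for i in range(n_tags)], name="tag_id")
    counts_df = pd.DataFrame(counts.astype(int), index=index, columns=samples)
    truth = pd.DataFrame({"de": true_lfc != 0.0, "true_log2fc": true_lfc}, index=index)
    return counts_df, truth, groups
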