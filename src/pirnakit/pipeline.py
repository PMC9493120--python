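"""End-to-end orchestration: simulate/load -> QC -> candidate calling ->
profiles -> clusters -> ping-pong -> differential expression -> report.

Configuration is a plain mapping (usually loaded from YAML). A run is
fully deterministic given its seed: all randomness flows from named
substreams of the single config seed. Every stage writes self-describing
TSVs (metadata block + column headers) into the output directory and the
run ends with a markdown report summarizing the panel set: QC accounting,
candidate counts per phase, length/base profiles, per-chromosome cluster
densities, ping-pong z-scores and the DE screen.
"""
from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

import pirnakit
from pirnakit import annotate, clusters as clusters_mod, diffexp, pingpong as pingpong_mod, profiles, qc as qc_mod
from pirnakit.io import (
    Tag,
    collapse_reads,
    merge_tag_sets,
    read_bed,
    read_collapsed_fasta,
    read_fasta_genome,
    read_gff3,
    write_bed,
    write_collapsed_fasta,
    write_fastq,
    write_tsv,
)
from pirnakit.synth import PHASES, SimConfig, SyntheticDataset, emit_raw_fastq, simulate_dataset

log = logging.getLogger("pirnakit")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {"emit_fastq": False},
    "qc": {
        "adapter3": "AGATCGGAAGAGCACACGTCT",
        "adapter5": "GTTCAGAGTTCTACAGTCCGACGATC",
        "qmax": 5,
        "q_frac": 0.5,
        "n_frac": 0.10,
        "polyx_frac": 0.8,
        "min_len": 24,
        "max_len": 33,
    },
    "clusters": {"window": 5000, "max_gap": 20000, "min_distinct": 10, "require_both_strands": False},
    "pingpong": {"weight": "product"},
    "de": {"p_max": 0.05, "fc_min": 2.0, "count_min": 10},
}


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and a machine-readable code."""

    def __init__(self, stage: str, message: str, code: str = "stage_failure"):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = code


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: Mapping[str, Any]) -> dict:
    cfg: dict[str, Any] = {}
    for key, value in DEFAULT_CONFIG.items():
        if isinstance(value, dict):
            cfg[key] = {**value, **dict(user.get(key, {}) or {})}
        else:
            cfg[key] = user.get(key, value)
    for key in user:
        if key not in cfg:
            cfg[key] = user[key]
    return cfg


def validate_config(cfg: Mapping[str, Any]) -> list[str]:
    """Return a list of violations; empty means the config is runnable."""
    v: list[str] = []
    seed = cfg.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        v.append("seed: must be a non-negative integer")
    cl = cfg.get("clusters", {})
    if cl.get("window", 1) <= 0:
        v.append("clusters.window: must be positive")
    if cl.get("min_distinct", 1) <= 0:
        v.append("clusters.min_distinct: must be positive")
    if cl.get("max_gap", 1) <= 0:
        v.append("clusters.max_gap: must be positive")
    elif cl.get("window", 0) > cl.get("max_gap", 0):
        v.append("clusters.window: must not exceed clusters.max_gap")
    de = cfg.get("de", {})
    if not (0 < de.get("p_max", 0.05) <= 1):
        v.append("de.p_max: must lie in (0, 1]")
    if de.get("fc_min", 2.0) <= 1:
        v.append("de.fc_min: must exceed 1")
    if de.get("count_min", 10) < 0:
        v.append("de.count_min: must be non-negative")
    pp = cfg.get("pingpong", {})
    if pp.get("weight", "product") not in ("product", "unique"):
        v.append("pingpong.weight: must be 'product' or 'unique'")
    qc_cfg = cfg.get("qc", {})
    if not (0 < qc_cfg.get("min_len", 24) <= qc_cfg.get("max_len", 33)):
        v.append("qc.min_len/max_len: need 0 < min_len <= max_len")
    if not qc_cfg.get("adapter3"):
        v.append("qc.adapter3: must be non-empty")
    has_sim = "simulate" in cfg and cfg["simulate"] is not None
    inputs = cfg.get("inputs")
    if inputs:
        for key in ("genome", "features", "repeats", "ncrna"):
            path = inputs.get(key)
            if path is None:
                v.append(f"inputs.{key}: missing path")
            elif not Path(path).exists():
                v.append(f"inputs.{key}: path does not exist: {path}")
        samples = inputs.get("samples") or {}
        if not samples:
            v.append("inputs.samples: at least one collapsed FASTA required")
        for sample, path in samples.items():
            if not Path(path).exists():
                v.append(f"inputs.samples.{sample}: path does not exist: {path}")
    elif not has_sim:
        v.append("config: needs either a 'simulate' section or an 'inputs' section")
    if has_sim:
        sim = {k: val for k, val in (cfg["simulate"] or {}).items() if k != "emit_fastq"}
        try:
            _sim_config(cfg.get("seed", 0), sim)
        except Exception as exc:  # surfacing SimConfig's own message
            v.append(f"simulate: {exc}")
    return v


def _sim_config(seed: int, sim: Mapping[str, Any]) -> SimConfig:
    fields = dict(sim)
    for key in ("cluster_span", "tags_per_cluster", "cluster_chrom_weights"):
        if key in fields and fields[key] is not None:
            fields[key] = tuple(fields[key])
    return SimConfig(seed=seed, **fields)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def _meta(cfg: Mapping[str, Any], **extra: Any) -> dict[str, Any]:
    base = {"pirnakit_version": pirnakit.__version__, "seed": cfg.get("seed", 0)}
    base.update(extra)
    return base


@_stage("inputs")
def _prepare_inputs(cfg, outdir: Path):
    """Either simulate a dataset or load user-provided files.

    Returns (genome, features, repeats, ncrna, per_sample_tags, phases,
    dataset-or-None, qc_reports dict).
    """
    qc_cfg = cfg["qc"]
    qc_reports: dict[str, qc_mod.QCReport] = {}
    if cfg.get("inputs"):
        inputs = cfg["inputs"]
        genome = read_fasta_genome(inputs["genome"])
        sizes = {c: len(s) for c, s in genome.items()}
        reader = read_gff3 if str(inputs["features"]).endswith((".gff", ".gff3")) else read_bed
        features = reader(inputs["features"], sizes)
        repeats = read_bed(inputs["repeats"], sizes)
        ncrna = read_bed(inputs["ncrna"], sizes)
        per_sample = {
            sample: read_collapsed_fasta(path, sample)
            for sample, path in inputs["samples"].items()
        }
        sheet = inputs.get("samplesheet")
        if sheet:
            df = pd.read_csv(sheet, sep="\t", comment="#")
            phases = dict(zip(df["sample"], df["phase"]))
        else:
            phases = {s: s[:2] for s in per_sample}
        return genome, features, repeats, ncrna, per_sample, phases, None, qc_reports

    sim_section = dict(cfg.get("simulate") or {})
    emit_fastq = bool(sim_section.pop("emit_fastq", False))
    sim_config = _sim_config(cfg.get("seed", 0), sim_section)
    dataset = simulate_dataset(sim_config)
    inputs_dir = outdir / "inputs"
    dataset.write(inputs_dir)
    per_sample: dict[str, list[Tag]] = {}
    for i, sample in enumerate(sim_config.samples):
        tags = dataset.sample_tags(sample)
        if emit_fastq:
            rng = np.random.default_rng([sim_config.seed, 13, i])
            reads, truth = emit_raw_fastq(tags, sample, sim_config, rng=rng)
            write_fastq(reads, inputs_dir / f"sample_{sample}.fastq")
            write_tsv(truth, inputs_dir / "truth" / f"fastq_{sample}.tsv")
            clean, report = qc_mod.run_qc(
                reads,
                qc_cfg["adapter3"],
                qc_cfg.get("adapter5"),
                qmax=qc_cfg["qmax"],
                q_frac=qc_cfg["q_frac"],
                n_frac=qc_cfg["n_frac"],
                polyx_frac=qc_cfg["polyx_frac"],
                min_len=qc_cfg["min_len"],
                max_len=qc_cfg["max_len"],
            )
            qc_reports[sample] = report
            tags = collapse_reads(clean, sample)
        per_sample[sample] = tags
    phases = {s: s[:2] for s in sim_config.samples}
    return dataset.genome, dataset.features, dataset.repeats, dataset.ncrna, per_sample, phases, dataset, qc_reports


@_stage("call")
def _call_candidates(cfg, genome, features, repeats, ncrna, per_sample, outdir: Path):
    merged = merge_tag_sets(per_sample.values())
    selected = qc_mod.length_select(merged, cfg["qc"]["min_len"], cfg["qc"]["max_len"])
    cand_set, tally, unplaced = annotate.annotate_candidates(selected, genome, features, repeats, ncrna)
    samples = sorted({s for tags in per_sample.values() for t in tags for s in t.counts})
    table = cand_set.table(samples)
    write_tsv(table, outdir / "candidates.tsv", _meta(cfg, n_candidates=len(cand_set.tags), n_unplaced=len(unplaced)))
    tally_df = pd.DataFrame(
        {"class": list(tally), "removed_tags": list(tally.values())}
    )
    write_tsv(tally_df, outdir / "exclusion_tally.tsv", _meta(cfg))
    with open(outdir / "alignments.bed", "w") as fh:
        for tag in cand_set.tags:
            for aln in cand_set.alignments[tag.tag_id]:
                fh.write(f"{aln.chrom}\t{aln.start}\t{aln.end}\t{aln.tag_id}\t{aln.n_loci}\t{aln.strand}\n")
    return cand_set, merged


@_stage("profile")
def _profile(cfg, cand_set, phases, outdir: Path):
    summary_rows = []
    for phase in sorted(set(phases.values())):
        phase_samples = [s for s, p in phases.items() if p == phase]
        tags = [t for t in cand_set.tags if t.count_in(phase_samples) > 0]
        ld = profiles.length_distribution(tags, samples=phase_samples)
        write_tsv(ld.reset_index(), outdir / f"length_dist_{phase}.tsv", _meta(cfg, phase=phase))
        for weighting in ("reads", "tags"):
            bf = profiles.positional_base_freq(tags, weighting=weighting, samples=phase_samples)
            write_tsv(bf.reset_index(), outdir / f"base_freq_{weighting}_{phase}.tsv", _meta(cfg, phase=phase))
        summary_rows.append(
            {
                "phase": phase,
                "n_candidate_tags": len(tags),
                "n_candidate_reads": int(sum(t.count_in(phase_samples) for t in tags)),
                "first_base_u_tags": profiles.first_base_u_fraction(tags, "tags"),
                "first_base_u_reads": profiles.first_base_u_fraction(tags, "reads", samples=phase_samples),
            }
        )
    summary = pd.DataFrame(summary_rows)
    write_tsv(summary, outdir / "profile_summary.tsv", _meta(cfg))
    return summary


def _phase_alignments(cand_set, phases, phase):
    phase_samples = [s for s, p in phases.items() if p == phase]
    alns = []
    counts = {}
    for tag in cand_set.tags:
        c = tag.count_in(phase_samples)
        if c > 0:
            counts[tag.tag_id] = c
            alns.extend(cand_set.alignments[tag.tag_id])
    alns.sort(key=lambda a: (a.chrom, a.start))
    return alns, counts


@_stage("clusters")
def _clusters(cfg, cand_set, phases, chrom_sizes, outdir: Path):
    params = clusters_mod.ClusterParams(
        window=cfg["clusters"]["window"],
        max_gap=cfg["clusters"]["max_gap"],
        min_distinct=cfg["clusters"]["min_distinct"],
    )
    per_phase = {}
    density_frames = []
    for phase in sorted(set(phases.values())):
        alns, counts = _phase_alignments(cand_set, phases, phase)
        found = clusters_mod.scan_clusters(
            alns, params, counts, require_both_strands=cfg["clusters"]["require_both_strands"]
        )
        per_phase[phase] = found
        write_bed(found, outdir / f"clusters_{phase}.bed")
        dens = clusters_mod.cluster_density_by_chrom(found, chrom_sizes)
        dens.insert(0, "phase", phase)
        density_frames.append(dens)
    write_tsv(pd.concat(density_frames, ignore_index=True), outdir / "cluster_density.tsv", _meta(cfg))
    phases_sorted = sorted(per_phase)
    if len(phases_sorted) == 2:
        a, b = phases_sorted
        comp = clusters_mod.compare_cluster_sets(per_phase[a], per_phase[b])
        comp_df = pd.DataFrame([{"phase_a": a, "phase_b": b, **comp}])
        write_tsv(comp_df, outdir / "cluster_comparison.tsv", _meta(cfg))
    return per_phase


@_stage("pingpong")
def _pingpong(cfg, cand_set, phases, outdir: Path):
    sequences = {t.tag_id: t.sequence for t in cand_set.tags}
    rows = []
    hists = {}
    for phase in sorted(set(phases.values())):
        alns, counts = _phase_alignments(cand_set, phases, phase)
        hist = pingpong_mod.overlap_histogram(alns, counts, weight=cfg["pingpong"]["weight"])
        hists[phase] = hist
        frame = hist.as_frame()
        frame.insert(0, "phase", phase)
        write_tsv(frame, outdir / f"overlap_hist_{phase}.tsv", _meta(cfg, phase=phase))
        freq = pingpong_mod.partner_base_freq(hist, sequences)
        top_bin = int(np.argmax(hist.weights) + 1) if hist.weights.sum() > 0 else 0
        rows.append(
            {
                "phase": phase,
                "z10": float("nan") if hist.z10 is None else hist.z10,
                "zero_variance": hist.zero_variance,
                "top_bin": top_bin,
                "partner_T1_freq": float(freq.loc[1, "T"]) if 1 in freq.index else float("nan"),
                "partner_A10_freq": float(freq.loc[10, "A"]) if 10 in freq.index else float("nan"),
            }
        )
    write_tsv(pd.DataFrame(rows), outdir / "pingpong_summary.tsv", _meta(cfg))
    return hists, pd.DataFrame(rows)


@_stage("de")
def _diffexp(cfg, cand_set, phases, outdir: Path):
    phase_names = sorted(set(phases.values()))
    if len(phase_names) != 2:
        raise PipelineError("de", f"differential expression needs two phases, got {phase_names}", "bad_design")
    samples = sorted(phases)
    counts = pd.DataFrame(
        {s: [t.counts.get(s, 0) for t in cand_set.tags] for s in samples},
        index=pd.Index([t.tag_id for t in cand_set.tags], name="tag_id"),
    )
    tpm_table = diffexp.tpm(counts)
    write_tsv(tpm_table.reset_index(), outdir / "tpm.tsv", _meta(cfg))
    numerator, denominator = phase_names
    results = diffexp.nb_test(counts, phases, numerator=numerator, denominator=denominator)
    called = diffexp.call_de(
        results,
        p_max=cfg["de"]["p_max"],
        fc_min=cfg["de"]["fc_min"],
        count_min=cfg["de"]["count_min"],
    )
    write_tsv(
        called.reset_index(),
        outdir / "de_results.tsv",
        _meta(cfg, test="in-package NB exact-style test (median-of-ratios + pooled moment dispersion)"),
    )
    n_up_a = int((called["direction"] == f"up_in_{numerator}").sum())
    n_up_b = int((called["direction"] == f"up_in_{denominator}").sum())
    summary = pd.DataFrame(
        [
            {
                "n_tags_tested": len(called),
                "n_de": n_up_a + n_up_b,
                f"n_up_in_{numerator}": n_up_a,
                f"n_up_in_{denominator}": n_up_b,
            }
        ]
    )
    write_tsv(summary, outdir / "de_summary.tsv", _meta(cfg))
    return called, summary


def _render_report(cfg, outdir: Path, qc_reports, profile_summary, cluster_sets, pingpong_summary, de_summary):
    lines = [
        "# pirnakit run report",
        "",
        f"pirnakit version: {pirnakit.__version__}; seed: {cfg.get('seed', 0)}",
        "",
    ]
    if qc_reports:
        lines += ["## Read QC", "", "| sample | input | clean | low_qual | high_N | 5' adapter | no 3' adapter | polyX | length |", "|---|---|---|---|---|---|---|---|---|"]
        for sample, rep in sorted(qc_reports.items()):
            lines.append(
                f"| {sample} | {rep.input_reads} | {rep.clean_reads} | {rep.removed_low_quality} "
                f"| {rep.removed_high_N} | {rep.removed_5p_adapter} | {rep.removed_no_3p_adapter} "
                f"| {rep.removed_polyACGT} | {rep.removed_length} |"
            )
        lines.append("")
    lines += ["## Candidate piRNAs", ""]
    for _, row in profile_summary.iterrows():
        lines.append(
            f"- {row['phase']}: {int(row['n_candidate_tags'])} tags / {int(row['n_candidate_reads'])} reads; "
            f"first-base U fraction {row['first_base_u_tags']:.3f} (tags), {row['first_base_u_reads']:.3f} (reads)"
        )
    lines += ["", "## Pi-clusters", ""]
    for phase, found in sorted(cluster_sets.items()):
        lines.append(f"- {phase}: {len(found)} clusters")
    lines += ["", "## Ping-pong signature", ""]
    for _, row in pingpong_summary.iterrows():
        z = "n/a (zero variance)" if row["zero_variance"] else f"{row['z10']:.2f}"
        lines.append(f"- {row['phase']}: z10 = {z}, top overlap bin = {int(row['top_bin'])}")
    lines += ["", "## Differential expression", ""]
    for col in de_summary.columns:
        lines.append(f"- {col}: {int(de_summary.iloc[0][col])}")
    lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))


def run_pipeline(cfg: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run every stage; deterministic given ``cfg['seed']``.

    Raises :class:`PipelineError` naming the failing stage. Returns a
    summary dict with the headline quantities of each stage.
    """
    cfg = merge_config(cfg)
    violations = validate_config(cfg)
    if violations:
        raise PipelineError("config", "; ".join(violations), "invalid_config")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, features, repeats, ncrna, per_sample, phases, dataset, qc_reports = _prepare_inputs(cfg, outdir)
    if qc_reports:
        rows = [{"sample": s, **rep.as_dict()} for s, rep in sorted(qc_reports.items())]
        write_tsv(pd.DataFrame(rows), outdir / "qc_report.tsv", _meta(cfg))
    cand_set, merged = _call_candidates(cfg, genome, features, repeats, ncrna, per_sample, outdir)
    profile_summary = _profile(cfg, cand_set, phases, outdir)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    cluster_sets = _clusters(cfg, cand_set, phases, chrom_sizes, outdir)
    hists, pp_summary = _pingpong(cfg, cand_set, phases, outdir)
    de_results, de_summary = _diffexp(cfg, cand_set, phases, outdir)
    _render_report(cfg, outdir, qc_reports, profile_summary, cluster_sets, pp_summary, de_summary)

    return {
        "n_tags": len(merged),
        "n_candidates": len(cand_set.tags),
        "profile_summary": profile_summary,
        "clusters": {ph: len(cl) for ph, cl in cluster_sets.items()},
        "pingpong": pp_summary,
        "de_results": de_results,
        "de_summary": de_summary,
        "dataset": dataset,
        "qc_reports": qc_reports,
    }
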