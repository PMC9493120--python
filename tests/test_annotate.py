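"""Exact alignment, exclusion cascade, 1U/10A rule, origin attribution."""
import re

import numpy as np
import pytest

from pirnakit.annotate import (
    AnnotationCascade,
    align_exact,
    annotate_candidates,
    assign_region,
    assign_te_class,
    call_candidates,
    exclude_known,
    is_candidate,
    te_class_of_family,
)
from pirnakit.io import Feature, Tag, ValidationError, revcomp
from pirnakit.synth import SimConfig, simulate_dataset, simulate_genome


def _tags(*seqs):
    return [Tag(f"t{i}", s, {"s": 1}) for i, s in enumerate(seqs)]


class TestAlignExact:
    def test_plus_strand_placement(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 1000))}
        tag = Tag("t0", genome["chr1"][100:130], {"s": 1})
        alns, unplaced = align_exact([tag], genome)
        assert unplaced == []
        (a,) = alns["t0"]
        assert (a.chrom, a.start, a.end, a.strand) == ("chr1", 100, 130, "+")

    def test_minus_strand_placement(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 1000))}
        tag = Tag("t0", revcomp(genome["chr1"][200:226]), {"s": 1})
        alns, _ = align_exact([tag], genome)
        (a,) = alns["t0"]
        assert (a.start, a.end, a.strand) == (200, 226, "-")

    def test_unplaced_tags_are_tallied(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 500))}
        tags = _tags("A" * 30)
        alns, unplaced = align_exact(tags, genome)
        assert unplaced == ["t0"] and alns == {}

    def test_agrees_with_regex_scan_oracle(self, rng):
        genome = {"chrA": "".join(rng.choice(list("ACGT"), 30_000))}
        tags = []
        for i in range(30):
            s = int(rng.integers(0, 30_000 - 28))
            seq = genome["chrA"][s : s + 28]
            tags.append(Tag(f"t{i}", seq if i % 2 == 0 else revcomp(seq), {"s": 1}))
        tags.append(Tag("miss", "ACGT" * 7, {"s": 1}))
        alns, unplaced = align_exact(tags, genome)
        for tag in tags:
            expected = set()
            for strand, query in (("+", tag.sequence), ("-", revcomp(tag.sequence))):
                for m in re.finditer(f"(?={re.escape(query)})", genome["chrA"]):
                    expected.add((m.start(), m.start() + len(tag), strand))
            got = {(a.start, a.end, a.strand) for a in alns.get(tag.tag_id, [])}
            assert got == expected
            if expected:
                assert all(a.n_loci == len(expected) for a in alns[tag.tag_id])

    def test_repeat_copies_produce_multi_mapping(self):
        cfg = SimConfig(
            seed=21, n_chroms=2, chrom_length=800_000, n_clusters=4,
            cluster_span=(2000, 4000), region_mix={"repeat": 1.0}, te_mix={"LINE": 1.0},
            repeat_copies=3, pingpong_rate=0.0, background={},
        )
        ds = simulate_genome(cfg)
        primaries = ds.tag_truth.query("role == 'primary'").head(10)
        tags = [Tag(r["tag_uid"], r["sequence"], {"s": 1}) for _, r in primaries.iterrows()]
        alns, _ = align_exact(tags, ds.genome)
        for tag in tags:
            assert alns[tag.tag_id][0].n_loci == 3


class TestExclusion:
    def test_rrna_overlap_removes_with_class(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 2000))}
        tag = Tag("t0", genome["chr1"][500:526], {"s": 1})
        alns, _ = align_exact([tag], genome)
        cascade = AnnotationCascade.from_ncrna([Feature("chr1", 490, 600, "+", "rRNA")])
        kept, tally = exclude_known([tag], alns, cascade)
        assert kept == [] and tally["rRNA"] == 1

    def test_non_overlapping_survives(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 2000))}
        tag = Tag("t0", genome["chr1"][500:526], {"s": 1})
        alns, _ = align_exact([tag], genome)
        cascade = AnnotationCascade.from_ncrna([Feature("chr1", 1000, 1100, "+", "rRNA")])
        kept, tally = exclude_known([tag], alns, cascade)
        assert kept == [tag] and sum(tally.values()) == 0

    def test_final_set_is_order_insensitive(self, small_dataset):
        ds = small_dataset
        truth = ds.tag_truth.query("chrom != ''")
        tags = [Tag(r["tag_uid"], r["sequence"], {"s": 1}) for _, r in truth.iterrows()]
        alns, _ = align_exact(tags, ds.genome)
        forward = AnnotationCascade.from_ncrna(ds.ncrna)
        backward = AnnotationCascade(list(reversed(forward.steps)))
        kept_f, _ = exclude_known(tags, alns, forward)
        kept_b, _ = exclude_known(tags, alns, backward)
        assert [t.tag_id for t in kept_f] == [t.tag_id for t in kept_b]

    def test_simulated_contaminant_tallies_match_truth(self, small_dataset):
        ds = small_dataset
        truth = ds.tag_truth.query("chrom != ''")
        tags = [Tag(r["tag_uid"], r["sequence"], {"s": 1}) for _, r in truth.iterrows()]
        alns, _ = align_exact(tags, ds.genome)
        cascade = AnnotationCascade.from_ncrna(ds.ncrna)
        _, tally = exclude_known(tags, alns, cascade)
        expected = truth["role"].str.removeprefix("contaminant_").value_counts()
        for cls in ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA"):
            assert tally[cls] == int(expected.get(cls, 0)), cls


class TestCandidateRule:
    def test_first_base_u(self):
        assert is_candidate("T" + "G" * 23)

    def test_tenth_base_a(self):
        assert is_candidate("G" * 9 + "A" + "G" * 14)

    def test_neither_rejected(self):
        assert not is_candidate("G" * 9 + "C" + "G" * 14)

    def test_short_tag_is_defensive_error(self):
        with pytest.raises(ValidationError, match="length selection"):
            call_candidates(_tags("ACGTACG"))


class TestOrigins:
    def test_priority_cds_beats_repeat(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 2000))}
        tag = Tag("t0", genome["chr1"][500:526], {"s": 1})
        alns, _ = align_exact([tag], genome)
        feats = [
            Feature("chr1", 400, 700, "+", "repeat", "LINE/L1"),
            Feature("chr1", 510, 520, "+", "CDS"),
        ]
        per_tag, props = assign_region(alns, feats)
        assert per_tag["t0"] == "CDS"
        assert props.sum() == pytest.approx(1.0)

    def test_no_feature_is_intergenic(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 1000))}
        tag = Tag("t0", genome["chr1"][100:126], {"s": 1})
        alns, _ = align_exact([tag], genome)
        per_tag, _ = assign_region(alns, [])
        assert per_tag["t0"] == "intergenic"

    def test_te_family_mapping(self):
        assert te_class_of_family("LINE/L1") == "LINE"
        assert te_class_of_family("DNA/hAT") == "DNA"
        assert te_class_of_family("Satellite") == "other"

    def test_region_mix_recovery_within_3se(self):
        cfg = SimConfig(
            seed=31, n_chroms=3, chrom_length=800_000, n_clusters=60,
            region_mix={"intron": 0.5, "CDS": 0.3, "repeat": 0.2},
            pingpong_rate=0.0, background={},
        )
        ds = simulate_genome(cfg)
        truth = ds.tag_truth.query("role == 'primary'")
        tags = [Tag(r["tag_uid"], r["sequence"], {"s": 1}) for _, r in truth.iterrows()]
        alns, _ = align_exact(tags, ds.genome)
        feats = ds.features
        _, props = assign_region(alns, feats)
        n = cfg.n_clusters  # the cluster is the independent sampling unit
        for cls, p in cfg.region_mix.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(props[cls] - p) <= 3 * se, (cls, props[cls], p)

    def test_te_mix_modal_class_is_line(self):
        cfg = SimConfig(
            seed=32, n_chroms=2, chrom_length=600_000, n_clusters=24,
            region_mix={"repeat": 1.0},
            te_mix={"LINE": 0.6, "SINE": 0.1, "LTR": 0.1, "DNA": 0.1, "other": 0.1},
            pingpong_rate=0.0, background={},
        )
        ds = simulate_genome(cfg)
        truth = ds.tag_truth.query("role == 'primary'")
        tags = [Tag(r["tag_uid"], r["sequence"], {"s": 1}) for _, r in truth.iterrows()]
        alns, _ = align_exact(tags, ds.genome)
        _, table = assign_te_class(alns, ds.repeats)
        modal = table.loc[table["mass"].idxmax(), "te_class"]
        assert modal == "LINE"
        class_i = table.loc[table["te_group"] == "Class I", "mass"].sum()
        assert class_i > table["mass"].sum() / 2

    def test_region_mass_conserves_tags(self, small_dataset):
        ds = small_dataset
        truth = ds.tag_truth.query("role == 'primary'")
        tags = [Tag(r["tag_uid"], r["sequence"], {"s": 1}) for _, r in truth.iterrows()]
        alns, _ = align_exact(tags, ds.genome)
        index_classes, props = assign_region(alns, ds.features)
        assert props.sum() == pytest.approx(1.0)


def test_annotate_candidates_end_to_end(small_dataset):
    ds = small_dataset
    truth = ds.tag_truth
    tags = [
        Tag(r["tag_uid"], r["sequence"], {"s": 1})
        for _, r in truth.iterrows()
        if 24 <= r["length"] <= 33
    ]
    cand, tally, unplaced = annotate_candidates(tags, ds.genome, ds.features, ds.repeats, ds.ncrna)
    cluster_tags = set(truth.loc[truth["cluster_id"] != "", "tag_uid"])
    assert {t.tag_id for t in cand.tags} == {t for t in cluster_tags}
    assert set(unplaced) == set(truth.loc[truth["role"] == "nongenomic", "tag_uid"])
    table = cand.table()
    assert ((table["first_base"] == "T") | (table["base10"] == "A")).all()
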