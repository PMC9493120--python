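"""Pi-cluster scanning vs a brute-force oracle, plus density/comparison."""
import numpy as np
import pytest

from pirnakit.clusters import (
    ClusterParams,
    cluster_density_by_chrom,
    compare_cluster_sets,
    scan_clusters,
)
from pirnakit.io import Alignment, PiCluster, ValidationError


def brute_force_clusters(alignments, params):
    """Independent reference: enumerate every window on the chromosome,
    mark occupied ones, merge regions to a fixed point, then threshold."""
    out = []
    for chrom in sorted({a.chrom for a in alignments}):
        alns = [a for a in alignments if a.chrom == chrom]
        w = params.window
        marked = sorted({a.five_prime // w for a in alns})
        regions = [[m] for m in marked]
        changed = True
        while changed:
            changed = False
            for i in range(len(regions) - 1):
                if (regions[i + 1][0] - regions[i][-1]) * w <= params.max_gap:
                    regions[i] = regions[i] + regions[i + 1]
                    del regions[i + 1]
                    changed = True
                    break
        for reg in regions:
            lo, hi = reg[0] * w, (reg[-1] + 1) * w
            members = [a for a in alns if lo <= a.five_prime < hi]
            if len({a.tag_id for a in members}) >= params.min_distinct:
                out.append(
                    (chrom, min(a.start for a in members), max(a.end for a in members),
                     len({a.tag_id for a in members}))
                )
    return sorted(out)


def _aln(tid, start, strand="+", chrom="chr1", length=26):
    return Alignment(tid, chrom, start, start + length, strand)


def _sorted(alns):
    return sorted(alns, key=lambda a: (a.chrom, a.start))


class TestScan:
    def test_twelve_tags_in_one_window_is_one_cluster(self):
        alns = _sorted(_aln(f"t{i}", 100 + i * 200) for i in range(12))
        (c,) = scan_clusters(alns, ClusterParams())
        assert c.n_distinct_tags == 12
        assert c.start == 100 and c.end == 100 + 11 * 200 + 26

    def test_nine_tags_is_below_threshold(self):
        alns = _sorted(_aln(f"t{i}", 100 + i * 200) for i in range(9))
        assert scan_clusters(alns, ClusterParams()) == []

    def test_gap_under_20kb_merges_over_25kb_splits(self):
        near = _sorted(
            [_aln(f"a{i}", i * 150) for i in range(6)]
            + [_aln(f"b{i}", 18_000 + i * 150) for i in range(6)]
        )
        (c,) = scan_clusters(near, ClusterParams())
        assert c.n_distinct_tags == 12

        far = _sorted(
            [_aln(f"a{i}", i * 150) for i in range(6)]
            + [_aln(f"b{i}", 25_000 + i * 150) for i in range(6)]
        )
        assert scan_clusters(far, ClusterParams()) == []

    def test_gap_exactly_20kb_still_chains(self):
        alns = _sorted(
            [_aln(f"a{i}", i * 150) for i in range(6)]
            + [_aln(f"b{i}", 20_000 + i * 150) for i in range(6)]
        )
        (c,) = scan_clusters(alns, ClusterParams())
        assert c.n_distinct_tags == 12

    def test_unsorted_input_raises(self):
        alns = [_aln("a", 5000), _aln("b", 100)]
        with pytest.raises(ValidationError, match="sorted"):
            scan_clusters(alns, ClusterParams())

    def test_strand_counts_and_totals(self):
        alns = _sorted(
            [_aln(f"p{i}", 100 + i * 50, "+") for i in range(6)]
            + [_aln(f"m{i}", 120 + i * 50, "-") for i in range(6)]
        )
        counts = {a.tag_id: 3 for a in alns}
        (c,) = scan_clusters(alns, ClusterParams(), counts)
        assert (c.plus_count, c.minus_count, c.total_count) == (18, 18, 36)

    def test_require_both_strands(self):
        alns = _sorted(_aln(f"t{i}", 100 + i * 50, "+") for i in range(12))
        assert scan_clusters(alns, ClusterParams(), require_both_strands=True) == []

    def test_matches_bruteforce_on_random_instances(self, rng):
        params = ClusterParams()
        for _ in range(60):
            n = int(rng.integers(5, 120))
            alns = _sorted(
                _aln(
                    f"t{rng.integers(0, max(2, n // 2))}",
                    int(rng.integers(0, 100_000 - 33)),
                    "+" if rng.random() < 0.5 else "-",
                    length=int(rng.integers(24, 34)),
                )
                for _ in range(n)
            )
            got = sorted((c.chrom, c.start, c.end, c.n_distinct_tags) for c in scan_clusters(alns, params))
            assert got == brute_force_clusters(alns, params)

    def test_order_invariance_after_sorting(self, rng):
        alns = [_aln(f"t{i}", int(rng.integers(0, 50_000)), "+") for i in range(40)]
        a = scan_clusters(_sorted(alns), ClusterParams(min_distinct=5))
        perm = [alns[i] for i in rng.permutation(len(alns))]
        b = scan_clusters(_sorted(perm), ClusterParams(min_distinct=5))
        assert a == b

    def test_emitted_clusters_respect_spacing_invariant(self, rng):
        params = ClusterParams(min_distinct=3)
        for _ in range(20):
            alns = _sorted(
                _aln(f"t{i}", int(rng.integers(0, 200_000)), "+") for i in range(80)
            )
            found = scan_clusters(alns, params)
            assert all(c.n_distinct_tags >= 3 for c in found)
            for c1, c2 in zip(found, found[1:]):
                if c1.chrom == c2.chrom:
                    assert c2.start - c1.start > params.max_gap


def test_params_validation():
    with pytest.raises(ValidationError):
        ClusterParams(min_distinct=0)
    with pytest.raises(ValidationError):
        ClusterParams(window=5000, max_gap=4000)


class TestDensityAndComparison:
    def test_density_counts_and_zero_chroms(self):
        cl = [PiCluster("chr1", 0, 1000, 10, 10, 10, 0)]
        df = cluster_density_by_chrom(cl, {"chr1": 1_000_000, "chr2": 2_000_000}).set_index("chrom")
        assert df.loc["chr1", "n_clusters"] == 1 and df.loc["chr2", "n_clusters"] == 0
        assert df.loc["chr1", "clusters_per_mb"] == pytest.approx(1.0)

    def test_empty_cluster_list(self):
        df = cluster_density_by_chrom([], {"chr1": 1_000_000})
        assert (df["n_clusters"] == 0).all()

    def test_identical_sets_all_shared(self):
        cl = [PiCluster("chr1", 0, 1000, 10, 10, 10, 0), PiCluster("chr2", 50, 900, 12, 12, 6, 6)]
        comp = compare_cluster_sets(cl, list(cl))
        assert comp["shared_a"] == comp["shared_b"] == 2
        assert comp["a_specific"] == comp["b_specific"] == 0

    def test_disjoint_sets_none_shared(self):
        a = [PiCluster("chr1", 0, 1000, 10, 10, 10, 0)]
        b = [PiCluster("chr1", 5000, 6000, 10, 10, 10, 0)]
        comp = compare_cluster_sets(a, b)
        assert comp["shared_a"] == 0 and comp["a_specific"] == 1 and comp["b_specific"] == 1

    def test_planted_per_chromosome_counts_recovered(self):
        from pirnakit.annotate import align_exact
        from pirnakit.io import Tag
        from pirnakit.synth import SimConfig, simulate_genome

        cfg = SimConfig(
            seed=41, n_chroms=2, chrom_length=700_000, n_clusters=18,
            cluster_chrom_weights=(2.0, 1.0), pingpong_rate=0.0, background={},
        )
        ds = simulate_genome(cfg)
        truth = ds.tag_truth.query("role == 'primary'")
        tags = [Tag(r["tag_uid"], r["sequence"], {"s": 1}) for _, r in truth.iterrows()]
        alns_by_tag, _ = align_exact(tags, ds.genome)
        alns = _sorted(a for alns in alns_by_tag.values() for a in alns)
        found = scan_clusters(alns, ClusterParams())
        planted = ds.cluster_truth["chrom"].value_counts().to_dict()
        recovered = cluster_density_by_chrom(found, ds.chrom_sizes).set_index("chrom")["n_clusters"]
        for chrom, n in planted.items():
            assert recovered[chrom] == n
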