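import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadlink.core import (
    CoordinateError,
    GeneModel,
    GenomicInterval,
    StepTrack,
    UndefinedDistanceError,
    assign_to_tads,
    build_tad_partition,
    classify_distance,
    gene_site_distance,
    merge_intervals,
)


def _gene(exons, chrom="chr1", strand="+", biotype="protein_coding"):
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    return GeneModel("g1", "G1", biotype, chrom, strand, ivs)


class TestTadPartition:
    def test_merge_and_complement(self):
        domains = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 150, 300)]
        part = build_tad_partition(domains, {"chr1": 1000})
        spans = [(iv.start, iv.end) for iv in part.intervals]
        assert spans == [(0, 100), (100, 300), (300, 1000)]
        assert part.n_tads == 3
        assert part.origins == ["complement", "called-domain", "complement"]

    def test_empty_domains_single_tad(self):
        part = build_tad_partition([], {"chr1": 5000})
        assert part.n_tads == 1
        assert (part.intervals[0].start, part.intervals[0].end) == (0, 5000)

    def test_bookended_domains_merge(self):
        domains = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 400)]
        part = build_tad_partition(domains, {"chr1": 400})
        assert part.n_tads == 1

    def test_out_of_bounds_domain_raises(self):
        with pytest.raises(CoordinateError, match="chr1:0-2000"):
            build_tad_partition([GenomicInterval("chr1", 0, 2000)], {"chr1": 1000})
        with pytest.raises(CoordinateError, match="undeclared"):
            build_tad_partition([GenomicInterval("chrX", 0, 10)], {"chr1": 1000})

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 9_000), st.integers(1, 1_000)),
            min_size=0,
            max_size=20,
        )
    )
    def test_partition_conservation_and_disjointness(self, raw):
        domains = [
            GenomicInterval("chr1", s, min(s + l, 10_000)) for s, l in raw
        ]
        part = build_tad_partition(domains, {"chr1": 10_000})
        total = sum(len(iv) for iv in part.intervals)
        assert total == 10_000
        edges = sorted((iv.start, iv.end) for iv in part.intervals)
        for (s1, e1), (s2, e2) in zip(edges, edges[1:]):
            assert e1 == s2  # disjoint and exhaustive

    def test_idempotence_on_called_domains(self):
        domains = [
            GenomicInterval("chr1", 10, 500),
            GenomicInterval("chr1", 400, 900),
            GenomicInterval("chr1", 2000, 3000),
        ]
        part1 = build_tad_partition(domains, {"chr1": 5000})
        called = [
            iv for iv, o in zip(part1.intervals, part1.origins) if o == "called-domain"
        ]
        part2 = build_tad_partition(called, {"chr1": 5000})
        called2 = [
            iv for iv, o in zip(part2.intervals, part2.origins) if o == "called-domain"
        ]
        assert called == called2


class TestAssignToTads:
    @pytest.fixture()
    def part(self):
        return build_tad_partition(
            [GenomicInterval("chr1", 0, 300), GenomicInterval("chr1", 350, 600)],
            {"chr1": 1000},
        )

    def test_boundary_spanning_feature_maps_to_both(self, part):
        res = assign_to_tads({"f": GenomicInterval("chr1", 250, 350)}, part)
        assert len(res["f"]) == 2

    def test_single_bp_site_maps_to_one(self, part):
        res = assign_to_tads({"s": GenomicInterval("chr1", 100, 101)}, part)
        assert len(res["s"]) == 1

    def test_every_in_bounds_feature_covered(self, part):
        rng = np.random.default_rng(0)
        feats = {
            f"f{i}": GenomicInterval("chr1", int(s), int(s) + int(l))
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 900, 50), rng.integers(1, 100, 50))
            )
        }
        res = assign_to_tads(feats, part)
        assert all(len(v) >= 1 for v in res.values())

    def test_undeclared_chromosome_raises(self, part):
        with pytest.raises(CoordinateError):
            assign_to_tads({"f": GenomicInterval("chrZ", 0, 10)}, part)


class TestGeneSiteDistance:
    def test_site_in_intron_is_zero(self):
        g = _gene([(1000, 1200), (2000, 2200)])
        assert gene_site_distance(g, "chr1", 1500) == 0

    def test_upstream_edge_arithmetic(self):
        g = _gene([(10_000, 12_000)])
        assert gene_site_distance(g, "chr1", 8_000) == 2_000

    def test_downstream_long_range(self):
        g = _gene([(10_000, 15_000), (19_000, 20_000)])
        assert gene_site_distance(g, "chr1", 520_000) == 500_000

    def test_different_chromosome_raises(self):
        g = _gene([(0, 100)])
        with pytest.raises(UndefinedDistanceError):
            gene_site_distance(g, "chr2", 50)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 9_999), st.integers(100, 5_000), st.integers(10, 2_000))
    def test_matches_interval_distance_oracle(self, pos, start, length):
        g = _gene([(start, start + length)])
        oracle = max(start - pos, pos - (start + length), 0)
        assert gene_site_distance(g, "chr1", pos) == oracle


class TestClassifyDistance:
    @pytest.mark.parametrize(
        "d,within,expected",
        [
            (0, True, "proximal"),
            (2_000, False, "proximal"),
            (2_001, False, "intermediate"),
            (500_000, False, "intermediate"),
            (500_001, False, "long"),
            (0, False, "proximal"),
        ],
    )
    def test_bin_boundaries(self, d, within, expected):
        assert classify_distance(d, within) == expected

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError):
            classify_distance(-1)


class TestGeneModel:
    def test_introns_are_gaps_between_merged_exons(self):
        g = _gene([(0, 100), (200, 300), (50, 120)])
        assert [(i.start, i.end) for i in g.introns] == [(120, 200)]
        assert g.body.start == 0 and g.body.end == 300
        assert g.exonic_length + g.intronic_length == len(g.body)

    def test_intronless_gene(self):
        g = _gene([(10, 400)])
        assert g.introns == ()

    def test_exons_on_multiple_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            GeneModel(
                "g", "G", "protein_coding", "chr1", "+",
                (GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10)),
            )

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)


class TestStepTrack:
    @pytest.fixture()
    def track(self):
        return StepTrack(
            {"chr1": (np.array([0, 100, 300]), np.array([100, 200, 400]),
                      np.array([1.0, 2.0, 4.0]))}
        )

    def test_values_at_positions(self, track):
        vals = track.values_at("chr1", np.array([50, 150, 250, 350]))
        assert vals[0] == 1.0 and vals[1] == 2.0 and np.isnan(vals[2]) and vals[3] == 4.0

    def test_weighted_mean_and_median(self, track):
        ivs = [GenomicInterval("chr1", 0, 200)]
        assert track.mean_over(ivs) == pytest.approx(1.5)
        # 100 bases of value 1, 100 of 2, 100 of 4 -> per-base median 2
        ivs = [GenomicInterval("chr1", 0, 400)]
        assert track.median_over(ivs) == pytest.approx(2.0)

    def test_uncovered_region_is_nan(self, track):
        assert np.isnan(track.mean_over([GenomicInterval("chr1", 200, 300)]))

    def test_coverage_fraction(self, track):
        assert track.coverage_fraction([GenomicInterval("chr1", 0, 400)]) == pytest.approx(0.75)


def test_merge_intervals_bookended_and_nested():
    merged = merge_intervals(
        [
            GenomicInterval("chr1", 0, 10),
            GenomicInterval("chr1", 10, 20),
            GenomicInterval("chr1", 12, 15),
            GenomicInterval("chr2", 5, 8),
        ]
    )
    assert [(m.chrom, m.start, m.end) for m in merged] == [
        ("chr1", 0, 20),
        ("chr2", 5, 8),
    ]
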