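import numpy as np
import pandas as pd
import pytest

from tadlink.architecture import (
    bbox_scan,
    boundary_distance_test,
    compute_architecture,
    contains_element_enrichment,
    ecdf_shift_test,
    mir_zero_matched_test,
    site_architecture_tests,
)
from tadlink.core import (
    GeneModel,
    GenomicInterval,
    RepeatElement,
    StepTrack,
    build_tad_partition,
)
from tadlink.errors import InsufficientDataError


def _gene(exons, gene_id="g1", chrom="chr1"):
    ivs = tuple(GenomicInterval(chrom, s, e, "+") for s, e in exons)
    return GeneModel(gene_id, gene_id, "protein_coding", chrom, "+", ivs)


class TestComputeArchitecture:
    def test_intron_fully_covered_by_mir_has_density_one(self):
        g = _gene([(0, 100), (200, 300)])
        mir = RepeatElement("m1", "MIR", "MIRb", GenomicInterval("chr1", 100, 200), 30)
        arch = compute_architecture([g], [mir])
        assert arch.loc["g1", "MIR_density_intron"] == pytest.approx(1.0)
        assert arch.loc["g1", "MIR_density_exon"] == 0.0
        assert arch.loc["g1", "contains_MIR"]

    def test_single_exon_gene_has_undefined_intronic_fields(self):
        arch = compute_architecture([_gene([(0, 500)])], [])
        assert np.isnan(arch.loc["g1", "intronic_length"])
        assert np.isnan(arch.loc["g1", "MIR_density_intron"])

    def test_gc_from_track(self):
        g = _gene([(0, 100), (200, 300)])
        gc = StepTrack(
            {"chr1": (np.array([0, 100, 200]), np.array([100, 200, 300]),
                      np.array([0.5, 0.8, 0.3]))}
        )
        arch = compute_architecture([g], [], gc=gc)
        assert arch.loc["g1", "gc_exon"] == pytest.approx(0.4)  # (0.5+0.3)/2
        assert arch.loc["g1", "gc_intron"] == pytest.approx(0.8)

    def test_density_sums_bounded_for_nonoverlapping_families(self, genome):
        arch = compute_architecture(genome.genes, genome.repeats)
        total = arch[["MIR_density_intron", "Alu_density_intron", "L1_density_intron"]].sum(axis=1)
        assert (total.dropna() <= 1.0 + 1e-9).all()


class TestEcdfShift:
    def test_identical_distributions_give_zero(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=400)
        curve, D, p, warn = ecdf_shift_test(b, b)
        assert D == pytest.approx(0.0)
        assert np.allclose(curve.curve, 0.0)

    def test_upward_shift_positive_curve(self):
        rng = np.random.default_rng(1)
        b = rng.normal(size=500)
        s = rng.choice(b, 100) + 1.0
        curve, D, p, _ = ecdf_shift_test(s, b)
        interior = curve.curve[10:-10]
        assert interior.max() > 0
        assert p < 1e-4

    def test_set_at_background_maximum(self):
        b = np.arange(1, 11, dtype=float)  # N = 10 distinct values
        s = np.array([10.0])
        curve, D, p, warn = ecdf_shift_test(s, b)
        assert D == pytest.approx(9 / 10)
        assert (curve.curve >= -1e-12).all()
        assert warn  # set smaller than 5

    def test_max_abs_curve_equals_ks_d(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            b = rng.normal(size=300)
            s = rng.normal(0.3, 1.2, size=60)
            curve, D, _, _ = ecdf_shift_test(s, b)
            assert curve.max_abs == pytest.approx(D)

    def test_curve_vanishes_at_extremes(self):
        rng = np.random.default_rng(3)
        b = rng.normal(size=200)
        s = rng.normal(size=50)
        curve, *_ = ecdf_shift_test(s, b)
        assert curve.curve[-1] == pytest.approx(0.0)


class TestContainsEnrichment:
    def test_closed_form(self):
        arch = pd.DataFrame(
            {"contains_MIR": [True] * 5 + [False] * 5},
            index=[f"g{i}" for i in range(10)],
        )
        gene_set = [f"g{i}" for i in range(5)]
        fold, p = contains_element_enrichment(gene_set, list(arch.index), arch, "MIR")
        assert p == pytest.approx(1 / 252)

    def test_set_equals_background_fold_one(self):
        arch = pd.DataFrame(
            {"contains_Alu": [True, False, True, True]},
            index=[f"g{i}" for i in range(4)],
        )
        fold, p = contains_element_enrichment(
            list(arch.index), list(arch.index), arch, "Alu"
        )
        assert fold == pytest.approx(1.0)

    def test_absent_family_flagged(self):
        arch = pd.DataFrame({"contains_L1": [False, False]}, index=["a", "b"])
        fold, p = contains_element_enrichment(["a"], ["a", "b"], arch, "L1")
        assert np.isnan(fold) and p == 1.0


def brute_force_bbox(seq: str) -> int:
    """Sliding-window oracle for the B-box motif in both orientations."""
    def match(win, pat):
        return all(p == "N" or (c == p) for c, p in zip(win, pat))

    n = 0
    for i in range(len(seq) - 8):
        win = seq[i : i + 9]
        n += match(win, "GTTCNANNC") + match(win, "GNNTNGAAC")
    return n


class TestBboxScan:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GTTCAATTC", 1),
            ("GAATTGAAC", 1),
            ("AAAAAAAAA", 0),
            ("GTTXAATTC", 0),  # non-ACGT at a fixed position fails
            ("GTTCXAXXC", 1),  # non-ACGT at N positions matches
        ],
    )
    def test_motif_examples(self, seq, expected):
        el = RepeatElement("m", "MIR", "MIRb", GenomicInterval("chr1", 0, len(seq)))
        assert bbox_scan([el], {"m": seq})["m"] == expected

    def test_overlapping_matches_counted(self):
        seq = "GTTCAATTCGTTCAATTC"
        el = RepeatElement("m", "MIR", "MIRb", GenomicInterval("chr1", 0, len(seq)))
        assert bbox_scan([el], {"m": seq})["m"] == 2

    def test_matches_sliding_window_oracle_on_genome_mirs(self, genome):
        mirs = [r for r in genome.repeats if r.family == "MIR"][:200]
        counts = bbox_scan(mirs, genome.repeat_sequences)
        for r in mirs[:50]:
            assert counts[r.element_id] == brute_force_bbox(
                genome.repeat_sequences[r.element_id]
            )

    def test_planted_bbox_fraction_detected(self, genome):
        mirs = [r for r in genome.repeats if r.family == "MIR"]
        counts = bbox_scan(mirs, genome.repeat_sequences)
        frac_with_box = (counts > 0).mean()
        assert 0.15 <= frac_with_box <= 0.45  # configured 30% carry a B-box


class TestBoundaryDistance:
    @pytest.fixture()
    def part(self):
        return build_tad_partition(
            [GenomicInterval("chr1", 0, 5_000), GenomicInterval("chr1", 6_000, 10_000)],
            {"chr1": 10_000},
        )

    def _els(self, spans):
        return [
            RepeatElement(f"e{i}", "MIR", "MIRb", GenomicInterval("chr1", s, e))
            for i, (s, e) in enumerate(spans)
        ]

    def test_straddling_element_distance_zero(self, part):
        els = self._els([(4_990, 5_010)])
        res = boundary_distance_test(els, part, els)
        assert res["median_set"] == 0.0

    def test_identical_sets_d_zero(self, part):
        els = self._els([(100, 200), (2_000, 2_100), (7_000, 7_050)])
        res = boundary_distance_test(els, part, els)
        assert res["D"] == pytest.approx(0.0)

    def test_center_planted_elements_further_than_uniform(self, part):
        rng = np.random.default_rng(0)
        centers = self._els([(2_400, 2_500), (2_500, 2_600), (7_900, 8_000)] * 10)
        starts = rng.integers(0, 9_900, size=60)
        uniform = self._els([(int(s), int(s) + 50) for s in starts])
        res = boundary_distance_test(centers, part, uniform)
        assert res["median_set"] > res["median_background"]
        assert res["p"] < 0.05


class TestSiteArchitecture:
    def test_sig_equals_all_gives_unit_folds(self, genome):
        sites = genome.cpg_sites[["chrom", "pos"]]
        rep = site_architecture_tests(
            sites, sites, genome.repeats,
            conservation=genome.conservation, enhancers=genome.enhancers,
        )
        assert rep["conservation"]["D"] == pytest.approx(0.0)
        assert rep["MIR"]["fold"] == pytest.approx(1.0)
        assert rep["enhancer"]["fold"] == pytest.approx(1.0)

    def test_empty_significant_set_gives_empty_report(self, genome):
        sites = genome.cpg_sites[["chrom", "pos"]]
        assert site_architecture_tests(sites.iloc[:0], sites, genome.repeats) == {}

    def test_driver_sites_enriched_on_mirs_and_enhancers(self, genome, discovery):
        _, meth, table, truth = discovery
        sig_sites = table.loc[table["significant"], "site_id"].unique()
        all_sites = table["site_id"].unique()
        rep = site_architecture_tests(
            meth.sites.loc[sig_sites], meth.sites.loc[all_sites], genome.repeats,
            conservation=genome.conservation, enhancers=genome.enhancers,
        )
        assert rep["MIR"]["fold"] > 1 and rep["MIR"]["p"] < 1e-4
        assert rep["enhancer"]["fold"] > 1 and rep["enhancer"]["p"] < 1e-4


class TestMirZeroMatched:
    def test_no_mir_zero_genes_raises(self):
        arch = pd.DataFrame(
            {
                "MIR_density_intron": np.linspace(0.01, 0.3, 30),
                "cpg_density": np.linspace(0.5, 2.0, 30),
            },
            index=[f"g{i}" for i in range(30)],
        )
        table = pd.DataFrame(
            {"gene_id": arch.index, "rho": 0.5}
        )
        with pytest.raises(InsufficientDataError):
            mir_zero_matched_test(table, arch)

    def test_planted_mir_effect_detected(self):
        # larger genome with uniform CpG placement so CpG-density matching
        # has comparable pools; planting still prefers MIR-dense genes
        from tadlink.correlation import correlate_within_tads, filter_features
        from tadlink.simulate import GenomeConfig, generate_cohort, generate_genome

        cfg = GenomeConfig(
            chrom_sizes={"chr1": 16_000_000, "chr2": 16_000_000},
            n_genes=500, cpg_on_mir_fraction=0.0, cpg_on_enhancer_fraction=0.0,
        )
        g = generate_genome(cfg, seed=11)
        cohort, _ = generate_cohort(g, seed=11)
        expr, meth = filter_features(cohort.expression, cohort.methylation)
        table = correlate_within_tads(expr, meth, g.partition, g.genes)
        arch = compute_architecture(g.genes, g.repeats, cpg_positions=g.cpg_sites)
        res = mir_zero_matched_test(table, arch, caliper_sd=1.0, min_pairs=10)
        # planted effects live in MIR-dense (regulatable) genes
        assert res["median_mir_dense"] > res["median_mir_zero"]
        assert res["p"] < 1e-2
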