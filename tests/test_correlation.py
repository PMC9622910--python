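import numpy as np
import pandas as pd
import pytest

from tadlink.core import GenomicInterval, build_tad_partition
from tadlink.correlation import (
    FilterParams,
    compare_cohort_coefficients,
    correlate_within_tads,
    filter_features,
    island_mean_methylation,
    max_abs_rho_ranking,
    proximal_enrichment_test,
    shared_site_gene_pairs,
    weakest_gene_set,
)
from tadlink.errors import InsufficientDataError
from tadlink.tables import ExpressionMatrix, MethylationTable


def _simple_meth(frac, coverage=None, positions=None, samples=None):
    n, k = frac.shape
    samples = samples or [f"s{i}" for i in range(k)]
    idx = [f"site{i}" for i in range(n)]
    positions = positions if positions is not None else np.arange(n) * 100 + 10
    sites = pd.DataFrame({"chrom": "chr1", "pos": positions}, index=idx)
    cov = (
        pd.DataFrame(coverage, index=idx, columns=samples)
        if coverage is not None
        else None
    )
    return MethylationTable(sites, pd.DataFrame(frac, index=idx, columns=samples), cov)


class TestFilterFeatures:
    def test_site_with_single_low_coverage_sample_dropped(self):
        frac = np.full((2, 4), 0.5)
        cov = np.full((2, 4), 30)
        cov[0, 2] = 9
        meth = _simple_meth(frac, cov)
        expr = ExpressionMatrix(
            pd.DataFrame(np.ones((2, 4)), index=["g1", "g2"],
                         columns=["s0", "s1", "s2", "s3"])
        )
        _, meth_f = filter_features(expr, meth)
        assert list(meth_f.fractions.index) == ["site1"]

    def test_probe_mode_rarely_methylated_probe_dropped(self):
        frac = np.zeros((2, 100))
        frac[0, :] = 0.2  # never exceeds 0.3 -> dropped
        frac[1, :10] = 0.9  # >0.3 in 10% of samples -> kept
        meth = _simple_meth(frac, samples=[f"s{i}" for i in range(100)])
        expr = ExpressionMatrix(
            pd.DataFrame(np.ones((1, 100)), index=["g1"],
                         columns=[f"s{i}" for i in range(100)])
        )
        _, meth_f = filter_features(expr, meth)
        assert list(meth_f.fractions.index) == ["site1"]

    def test_top_half_of_genes_kept(self):
        values = pd.DataFrame(
            {"s0": np.arange(100.0), "s1": np.arange(100.0)},
            index=[f"g{i}" for i in range(100)],
        )
        expr = ExpressionMatrix(values)
        frac = np.full((1, 2), 0.5)
        meth = _simple_meth(frac, np.full((1, 2), 30), samples=["s0", "s1"])
        expr_f, _ = filter_features(expr, meth)
        assert len(expr_f.genes) == 50
        assert "g99" in expr_f.genes and "g0" not in expr_f.genes


def _tiny_discovery(n=12, rho_sign=-1):
    """One TAD, one gene, one site with a perfectly monotone relationship."""
    from tadlink.core import GeneModel

    part = build_tad_partition([GenomicInterval("chr1", 0, 10_000)], {"chr1": 10_000})
    gene = GeneModel(
        "g1", "G1", "protein_coding", "chr1", "+",
        (GenomicInterval("chr1", 1000, 2000, "+"),),
    )
    m = np.linspace(0.1, 0.9, n)
    x = (10 - rho_sign * -1 * m * 5) if rho_sign > 0 else (10 - m * 5)
    expr = ExpressionMatrix(
        pd.DataFrame([x if rho_sign < 0 else m * 5 + 1],
                     index=["g1"], columns=[f"s{i}" for i in range(n)])
    )
    meth = _simple_meth(m[None, :], np.full((1, n), 30), positions=[1500],
                        samples=[f"s{i}" for i in range(n)])
    return expr, meth, part, [gene]


class TestCorrelateWithinTads:
    def test_monotone_increasing_gives_rho_one(self):
        expr, meth, part, genes = _tiny_discovery(rho_sign=+1)
        table = correlate_within_tads(expr, meth, part, genes)
        assert table.loc[0, "rho"] == pytest.approx(1.0)

    def test_monotone_decreasing_gives_rho_minus_one(self):
        expr, meth, part, genes = _tiny_discovery(rho_sign=-1)
        table = correlate_within_tads(expr, meth, part, genes)
        assert table.loc[0, "rho"] == pytest.approx(-1.0)

    def test_insufficient_shared_samples_rejected(self):
        expr, meth, part, genes = _tiny_discovery(n=12)
        expr2 = expr.subset_samples(["s0", "s1"])
        with pytest.raises(InsufficientDataError):
            correlate_within_tads(expr2, meth, part, genes)

    def test_zero_variance_vectors_skipped_and_counted(self):
        expr, meth, part, genes = _tiny_discovery()
        const = meth.fractions.copy()
        const.iloc[0] = 0.5
        meth2 = MethylationTable(meth.sites, const, meth.coverage)
        with pytest.raises(Exception):
            # the only pair is skipped -> empty result
            correlate_within_tads(expr, meth2, part, genes)

    def test_matches_scipy_spearman_per_pair(self, discovery):
        from scipy import stats as sps

        expr, meth, table, _ = discovery
        sample = table.sample(50, random_state=0)
        for row in sample.itertuples():
            r, p = sps.spearmanr(
                expr.values.loc[row.gene_id], meth.fractions.loc[row.site_id]
            )
            assert row.rho == pytest.approx(r, abs=1e-12)
            assert row.p == pytest.approx(p, rel=1e-6)

    def test_pairs_unique_and_bins_partition_significant(self, discovery):
        _, _, table, _ = discovery
        assert not table.duplicated(subset=["gene_id", "site_id"]).any()
        sig = table[table["significant"]]
        counts = sig["bin"].value_counts()
        assert counts.sum() == len(sig)
        assert set(counts.index) <= {"proximal", "intermediate", "long"}

    def test_significance_flag_matches_thresholds(self, discovery):
        _, _, table, _ = discovery
        expected = (table["rho"].abs() > 0.5) & (table["q"] < 0.05)
        assert (table["significant"] == expected).all()


class TestIslandMean:
    def test_island_mean_of_member_sites(self):
        frac = np.array([[0.2, 0.2], [0.4, 0.4], [0.9, 0.9]])
        meth = _simple_meth(frac, np.full((3, 2), 30), positions=[100, 150, 5000],
                            samples=["s0", "s1"])
        islands = [GenomicInterval("chr1", 0, 200), GenomicInterval("chr1", 9000, 9500)]
        out = island_mean_methylation(meth, islands)
        assert len(out.fractions) == 1  # second island has no sites -> dropped
        assert out.fractions.iloc[0, 0] == pytest.approx(0.3)

    def test_single_site_island_identity(self):
        frac = np.array([[0.7, 0.1]])
        meth = _simple_meth(frac, np.full((1, 2), 30), positions=[100],
                            samples=["s0", "s1"])
        out = island_mean_methylation(meth, [GenomicInterval("chr1", 50, 150)])
        assert out.fractions.iloc[0].tolist() == pytest.approx([0.7, 0.1])


class TestWeakestGeneSet:
    def _table(self):
        return pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d", "e"],
                "site_id": [f"s{i}" for i in range(5)],
                "rho": [0.1, -0.2, 0.3, -0.4, 0.5],
                "bin": ["proximal"] * 5,
            }
        )

    def test_lowest_scores_selected_in_order(self):
        genes, short = weakest_gene_set(self._table(), n=2, bin="proximal")
        assert genes == ["a", "b"]
        assert not short

    def test_short_table_flagged(self):
        genes, short = weakest_gene_set(self._table(), n=10, bin="proximal")
        assert len(genes) == 5 and short

    def test_zero_rho_gene_always_first(self):
        t = pd.DataFrame(
            {
                "gene_id": ["z", "a"],
                "site_id": ["s9", "s0"],
                "rho": [0.0, 0.1],
                "bin": ["proximal"] * 2,
            }
        )
        genes, _ = weakest_gene_set(t, n=1, bin="proximal")
        assert genes == ["z"]

    def test_ranking_is_descending_max_abs_rho(self):
        ranking = max_abs_rho_ranking(self._table(), bin="proximal")
        assert list(ranking.index) == ["e", "d", "c", "b", "a"]


class TestSharedSitePairs:
    def _table(self, sig2):
        rows = []
        for g in ("g1", "g2"):
            sig = set(range(5)) if g == "g1" else sig2
            for i in range(10):
                rows.append(
                    {
                        "gene_id": g,
                        "site_id": f"s{i}",
                        "tad_ids": "tad_chr1_0",
                        "rho": 0.9 if i in sig else 0.0,
                        "significant": i in sig,
                    }
                )
        return pd.DataFrame(rows)

    @pytest.fixture()
    def part(self):
        return build_tad_partition([], {"chr1": 1000})

    def test_identical_significant_sets_closed_form(self, part):
        out = shared_site_gene_pairs(self._table(set(range(5))), part)
        assert len(out) == 1
        assert out.loc[0, "p"] == pytest.approx(1 / 252)
        assert out.loc[0, "fold"] == pytest.approx(2.0)

    def test_disjoint_sets_fold_zero(self, part):
        out = shared_site_gene_pairs(self._table({5, 6, 7, 8, 9}), part)
        assert out.loc[0, "fold"] == 0.0
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_random_subsets_average_fold_near_one(self, part):
        rng = np.random.default_rng(0)
        folds = []
        for _ in range(300):
            sig2 = set(rng.choice(10, size=5, replace=False))
            out = shared_site_gene_pairs(self._table(sig2), part)
            folds.append(out.loc[0, "fold"])
        assert np.mean(folds) == pytest.approx(1.0, abs=0.1)


class TestCompareCohorts:
    def test_null_alternate_cohort_detected(self):
        rng = np.random.default_rng(0)
        n_pairs, n_samp = 100, 20
        genes = [f"g{i}" for i in range(n_pairs)]
        sids = [f"site{i}" for i in range(n_pairs)]
        pairs = pd.DataFrame(
            {"gene_id": genes, "site_id": sids, "rho": [-0.8] * n_pairs}
        )
        expr = ExpressionMatrix(
            pd.DataFrame(rng.uniform(1, 10, size=(n_pairs, n_samp)), index=genes,
                         columns=[f"w{i}" for i in range(n_samp)])
        )
        meth = _simple_meth(
            rng.beta(2, 2, size=(n_pairs, n_samp)),
            np.full((n_pairs, n_samp), 30),
            samples=[f"w{i}" for i in range(n_samp)],
        )
        stat, p, n_exc = compare_cohort_coefficients(pairs, expr, meth)
        assert p < 1e-4
        assert n_exc == 0

    def test_too_few_pairs_rejected(self):
        pairs = pd.DataFrame({"gene_id": ["g1"], "site_id": ["site0"], "rho": [0.8]})
        expr = ExpressionMatrix(
            pd.DataFrame(np.ones((1, 5)) * np.arange(5), index=["g1"],
                         columns=[f"w{i}" for i in range(5)])
        )
        meth = _simple_meth(np.full((1, 5), 0.5), np.full((1, 5), 30),
                            samples=[f"w{i}" for i in range(5)])
        with pytest.raises(InsufficientDataError):
            compare_cohort_coefficients(pairs, expr, meth)


def test_proximal_enrichment_detects_planted_excess(discovery):
    _, _, table, _ = discovery
    res = proximal_enrichment_test(table, "negative")
    assert res["n"] > 0
    assert 0 <= res["p"] <= 1
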