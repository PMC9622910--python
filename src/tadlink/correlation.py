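"""Within-TAD expression-methylation correlation discovery.

Every expressed gene is tested against every mCpG (or probe) that overlaps
the same TAD by at least 1 bp.  Spearman rho is computed as Pearson on
average ranks, p-values come from the exact permutation null for untied
vectors with n <= 9 samples and the t-approximation otherwise, and
Benjamini-Hochberg correction is applied genome-wide across all tested
pairs.  A pair is significant when |rho| > 0.5 and FDR < 5% (defaults).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    GeneModel,
    GenomicInterval,
    TadPartition,
    classify_distance,
    gene_site_distance,
)
from .errors import EmptyResultError, InsufficientDataError
from .stats import bh_fdr, hypergeom_enrichment, spearman_pvalue_exact, spearman_pvalues_t
from .tables import ExpressionMatrix, MethylationTable

RHO_THRESHOLD = 0.5
FDR_THRESHOLD = 0.05


@dataclass
class FilterParams:
    min_coverage: int = 10  # site-level: drop sites below this in ANY sample
    probe_value: float = 0.3  # probe-level: keep probes > value ...
    probe_sample_fraction: float = 0.03  # ... in more than this fraction of samples
    top_expressed_fraction: float = 0.5
    protein_coding_only: bool = True


def filter_features(
    expr: ExpressionMatrix, meth: MethylationTable, params: FilterParams = FilterParams()
) -> tuple[ExpressionMatrix, MethylationTable]:
    """Study filters: drop low-coverage sites (site-level) or rarely
    methylated probes (probe-level); keep the top fraction of protein-coding
    genes by mean expression."""
    if meth.mode == "site-level":
        keep = (meth.coverage >= params.min_coverage).all(axis=1)
    else:
        n = meth.fractions.shape[1]
        keep = (meth.fractions > params.probe_value).sum(axis=1) > params.probe_sample_fraction * n
    if not keep.any():
        raise EmptyResultError("no methylation features pass filtering")
    meth_f = meth.subset_sites(meth.fractions.index[keep])

    vals = expr.values
    if params.protein_coding_only and expr.biotypes is not None:
        vals = vals[expr.biotypes.loc[vals.index] == "protein_coding"]
    if vals.empty:
        raise EmptyResultError("no protein-coding genes available")
    n_keep = int(np.ceil(params.top_expressed_fraction * len(vals)))
    top = vals.mean(axis=1).sort_values(ascending=False, kind="stable").index[:n_keep]
    if len(top) == 0:
        raise EmptyResultError("no genes pass the expression filter")
    return expr.subset_genes(top), meth_f


def _rank_zscore(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks, z-scored; returns (Z, zero_variance_mask)."""
    ranks = sps.rankdata(mat, axis=1)
    mu = ranks.mean(axis=1, keepdims=True)
    sd = ranks.std(axis=1, keepdims=True)
    zero = sd[:, 0] == 0
    sd[zero] = 1.0
    return (ranks - mu) / sd, zero


def correlate_within_tads(
    expr: ExpressionMatrix,
    meth: MethylationTable,
    partition: TadPartition,
    genes: Sequence[GeneModel],
    rho_threshold: float = RHO_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Spearman correlation of every unique within-TAD gene-mCpG pair.

    Returns one row per unique pair with columns gene_id, site_id, tad_ids,
    rho, p, q, distance, bin, significant.  Pairs eligible through more than
    one TAD are tested once.  Zero-variance vectors are skipped; the count of
    skipped pairs is attached as ``result.attrs['n_skipped_zero_variance']``.
    """
    shared = expr.samples.intersection(meth.samples)
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} shared samples between matrices (need >= 3)"
        )
    expr = expr.subset_samples(shared)
    meth = meth.subset_samples(shared)
    n = len(shared)

    by_id = {g.gene_id: g for g in genes}
    gene_ids = [g for g in expr.genes if g in by_id]
    site_ids = list(meth.fractions.index)

    E, e_zero = _rank_zscore(expr.values.loc[gene_ids].to_numpy(dtype=float))
    M, m_zero = _rank_zscore(meth.fractions.loc[site_ids].to_numpy(dtype=float))
    e_ties = np.array(
        [len(np.unique(row)) < n for row in expr.values.loc[gene_ids].to_numpy()]
    )
    m_ties = np.array(
        [len(np.unique(row)) < n for row in meth.fractions.loc[site_ids].to_numpy()]
    )

    gene_row = {g: i for i, g in enumerate(gene_ids)}
    site_row = {s: i for i, s in enumerate(site_ids)}

    # TAD membership
    tad_genes: dict[str, list] = {}
    for gid in gene_ids:
        for t in partition.overlapping(by_id[gid].body):
            tad_genes.setdefault(t, []).append(gid)
    tad_sites: dict[str, list] = {}
    sites_df = meth.sites
    for sid in site_ids:
        row = sites_df.loc[sid]
        iv = GenomicInterval(row["chrom"], int(row["pos"]), int(row["pos"]) + 1)
        for t in partition.overlapping(iv):
            tad_sites.setdefault(t, []).append(sid)

    pair_tads: dict[tuple[str, str], set] = {}
    n_skipped = 0
    records: dict[tuple[str, str], float] = {}
    for t, gids in tad_genes.items():
        sids = tad_sites.get(t)
        if not sids:
            continue
        gi = np.array([gene_row[g] for g in gids])
        si = np.array([site_row[s] for s in sids])
        rho_block = E[gi] @ M[si].T / n
        for a, gid in enumerate(gids):
            for b, sid in enumerate(sids):
                key = (gid, sid)
                if key in pair_tads:
                    pair_tads[key].add(t)
                    continue
                if e_zero[gene_row[gid]] or m_zero[site_row[sid]]:
                    n_skipped += 1
                    pair_tads[key] = {t}
                    records[key] = np.nan
                    continue
                pair_tads[key] = {t}
                records[key] = float(rho_block[a, b])

    keys = [k for k, v in records.items() if not np.isnan(v)]
    if not keys:
        raise EmptyResultError("no testable within-TAD pairs")
    rho = np.array([records[k] for k in keys])
    if n <= 9:
        p = np.array(
            [
                spearman_pvalue_exact(r, n)
                if not (e_ties[gene_row[g]] or m_ties[site_row[s]])
                else spearman_pvalues_t(np.array([r]), n)[0]
                for r, (g, s) in zip(rho, keys)
            ]
        )
    else:
        p = spearman_pvalues_t(rho, n)
    q = bh_fdr(p)

    dist = np.empty(len(keys), dtype=np.int64)
    bins = []
    for i, (gid, sid) in enumerate(keys):
        row = sites_df.loc[sid]
        d = gene_site_distance(by_id[gid], row["chrom"], int(row["pos"]))
        dist[i] = d
        bins.append(classify_distance(d, within_body=(d == 0)))

    table = pd.DataFrame(
        {
            "gene_id": [k[0] for k in keys],
            "site_id": [k[1] for k in keys],
            "tad_ids": [",".join(sorted(pair_tads[k])) for k in keys],
            "rho": rho,
            "p": p,
            "q": q,
            "distance": dist,
            "bin": bins,
        }
    )
    table["significant"] = (np.abs(table["rho"]) > rho_threshold) & (
        table["q"] < fdr_threshold
    )
    table.attrs["n_skipped_zero_variance"] = n_skipped
    table.attrs["n_samples"] = n
    return table


def island_mean_methylation(
    meth: MethylationTable, islands: Sequence[GenomicInterval]
) -> MethylationTable:
    """Per CpG island and sample, the unweighted mean fraction over member
    sites; islands without covered sites are dropped."""
    if meth.mode != "site-level":
        raise ValueError("island aggregation requires site-level data")
    rows, names, meta = [], [], []
    for i, isl in enumerate(islands):
        m = (
            (meth.sites["chrom"] == isl.chrom)
            & (meth.sites["pos"] >= isl.start)
            & (meth.sites["pos"] < isl.end)
        )
        if not m.any():
            continue
        rows.append(meth.fractions[m.to_numpy()].mean(axis=0))
        names.append(f"island_{i:04d}")
        meta.append((isl.chrom, isl.start))
    if not rows:
        raise EmptyResultError("no island has covered sites")
    fractions = pd.DataFrame(rows, index=names)
    sites = pd.DataFrame(meta, columns=["chrom", "pos"], index=names)
    return MethylationTable(sites, fractions, None, meth.sample_groups)


def weakest_gene_set(
    table: pd.DataFrame, n: int = 1000, bin: str = "proximal"
) -> tuple[list[str], bool]:
    """The W set: the n genes with the weakest correlations in a distance bin.

    Per gene the score is max |rho| over its sites in the bin; the n
    lowest-scoring genes are returned (ties broken by gene id).  The second
    element flags whether fewer than n genes were available."""
    sub = table[table["bin"] == bin]
    if sub.empty:
        raise EmptyResultError(f"no pairs in bin {bin!r}")
    scores = sub.assign(a=sub["rho"].abs()).groupby("gene_id")["a"].max()
    ranked = scores.reset_index().sort_values(["a", "gene_id"], kind="stable")
    short = len(ranked) < n
    return list(ranked["gene_id"].head(n)), short


def max_abs_rho_ranking(table: pd.DataFrame, bin: Optional[str] = None) -> pd.Series:
    """Genes ranked (descending) by max |rho|, optionally within one bin —
    the input ranking for gene-set enrichment tools."""
    sub = table if bin is None else table[table["bin"] == bin]
    scores = sub.assign(a=sub["rho"].abs()).groupby("gene_id")["a"].max()
    return scores.sort_values(ascending=False, kind="stable")


def shared_site_gene_pairs(
    table: pd.DataFrame, partition: TadPartition
) -> pd.DataFrame:
    """Hypergeometric enrichment of mCpGs commonly correlated with two genes.

    For each within-TAD gene pair with >= 1 significant site each: population
    = sites tested against both genes, draws/successes = each gene's
    significant sites therein, observed = shared significant sites."""
    tested: dict[str, set] = {}
    signif: dict[str, set] = {}
    gene_tads: dict[str, set] = {}
    for row in table.itertuples():
        tested.setdefault(row.gene_id, set()).add(row.site_id)
        gene_tads.setdefault(row.gene_id, set()).update(row.tad_ids.split(","))
        if row.significant:
            signif.setdefault(row.gene_id, set()).add(row.site_id)
    genes = sorted(signif)
    rows = []
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1 :]:
            if not (gene_tads[g1] & gene_tads[g2]):
                continue
            both = tested[g1] & tested[g2]
            if not both:
                continue
            k1 = signif[g1] & both
            k2 = signif[g2] & both
            obs = len(k1 & k2)
            fold, p = hypergeom_enrichment(obs, len(both), len(k1), len(k2))
            rows.append(
                {
                    "gene1": g1,
                    "gene2": g2,
                    "n_shared_tested": len(both),
                    "observed": obs,
                    "fold": 0.0 if obs == 0 else fold,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows, columns=["gene1", "gene2", "n_shared_tested", "observed", "fold", "p"])
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = []
    return out


def compare_cohort_coefficients(
    pairs: pd.DataFrame,
    alt_expr: ExpressionMatrix,
    alt_meth: MethylationTable,
) -> tuple[float, float, int]:
    """Recompute each discovery pair's rho in an alternate sample set and test
    whether |rho| dropped (paired one-sided Wilcoxon signed-rank).

    Returns (statistic, p, n_excluded_zero_variance)."""
    shared = alt_expr.samples.intersection(alt_meth.samples)
    alt_expr = alt_expr.subset_samples(shared)
    alt_meth = alt_meth.subset_samples(shared)
    disc, alt = [], []
    n_excluded = 0
    for row in pairs.itertuples():
        if row.gene_id not in alt_expr.genes or row.site_id not in alt_meth.fractions.index:
            continue
        x = alt_expr.values.loc[row.gene_id].to_numpy(dtype=float)
        y = alt_meth.fractions.loc[row.site_id].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            n_excluded += 1
            continue
        r = sps.spearmanr(x, y).statistic
        disc.append(abs(row.rho))
        alt.append(abs(r))
    if len(disc) < 10:
        raise InsufficientDataError(f"only {len(disc)} comparable pairs (need >= 10)")
    diff = np.asarray(disc) - np.asarray(alt)
    if np.allclose(diff, 0):
        return 0.0, 0.5, n_excluded
    res = sps.wilcoxon(disc, alt, alternative="greater")
    return float(res.statistic), float(res.pvalue), n_excluded


def proximal_enrichment_test(table: pd.DataFrame, direction: str) -> dict:
    """One-sided chi-squared: are positive (or negative) significant
    correlations enriched in the proximal bin relative to all tested pairs?"""
    from .stats import chi2_gof

    sig = table[table["significant"] & ((table["rho"] > 0) == (direction == "positive"))]
    if sig.empty:
        raise EmptyResultError(f"no significant {direction} correlations")
    obs = np.array(
        [(sig["bin"] == "proximal").sum(), (sig["bin"] != "proximal").sum()]
    )
    props = np.array(
        [(table["bin"] == "proximal").sum(), (table["bin"] != "proximal").sum()],
        dtype=float,
    )
    res = chi2_gof(obs, props / props.sum(), one_sided_category=0)
    return {"n": int(len(sig)), "statistic": res.statistic, "p": res.p, "exact_fallback": res.exact_fallback}
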