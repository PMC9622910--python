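"""Significance Analysis of Microarrays (SAM) and the differential
methylation / differential expression analyses built on it.

The two-class SAM statistic for feature i is

    d_i = (mean2_i - mean1_i) / (s_i + s0)

with the Tusher pooled scatter

    s_i = sqrt( (1/n1 + 1/n2) * (SS1_i + SS2_i) / (n1 + n2 - 2) )

and the exchangeability factor s0 chosen to minimise the coefficient of
variation of the d-statistic's spread across the range of s (computed over
percentile windows of s).  The null distribution comes from label
permutations: order statistics of the permuted d are averaged to give the
expected d, and features are called at the smallest threshold delta whose
estimated FDR (pi0 * median permuted call count / observed call count) is
below the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .core import GeneModel, RepeatElement
from .errors import DesignError, InsufficientDataError
from .stats import chi2_gof, hypergeom_enrichment
from .tables import ExpressionMatrix, MethylationTable

_PERM_CHUNK = 500


@dataclass
class SamResult:
    """Outcome of a two-class SAM run."""

    scores: pd.DataFrame  # per feature: d, s, numerator
    s0: float
    delta: float
    fdr_at_delta: float
    pi0: float
    significant: pd.DataFrame  # feature id index, columns: d, direction
    expected_d: np.ndarray  # mean permuted order statistics, ascending
    observed_d_sorted: np.ndarray
    n_permutations: int
    seed: Optional[int]
    class_labels: tuple[str, str] = ("class1", "class2")

    @property
    def up(self) -> list:
        return list(self.significant.index[self.significant["direction"] == "up"])

    @property
    def down(self) -> list:
        return list(self.significant.index[self.significant["direction"] == "down"])


def _class_masks(labels: Sequence) -> tuple[np.ndarray, np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise DesignError(f"expected exactly two classes, got {list(classes)}")
    m1 = labels == classes[0]
    m2 = labels == classes[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise DesignError("each class needs >= 2 samples")
    return m1, m2, (classes[0], classes[1])


def _d_stats(X: np.ndarray, mask2: np.ndarray, s0: float = 0.0):
    """Numerator, scatter and d for class assignment given by mask2 (class 2)."""
    m1, m2 = ~mask2, mask2
    n1, n2 = m1.sum(), m2.sum()
    mu1 = X[:, m1].mean(axis=1)
    mu2 = X[:, m2].mean(axis=1)
    ss1 = ((X[:, m1] - mu1[:, None]) ** 2).sum(axis=1)
    ss2 = ((X[:, m2] - mu2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    r = mu2 - mu1
    with np.errstate(invalid="ignore", divide="ignore"):
        d = r / (s + s0)
    return r, s, d


def _select_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Tusher/Chu fudge factor: minimise the CV of the d-spread across s."""
    alphas = np.arange(0.0, 1.0001, 0.05)
    qs = np.quantile(s, alphas)
    # 100 percentile windows of s
    edges = np.quantile(s, np.linspace(0, 1, 101))
    bin_idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 99)
    best_cv, best_s0 = np.inf, 0.0
    for s0 in qs:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = r / (s + s0)
        vs = []
        for b in range(100):
            sel = bin_idx == b
            if sel.sum() >= 2:
                vs.append(median_abs_deviation(d[sel], scale="normal"))
        vs = np.asarray(vs)
        if len(vs) < 2 or vs.mean() == 0:
            continue
        cv = vs.std(ddof=1) / vs.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _permutation_masks(n: int, n2: int, n_perm: int, rng: np.random.Generator):
    """Boolean masks (B x n) assigning samples to class 2 under the null."""
    total = comb(n, n2)
    if total <= n_perm:
        from itertools import combinations

        masks = np.zeros((total, n), dtype=bool)
        for b, idx in enumerate(combinations(range(n), n2)):
            masks[b, list(idx)] = True
        return masks
    masks = np.zeros((n_perm, n), dtype=bool)
    for b in range(n_perm):
        masks[b, rng.choice(n, size=n2, replace=False)] = True
    return masks


def sam_two_class(
    X,
    labels: Sequence,
    n_perm: int = 5000,
    fdr_target: float = 0.05,
    seed: Optional[int] = 0,
) -> SamResult:
    """Two-class SAM with permutation null and delta/FDR calibration.

    ``X`` is a feature x sample DataFrame (or array); ``labels`` gives the
    two class labels per sample (order of first appearance defines class 1
    vs class 2; d > 0 means higher in class 2).
    """
    if isinstance(X, pd.DataFrame):
        features = X.index
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        features = pd.RangeIndex(mat.shape[0])
    mask1, mask2, classes = _class_masks(labels)
    rng = np.random.default_rng(seed)

    r, s, _ = _d_stats(mat, mask2)
    s0 = _select_s0(r, s)
    if s0 <= 0 and (s == 0).any():
        # zero-scatter features: keep the denominator strictly positive
        s0 = float(s[s > 0].min()) * 0.05 if (s > 0).any() else 1.0
    d = r / (s + s0)

    n = mat.shape[1]
    masks = _permutation_masks(n, int(mask2.sum()), n_perm, rng)
    B = masks.shape[0]
    p = mat.shape[0]
    perm_sorted = np.empty((B, p))
    for start in range(0, B, _PERM_CHUNK):
        block = masks[start : start + _PERM_CHUNK]
        for j, m2 in enumerate(block):
            _, _, db = _d_stats(mat, m2, s0)
            perm_sorted[start + j] = np.sort(db)
    expected_d = perm_sorted.mean(axis=0)

    order = np.argsort(d)
    d_sorted = d[order]

    # pi0: fraction of features whose d falls in the central 50% of the null
    q25, q75 = np.quantile(perm_sorted, [0.25, 0.75])
    pi0 = min(1.0, np.count_nonzero((d >= q25) & (d <= q75)) / (0.5 * p))

    diffs = d_sorted - expected_d
    candidate_deltas = np.unique(np.concatenate([[0.0], np.abs(diffs)]))

    def _cuts(delta: float):
        up = np.where(diffs >= delta)[0]
        lo = np.where(diffs <= -delta)[0]
        cutup = d_sorted[up[0]] if len(up) else np.inf
        cutlow = d_sorted[lo[-1]] if len(lo) else -np.inf
        if cutlow >= cutup:  # degenerate crossing; call nothing on the low side
            cutlow = -np.inf
        return cutup, cutlow

    chosen_delta, chosen_fdr, cutup, cutlow = None, 1.0, np.inf, -np.inf
    for delta in candidate_deltas:
        cu, cl = _cuts(float(delta))
        called = int(np.count_nonzero((d >= cu) | (d <= cl)))
        if called == 0:
            chosen_delta, chosen_fdr, cutup, cutlow = float(delta), 0.0, cu, cl
            break
        false_called = np.median(
            np.count_nonzero((perm_sorted >= cu) | (perm_sorted <= cl), axis=1)
        )
        fdr = min(1.0, pi0 * false_called / called)
        if fdr <= fdr_target:
            chosen_delta, chosen_fdr, cutup, cutlow = float(delta), float(fdr), cu, cl
            break
    if chosen_delta is None:  # nothing satisfies the target
        chosen_delta, chosen_fdr = float(candidate_deltas[-1]), 1.0
        cutup, cutlow = np.inf, -np.inf

    sig_mask = (d >= cutup) | (d <= cutlow)
    significant = pd.DataFrame(
        {
            "d": d[sig_mask],
            "direction": np.where(d[sig_mask] > 0, "up", "down"),
        },
        index=features[sig_mask],
    )
    scores = pd.DataFrame({"d": d, "s": s, "numerator": r}, index=features)
    return SamResult(
        scores=scores,
        s0=float(s0),
        delta=chosen_delta,
        fdr_at_delta=chosen_fdr,
        pi0=float(pi0),
        significant=significant,
        expected_d=expected_d,
        observed_d_sorted=d_sorted,
        n_permutations=B,
        seed=seed,
        class_labels=(str(classes[0]), str(classes[1])),
    )


# ---------------------------------------------------------------------------
# differential methylation of retrotransposons


def _sites_on_intervals(sites: pd.DataFrame, intervals) -> pd.Index:
    """Site ids (1-bp positions) falling on any of the intervals."""
    hits = []
    by_chrom: dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, ranges in by_chrom.items():
        ranges.sort()
        starts = np.array([r[0] for r in ranges])
        ends = np.array([r[1] for r in ranges])
        sub = sites[sites["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        hits.extend(sub.index[ok])
    return pd.Index(hits)


def dmc_by_repeat_family(
    meth: MethylationTable,
    labels: Sequence,
    repeats: Sequence[RepeatElement],
    family: str,
    n_perm: int = 5000,
    fdr_target: float = 0.05,
    seed: Optional[int] = 0,
) -> tuple[SamResult, dict]:
    """Differentially methylated cytosines on one retrotransposon family.

    Eligible sites overlap the family, have coverage > 10 in every sample and
    non-zero methylation in >= 2 samples of each class; SAM is then run on
    the methylation fractions.  Returns the SAM result plus a summary with
    the %DMC among tested family sites and the hyper/hypo split.
    """
    fam_ivs = [r.interval for r in repeats if r.family == family]
    if not fam_ivs:
        raise InsufficientDataError(f"no {family} elements annotated")
    ids = _sites_on_intervals(meth.sites, fam_ivs)
    if len(ids) == 0:
        raise InsufficientDataError(f"no sites overlap {family} elements")
    frac = meth.fractions.loc[ids]
    labels = np.asarray(labels)
    keep = pd.Series(True, index=ids)
    if meth.coverage is not None:
        keep &= (meth.coverage.loc[ids] > 10).all(axis=1)
    for cls in pd.unique(labels):
        keep &= (frac.loc[:, labels == cls] > 0).sum(axis=1) >= 2
    frac = frac[keep]
    if len(frac) < 10:
        raise InsufficientDataError(
            f"only {len(frac)} eligible {family} sites (need >= 10)"
        )
    res = sam_two_class(frac, labels, n_perm=n_perm, fdr_target=fdr_target, seed=seed)
    n_dmc = len(res.significant)
    summary = {
        "family": family,
        "n_tested": int(len(frac)),
        "n_dmc": int(n_dmc),
        "pct_dmc": 100.0 * n_dmc / len(frac),
        "n_hyper_in_" + res.class_labels[1]: int((res.significant["direction"] == "up").sum()),
        "n_hypo_in_" + res.class_labels[1]: int((res.significant["direction"] == "down").sum()),
    }
    return res, summary


def annotate_site_category(
    sites: pd.DataFrame, genes: Sequence[GeneModel]
) -> pd.Series:
    """Mutually exclusive site category with precedence
    protein-coding > non-coding > intergenic."""
    coding = [g.body for g in genes if g.biotype == "protein_coding"]
    noncod = [g.body for g in genes if g.biotype != "protein_coding"]
    cat = pd.Series("intergenic", index=sites.index)
    nc_ids = _sites_on_intervals(sites, noncod) if noncod else pd.Index([])
    cat.loc[nc_ids] = "non-coding"
    pc_ids = _sites_on_intervals(sites, coding) if coding else pd.Index([])
    cat.loc[pc_ids] = "protein-coding"
    return cat


def dmc_annotation_tests(
    dmc_ids,
    meth: MethylationTable,
    genes: Sequence[GeneModel],
    enhancers,
    gene_sets: Optional[dict[str, set]] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Positional annotation of DMCs vs all tested sites.

    Chi-squared of the protein-coding / non-coding / intergenic split against
    the tested-site proportions, plus hypergeometric folds for overlap with
    enhancers and with supplied gene sets (e.g. proximal and W sets).
    """
    dmc_ids = pd.Index(dmc_ids)
    sites = meth.sites
    cat = annotate_site_category(sites, genes)
    order = ["protein-coding", "non-coding", "intergenic"]
    all_counts = cat.value_counts().reindex(order).fillna(0).to_numpy()
    dmc_counts = cat.loc[dmc_ids].value_counts().reindex(order).fillna(0).to_numpy()
    chi2 = chi2_gof(dmc_counts, all_counts / all_counts.sum(), rng=rng)

    report: dict = {
        "categories": order,
        "dmc_counts": dmc_counts.astype(int).tolist(),
        "tested_counts": all_counts.astype(int).tolist(),
        "chi2": chi2,
    }
    N, n = len(sites), len(dmc_ids)
    enh_ids = _sites_on_intervals(sites, enhancers) if len(enhancers) else pd.Index([])
    K = len(enh_ids)
    obs = len(dmc_ids.intersection(enh_ids))
    fold, p = hypergeom_enrichment(obs, N, K, n)
    report["enhancer"] = {"fold": fold, "p": p, "observed": obs}

    if gene_sets:
        by_id = {g.gene_id: g for g in genes}
        report["gene_sets"] = {}
        for name, gset in gene_sets.items():
            bodies = [by_id[g].body for g in gset if g in by_id]
            in_ids = _sites_on_intervals(sites, bodies) if bodies else pd.Index([])
            obs = len(dmc_ids.intersection(in_ids))
            fold, p = hypergeom_enrichment(obs, N, len(in_ids), n)
            report["gene_sets"][name] = {"fold": fold, "p": p, "observed": obs}
    return report


# ---------------------------------------------------------------------------
# differential expression


def de_two_class(
    expr: ExpressionMatrix,
    labels: Sequence,
    pseudo_replicate: bool = False,
    n_perm: int = 5000,
    fdr_target: float = 0.05,
    seed: Optional[int] = 0,
    log_offset: float = 1.0,
    min_median: Optional[float] = None,
) -> SamResult:
    """Two-class differential expression via SAM on log2(x + offset).

    With ``pseudo_replicate`` and exactly two samples per class, the per-gene
    mean of the two replicates is appended as a third pseudo-replicate before
    the statistic is computed.  ``min_median`` optionally drops genes with a
    median expression below the threshold (FPKM-like filtering).
    """
    X = expr.values
    labels = np.asarray(labels)
    if min_median is not None:
        X = X[X.median(axis=1) >= min_median]
    if X.empty:
        raise InsufficientDataError("no genes pass the expression filter")
    logX = np.log2(X + log_offset)
    if pseudo_replicate:
        cols, labs = [logX], [labels]
        for cls in pd.unique(labels):
            m = labels == cls
            if m.sum() != 2:
                raise DesignError(
                    f"pseudo-replicate rule requires exactly 2 samples per class; "
                    f"class {cls!r} has {m.sum()}"
                )
            mean_col = logX.loc[:, m].mean(axis=1).to_frame(f"{cls}_pseudo")
            cols.append(mean_col)
            labs.append(np.array([cls]))
        logX = pd.concat(cols, axis=1)
        labels = np.concatenate(labs)
    return sam_two_class(logX, labels, n_perm=n_perm, fdr_target=fdr_target, seed=seed)
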