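"""Gene and mCpG architecture profiling.

Per-gene metrics (exon/intron length, GC, median per-base conservation,
repeat-family densities), ECDF-shift curves against a background gene
population with one-sample Kolmogorov-Smirnov tests, hypergeometric
contains-at-least-one-element enrichment, B-box scanning of repeat
sequences, TAD-boundary distance tests, and the MIR-dense vs MIR-zero
matched comparison of methylation dependency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    GeneModel,
    GenomicInterval,
    RepeatElement,
    StepTrack,
    TadPartition,
    merge_intervals,
    overlap_bases,
)
from .errors import EmptyResultError, InsufficientDataError
from .stats import hypergeom_enrichment

BBOX_SENSE = re.compile(r"(?=GTTC.A..C)")
BBOX_ANTISENSE = re.compile(r"(?=G..T.GAAC)")  # reverse complement of GTTCNANNC


def compute_architecture(
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatElement],
    conservation: Optional[StepTrack] = None,
    gc: Optional[StepTrack] = None,
    cpg_positions: Optional[pd.DataFrame] = None,
    families: Sequence[str] = ("MIR", "Alu", "L1"),
    min_track_coverage: float = 0.5,
) -> pd.DataFrame:
    """One row per gene with lengths, GC, conservation and repeat densities.

    Intronless genes carry NaN intronic fields and are excluded from
    intron-based tests downstream.  Genes with < ``min_track_coverage`` of
    their bases covered by the conservation track are flagged."""
    fam_ivs = {f: [r.interval for r in repeats if r.family == f] for f in families}
    rows = []
    for g in genes:
        exons, introns = list(g.exons), list(g.introns)
        rec = {
            "gene_id": g.gene_id,
            "biotype": g.biotype,
            "exonic_length": g.exonic_length,
            "intronic_length": g.intronic_length if introns else np.nan,
        }
        if gc is not None:
            rec["gc_exon"] = gc.mean_over(exons)
            rec["gc_intron"] = gc.mean_over(introns) if introns else np.nan
        if conservation is not None:
            rec["cons_exon"] = conservation.median_over(exons)
            rec["cons_intron"] = conservation.median_over(introns) if introns else np.nan
            rec["low_track_coverage"] = (
                conservation.coverage_fraction(exons + introns) < min_track_coverage
            )
        for f in families:
            rec[f"{f}_density_exon"] = overlap_bases(exons, fam_ivs[f]) / g.exonic_length
            rec[f"{f}_density_intron"] = (
                overlap_bases(introns, fam_ivs[f]) / g.intronic_length
                if introns
                else np.nan
            )
            rec[f"contains_{f}"] = bool(
                overlap_bases(exons, fam_ivs[f]) + (overlap_bases(introns, fam_ivs[f]) if introns else 0)
            )
        if cpg_positions is not None:
            m = (
                (cpg_positions["chrom"] == g.chrom)
                & (cpg_positions["pos"] >= g.body.start)
                & (cpg_positions["pos"] < g.body.end)
            )
            rec["cpg_density"] = 1_000.0 * m.sum() / len(g.body)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class EcdfShiftCurve:
    """Background ECDF minus gene-set ECDF on a shared grid.

    Positive values mean the set's distribution is shifted toward higher
    metric values."""

    grid: np.ndarray
    curve: np.ndarray

    @property
    def max_abs(self) -> float:
        return float(np.max(np.abs(self.curve))) if len(self.curve) else 0.0


def _ecdf(values: np.ndarray):
    v = np.sort(values)

    def f(x):
        return np.searchsorted(v, x, side="right") / len(v)

    return f


def ecdf_shift_test(
    set_values, background_values
) -> tuple[EcdfShiftCurve, float, float, bool]:
    """One-sample KS of a gene set against the background ECDF.

    Returns (curve, D, p, small_set_warning).  D equals max |curve| because
    both ECDFs are evaluated on the union of their jump points."""
    s = np.asarray(set_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    s, b = s[~np.isnan(s)], b[~np.isnan(b)]
    if len(s) == 0 or len(b) == 0:
        raise EmptyResultError("empty value set")
    grid = np.unique(np.concatenate([s, b]))
    fb, fs = _ecdf(b), _ecdf(s)
    curve = fb(grid) - fs(grid)
    # both ECDFs are constant between grid points, so the supremum of the
    # discrepancy is attained on the grid itself
    D = float(np.max(np.abs(curve)))
    p = float(sps.kstwo.sf(D, len(s)))
    return EcdfShiftCurve(grid, curve), D, p, len(s) < 5


def contains_element_enrichment(
    gene_set: Sequence[str],
    background_genes: Sequence[str],
    architecture: pd.DataFrame,
    family: str,
) -> tuple[float, float]:
    """Hypergeometric test: does the gene set contain more genes with >= 1
    element of ``family`` than expected from the background?"""
    col = f"contains_{family}"
    bg = architecture.loc[list(background_genes), col]
    if not bg.any():
        return float("nan"), 1.0
    sset = architecture.loc[list(gene_set), col]
    fold, p = hypergeom_enrichment(
        int(sset.sum()), len(bg), int(bg.sum()), len(sset)
    )
    return fold, p


def site_architecture_tests(
    sites_sig: pd.DataFrame,
    sites_all: pd.DataFrame,
    repeats: Sequence[RepeatElement],
    conservation: Optional[StepTrack] = None,
    enhancers: Optional[Sequence[GenomicInterval]] = None,
    families: Sequence[str] = ("MIR", "Alu", "L1"),
) -> dict:
    """Architecture of significant mCpGs against all tested mCpGs.

    KS on per-site conservation plus hypergeometric folds for overlap with
    each repeat family and with enhancers."""
    report: dict = {}
    if sites_sig.empty:
        return report
    if conservation is not None:
        cs = np.concatenate(
            [
                conservation.values_at(c, g["pos"].to_numpy())
                for c, g in sites_sig.groupby("chrom")
            ]
        )
        cb = np.concatenate(
            [
                conservation.values_at(c, g["pos"].to_numpy())
                for c, g in sites_all.groupby("chrom")
            ]
        )
        cs, cb = cs[~np.isnan(cs)], cb[~np.isnan(cb)]
        curve, D, p, warn = ecdf_shift_test(cs, cb)
        report["conservation"] = {"D": D, "p": p, "curve": curve, "small_set": warn}

    def _on(intervals, sites) -> int:
        if not intervals:
            return 0
        flags = _positions_on(sites, intervals)
        return int(flags.sum())

    N, n = len(sites_all), len(sites_sig)
    for f in families:
        ivs = [r.interval for r in repeats if r.family == f]
        K = _on(ivs, sites_all)
        if K == 0:
            report[f] = {"excluded": True}
            continue
        obs = _on(ivs, sites_sig)
        fold, p = hypergeom_enrichment(obs, N, K, n)
        report[f] = {"fold": fold, "p": p, "observed": obs, "background": K}
    if enhancers:
        K = _on(list(enhancers), sites_all)
        obs = _on(list(enhancers), sites_sig)
        fold, p = hypergeom_enrichment(obs, N, K, n)
        report["enhancer"] = {"fold": fold, "p": p, "observed": obs, "background": K}
    return report


def _positions_on(sites: pd.DataFrame, intervals) -> np.ndarray:
    flags = np.zeros(len(sites), dtype=bool)
    merged = merge_intervals(intervals)
    by_chrom: dict[str, list] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for chrom, ivs in by_chrom.items():
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        m = chroms == chrom
        idx = np.searchsorted(starts, pos[m], side="right") - 1
        ok = (idx >= 0) & (pos[m] < ends[np.clip(idx, 0, None)])
        flags[np.where(m)[0][ok]] = True
    return flags


def bbox_scan(
    elements: Sequence[RepeatElement], sequences: Mapping[str, str]
) -> pd.Series:
    """Count B-box motifs (GTTCNANNC, sense or antisense) per element.

    Overlapping matches all count; any non-ACGT character fails the fixed
    motif positions while N positions match any character."""
    counts = {}
    for el in elements:
        seq = sequences.get(el.element_id, "").upper()
        counts[el.element_id] = len(BBOX_SENSE.findall(seq)) + len(
            BBOX_ANTISENSE.findall(seq)
        )
    return pd.Series(counts, dtype=int)


def boundary_distance_test(
    elements: Sequence[RepeatElement],
    partition: TadPartition,
    background_elements: Sequence[RepeatElement],
) -> dict:
    """Two-sample KS of distance-to-nearest-TAD-boundary, set vs background."""

    def _dists(els):
        out = np.empty(len(els))
        for i, el in enumerate(els):
            bnd = partition.boundaries(el.interval.chrom)
            iv = el.interval
            inside = bnd[(bnd >= iv.start) & (bnd <= iv.end)]
            if len(inside):
                out[i] = 0
            else:
                out[i] = min(
                    np.min(np.abs(bnd - iv.start)), np.min(np.abs(bnd - iv.end))
                )
        return out

    ds = _dists(list(elements))
    db = _dists(list(background_elements))
    res = sps.ks_2samp(ds, db)
    return {
        "D": float(res.statistic),
        "p": float(res.pvalue),
        "median_set": float(np.median(ds)),
        "median_background": float(np.median(db)),
    }


def mir_zero_matched_test(
    corr_table: pd.DataFrame,
    architecture: pd.DataFrame,
    caliper_sd: float = 0.2,
    min_pairs: int = 20,
) -> dict:
    """Methylation dependency of MIR-dense vs matched MIR-zero genes.

    Top-decile intronic-MIR-density genes are matched to MIR-zero genes on
    CpG density (nearest neighbour within a caliper of ``caliper_sd`` SDs,
    without replacement); per-gene max |rho| distributions are compared by
    two-sample KS."""
    arch = architecture.dropna(subset=["MIR_density_intron", "cpg_density"])
    scores = (
        corr_table.assign(a=corr_table["rho"].abs()).groupby("gene_id")["a"].max()
    )
    arch = arch[arch.index.isin(scores.index)]
    zero = arch[arch["MIR_density_intron"] == 0]
    nonzero = arch[arch["MIR_density_intron"] > 0]
    if zero.empty:
        raise InsufficientDataError("no MIR-zero genes available")
    cutoff = nonzero["MIR_density_intron"].quantile(0.9)
    dense = nonzero[nonzero["MIR_density_intron"] >= cutoff]
    sd = arch["cpg_density"].std()
    caliper = caliper_sd * sd if sd > 0 else np.inf
    available = dict(zero["cpg_density"])
    pairs = []
    for gid, cd in dense["cpg_density"].items():
        if not available:
            break
        best = min(available, key=lambda z: abs(available[z] - cd))
        if abs(available[best] - cd) <= caliper:
            pairs.append((gid, best))
            del available[best]
    if len(pairs) < min_pairs:
        raise InsufficientDataError(
            f"only {len(pairs)} matched pairs within the caliper (need >= {min_pairs})"
        )
    a = scores.loc[[p[0] for p in pairs]].to_numpy()
    b = scores.loc[[p[1] for p in pairs]].to_numpy()
    res = sps.ks_2samp(a, b)
    return {
        "D": float(res.statistic),
        "p": float(res.pvalue),
        "n_pairs": len(pairs),
        "median_mir_dense": float(np.median(a)),
        "median_mir_zero": float(np.median(b)),
    }
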