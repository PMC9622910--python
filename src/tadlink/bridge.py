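"""Protein-pair bridging of correlated mCpG-gene pairs.

A physically interacting protein pair (A, B) "bridges" a correlated pair
when A has a ChIP-seq peak on the mCpG and B on the gene (or, in MIR mode,
on a MIR element in the gene's intronic space).  Enrichment is evaluated
against all correlated pairs by an upper-tail hypergeometric test, BH
corrected across the tested PPIs.  Ordered pairs are tested separately:
(A at site, B at gene) is not the same hypothesis as (B at site, A at gene).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, RepeatElement
from .stats import bh_fdr, hypergeom_enrichment


def binding_map(
    dbp_peaks: Mapping[str, Sequence[GenomicInterval]],
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    repeats: Optional[Sequence[RepeatElement]] = None,
) -> dict:
    """Per-entity DBP sets.

    Returns {'site': {site_id: set}, 'gene': {gene_id: set},
    'gene_mir': {gene_id: set}} where gene_mir restricts gene binding to the
    footprints of the gene's intronic MIR elements."""
    intronic_mirs: dict[str, list[GenomicInterval]] = {}
    if repeats is not None:
        for g in genes:
            for r in repeats:
                if r.family != "MIR" or r.interval.chrom != g.chrom:
                    continue
                if any(r.interval.overlaps(i) for i in g.introns):
                    intronic_mirs.setdefault(g.gene_id, []).append(r.interval)

    site_map: dict[str, set] = {s: set() for s in sites.index}
    gene_map: dict[str, set] = {g.gene_id: set() for g in genes}
    mir_map: dict[str, set] = {g.gene_id: set() for g in genes}
    for dbp, peaks in dbp_peaks.items():
        by_chrom: dict[str, list] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
        index = {}
        for chrom, ps in by_chrom.items():
            ps.sort()
            starts = np.array([a for a, _ in ps], dtype=np.int64)
            ends = np.maximum.accumulate(np.array([b for _, b in ps], dtype=np.int64))
            index[chrom] = (starts, ends)

        def _hit(chrom: str, lo: int, hi: int) -> bool:
            if chrom not in index:
                return False
            starts, ends = index[chrom]
            k = int(np.searchsorted(starts, hi, side="left"))
            return k > 0 and ends[k - 1] > lo

        for sid, row in sites.iterrows():
            if _hit(row["chrom"], int(row["pos"]), int(row["pos"]) + 1):
                site_map[sid].add(dbp)
        for g in genes:
            if _hit(g.chrom, g.body.start, g.body.end):
                gene_map[g.gene_id].add(dbp)
            for iv in intronic_mirs.get(g.gene_id, ()):
                if _hit(iv.chrom, iv.start, iv.end):
                    mir_map[g.gene_id].add(dbp)
                    break
    return {"site": site_map, "gene": gene_map, "gene_mir": mir_map}


def bridge_enrichment(
    correlated_pairs: pd.DataFrame,
    bmap: dict,
    ppi_edges: Sequence[tuple],
    mode: str = "gene",
    include_self: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of PPI pairs bridging correlated pairs.

    ``correlated_pairs`` needs gene_id and site_id columns (typically the
    significant rows of the correlation table).  For ordered PPI (A, B):
    population = all correlated pairs, draws = pairs with A bound at the
    site, successes = pairs with B bound at the gene (mode 'gene') or at an
    intronic MIR of the gene (mode 'mir'), observed = pairs with both."""
    if mode not in ("gene", "mir"):
        raise ValueError("mode must be 'gene' or 'mir'")
    gene_key = "gene" if mode == "gene" else "gene_mir"
    pairs = list(
        zip(correlated_pairs["gene_id"].tolist(), correlated_pairs["site_id"].tolist())
    )
    N = len(pairs)
    rows = []
    ordered = []
    for a, b in ppi_edges:
        ordered.append((a, b))
        if (b, a) not in ordered:
            ordered.append((b, a))
    for a, b in ordered:
        if a == b and not include_self:
            continue
        a_at_site = np.array([a in bmap["site"].get(s, ()) for _, s in pairs])
        b_at_gene = np.array([b in bmap[gene_key].get(g, ()) for g, _ in pairs])
        draws = int(a_at_site.sum())
        succ = int(b_at_gene.sum())
        obs = int((a_at_site & b_at_gene).sum())
        if draws == 0 or succ == 0:
            continue
        fold, p = hypergeom_enrichment(obs, N, succ, draws)
        rows.append(
            {
                "protein_site": a,
                "protein_gene": b,
                "observed": obs,
                "draws": draws,
                "successes": succ,
                "population": N,
                "fold": 0.0 if obs == 0 else fold,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "protein_site",
            "protein_gene",
            "observed",
            "draws",
            "successes",
            "population",
            "fold",
            "p",
        ],
    )
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out
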