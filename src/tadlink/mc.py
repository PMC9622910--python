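"""Monte-Carlo interval-shuffling null for DNA-binding-protein enrichment.

Observed = number of features (genes, MIR elements, mCpGs) overlapped by at
least one ChIP-seq peak.  The null shuffles the peaks uniformly within a
genomic space (e.g. the union of all tested genes), preserving peak lengths
and keeping each peak inside a single space segment; the enrichment Z-score
compares the observed count with the shuffled distribution.  |Z| > 10 is the
conventional significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, RepeatElement, merge_intervals
from .errors import InsufficientDataError, PlacementError

Z_THRESHOLD = 10.0


@dataclass
class McResult:
    name: str
    observed: int
    null_mean: float
    null_sd: float
    z: float
    n_iterations: int
    seed: Optional[int]
    degenerate: bool = False
    n_features: int = 0

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and abs(self.z) > Z_THRESHOLD


class _Space:
    """Merged space segments, linearised into disjoint global blocks
    (one spacer base between blocks so no cross-segment overlap is possible)."""

    def __init__(self, space: Sequence[GenomicInterval]):
        self.segments = merge_intervals(space)
        if not self.segments:
            raise PlacementError("empty shuffling space")
        self.seg_len = np.array([len(s) for s in self.segments], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.seg_len + 1)[:-1]])

    def to_global_pieces(self, intervals: Sequence[GenomicInterval]):
        """Clip intervals to segments; returns (starts, ends, owner_index)."""
        starts, ends, owners = [], [], []
        for i, iv in enumerate(intervals):
            for k, seg in enumerate(self.segments):
                if seg.chrom != iv.chrom:
                    continue
                lo, hi = max(iv.start, seg.start), min(iv.end, seg.end)
                if lo < hi:
                    starts.append(self.offsets[k] + lo - seg.start)
                    ends.append(self.offsets[k] + hi - seg.start)
                    owners.append(i)
        return (
            np.array(starts, dtype=np.int64),
            np.array(ends, dtype=np.int64),
            np.array(owners, dtype=np.int64),
        )


def _placement_tables(sp: _Space, lengths: np.ndarray):
    """Cumulative valid-start counts per (segment, peak length)."""
    counts = np.maximum(sp.seg_len[:, None] - lengths[None, :] + 1, 0)  # K x P
    cum = np.cumsum(counts, axis=0)
    totals = cum[-1]
    return counts, cum, totals


def shuffle_within_space(
    intervals: Sequence[GenomicInterval],
    space: Sequence[GenomicInterval],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Place each interval uniformly among all positions where it fits
    entirely inside one space segment (longer segments get proportionally
    more mass).  Lengths are preserved; shuffled intervals may overlap."""
    sp = _Space(space)
    lengths = np.array([len(iv) for iv in intervals], dtype=np.int64)
    counts, cum, totals = _placement_tables(sp, lengths)
    for iv, total in zip(intervals, totals):
        if total == 0:
            raise PlacementError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} "
                f"(len {len(iv)}) fits in no space segment"
            )
    u = (rng.random(len(lengths)) * totals).astype(np.int64)
    seg = np.argmax(cum > u[None, :], axis=0)
    offset = u - (cum[seg, np.arange(len(lengths))] - counts[seg, np.arange(len(lengths))])
    out = []
    for i, l in enumerate(lengths):
        s = sp.segments[seg[i]]
        start = s.start + int(offset[i])
        out.append(GenomicInterval(s.chrom, start, start + int(l)))
    return out


def _count_overlapped(features: Sequence[GenomicInterval], peaks) -> int:
    """Number of features overlapped by >= 1 peak (>= 1 bp)."""
    by_chrom: dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    index = {}
    for chrom, ps in by_chrom.items():
        ps.sort()
        starts = np.array([a for a, _ in ps], dtype=np.int64)
        ends = np.maximum.accumulate(np.array([b for _, b in ps], dtype=np.int64))
        index[chrom] = (starts, ends)
    n = 0
    for f in features:
        if f.chrom not in index:
            continue
        starts, ends = index[f.chrom]
        k = int(np.searchsorted(starts, f.end, side="left"))
        if k > 0 and ends[k - 1] > f.start:
            n += 1
    return n


def mc_enrichment_z(
    peaks: Sequence[GenomicInterval],
    feature_set: Sequence[GenomicInterval],
    space: Sequence[GenomicInterval],
    n: int = 1000,
    seed: Optional[int] = 0,
    name: str = "",
) -> McResult:
    """Monte-Carlo Z-score for peak enrichment over a feature set.

    The null is computed in a linearised copy of the space so that a whole
    iteration is a handful of vector operations."""
    if n < 100:
        raise ValueError("need >= 100 iterations")
    rng = np.random.default_rng(seed)
    features = list(feature_set)
    peaks = list(peaks)
    if not peaks:
        return McResult(name, 0, 0.0, 0.0, 0.0, n, seed, degenerate=True,
                        n_features=len(features))
    observed = _count_overlapped(features, peaks)

    sp = _Space(space)
    lengths = np.array([len(p) for p in peaks], dtype=np.int64)
    counts, cum, totals = _placement_tables(sp, lengths)
    if (totals == 0).any():
        bad = peaks[int(np.argmax(totals == 0))]
        raise PlacementError(
            f"interval {bad.chrom}:{bad.start}-{bad.end} fits in no space segment"
        )
    f_start, f_end, f_owner = sp.to_global_pieces(features)
    n_feat = len(features)
    P = len(peaks)
    idx = np.arange(P)
    null = np.empty(n)
    for b in range(n):
        u = (rng.random(P) * totals).astype(np.int64)
        seg = np.argmax(cum > u[None, :], axis=0)
        start = sp.offsets[seg] + (u - (cum[seg, idx] - counts[seg, idx]))
        end = start + lengths
        order = np.argsort(start)
        ps, pe = start[order], np.maximum.accumulate(end[order])
        k = np.searchsorted(ps, f_end, side="left")
        hit = (k > 0) & (pe[np.clip(k - 1, 0, None)] > f_start)
        mask = np.zeros(n_feat, dtype=bool)
        mask[f_owner[hit]] = True
        null[b] = mask.sum()
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        return McResult(name, observed, mean, 0.0, 0.0, n, seed, degenerate=True,
                        n_features=len(features))
    return McResult(
        name, observed, mean, sd, (observed - mean) / sd, n, seed,
        n_features=len(features)
    )


def mir_space_z(
    peaks: Sequence[GenomicInterval],
    gene_set: Sequence[GeneModel],
    repeats: Sequence[RepeatElement],
    n: int = 1000,
    seed: Optional[int] = 0,
    name: str = "",
) -> McResult:
    """Monte-Carlo enrichment restricted to the intronic MIR elements of a
    gene set: those MIRs are both the features and the shuffling space.
    Peaks longer than the largest MIR are centre-trimmed to fit."""
    mirs = []
    for r in repeats:
        if r.family != "MIR":
            continue
        for g in gene_set:
            if r.interval.chrom == g.chrom and any(
                r.interval.overlaps(i) for i in g.introns
            ):
                mirs.append(r.interval)
                break
    if not mirs:
        raise InsufficientDataError("gene set has no intronic MIR elements")
    max_len = max(len(m) for m in mirs)
    fitted = []
    for p in peaks:
        if len(p) <= max_len:
            fitted.append(p)
        else:
            mid = (p.start + p.end) // 2
            s = max(0, mid - max_len // 2)
            fitted.append(GenomicInterval(p.chrom, s, s + max_len))
    return mc_enrichment_z(fitted, mirs, mirs, n=n, seed=seed, name=name)


def cumulative_binding(
    dbp_bound: dict[str, set], order: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Unique entities bound by up to N DBPs (cumulative union curve).

    Default order: DBPs by descending per-DBP bound count."""
    if order is None:
        order = sorted(dbp_bound, key=lambda d: (-len(dbp_bound[d]), d))
    seen: set = set()
    rows = []
    for i, d in enumerate(order, start=1):
        seen |= dbp_bound[d]
        rows.append({"n_dbps": i, "dbp": d, "cumulative_bound": len(seen)})
    return pd.DataFrame(rows)
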