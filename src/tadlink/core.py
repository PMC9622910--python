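"""Genomic interval data model and TAD partition construction.

Coordinates are 0-based half-open throughout ([start, end)).  BED input is
consumed unchanged; GTF coordinates (1-based inclusive) are converted on read.
Topologically associating domains (TADs) enter as called domains; overlapping
and book-ended domains are merged into single TADs and the complement of the
merged set against each declared chromosome is added back as TADs, so the
final partition is a disjoint, exhaustive cover of every chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

PROXIMAL_BP = 2_000
LONG_BP = 500_000

REPEAT_FAMILIES = ("MIR", "Alu", "L1", "other")


class CoordinateError(ValueError):
    """An interval falls outside its declared chromosome (or off an undeclared one)."""


class UndefinedDistanceError(ValueError):
    """Distance requested between features on different chromosomes."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RepeatElement:
    """One RepeatMasker-style repeat copy.

    ``divergence`` is the element's percent substitutions + insertions +
    deletions relative to the family consensus, a proxy for element age.
    """

    element_id: str
    family: str
    subfamily: str
    interval: GenomicInterval
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in REPEAT_FAMILIES:
            raise ValueError(f"unknown repeat family {self.family!r}")
        if self.divergence < 0:
            raise ValueError("divergence score must be >= 0")


@dataclass(frozen=True)
class GeneModel:
    """A gene as the union of its exons; introns are the gaps between
    merged exons, and the gene body is the contiguous span of both."""

    gene_id: str
    symbol: str
    biotype: str  # 'protein_coding' | 'non_coding'
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    introns: tuple[GenomicInterval, ...] = field(init=False)
    body: GenomicInterval = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        if any(e.chrom != self.chrom for e in self.exons):
            raise ValueError(f"gene {self.gene_id}: exons on multiple chromosomes")
        merged = merge_intervals(self.exons)
        introns = tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(merged, merged[1:])
            if b.start > a.end
        )
        object.__setattr__(self, "exons", tuple(merged))
        object.__setattr__(self, "introns", introns)
        object.__setattr__(
            self,
            "body",
            GenomicInterval(self.chrom, merged[0].start, merged[-1].end, self.strand),
        )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def intronic_length(self) -> int:
        return sum(len(i) for i in self.introns)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and book-ended intervals, per chromosome.

    Strand is dropped: merged intervals are unstranded.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def complement_intervals(
    merged: Sequence[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> list[GenomicInterval]:
    """Gaps between ``merged`` intervals and the chromosome bounds [0, size)."""
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_sizes}
    for iv in merged:
        by_chrom[iv.chrom].append(iv)
    for chrom, size in chrom_sizes.items():
        pos = 0
        for iv in sorted(by_chrom[chrom], key=lambda x: x.start):
            if iv.start > pos:
                out.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < size:
            out.append(GenomicInterval(chrom, pos, size))
    return out


@dataclass
class TadPartition:
    """Disjoint, exhaustive TAD cover of each declared chromosome.

    ``origins[i]`` is 'called-domain' for TADs arising from (merged) Hi-C
    domain calls and 'complement' for the gap-filling TADs.
    """

    chrom_sizes: dict[str, int]
    intervals: list[GenomicInterval]
    tad_ids: list[str]
    origins: list[str]
    # per-chromosome index: sorted starts/ends + row indices, for overlap queries
    _index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self._index = {}
        for chrom in self.chrom_sizes:
            rows = np.array(
                [i for i, iv in enumerate(self.intervals) if iv.chrom == chrom],
                dtype=int,
            )
            starts = np.array([self.intervals[i].start for i in rows])
            ends = np.array([self.intervals[i].end for i in rows])
            order = np.argsort(starts)
            self._index[chrom] = (starts[order], ends[order], rows[order])

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def n_tads(self) -> int:
        return len(self.intervals)

    def boundaries(self, chrom: str) -> np.ndarray:
        """All partition edges on a chromosome (including 0 and the length)."""
        starts, ends, _ = self._index[chrom]
        return np.unique(np.concatenate([starts, ends]))

    def overlapping(self, interval: GenomicInterval) -> list[str]:
        """TAD ids overlapping ``interval`` by >= 1 bp, in genomic order."""
        if interval.chrom not in self._index:
            raise CoordinateError(
                f"feature {interval.chrom}:{interval.start}-{interval.end} "
                "is on an undeclared chromosome"
            )
        starts, ends, rows = self._index[interval.chrom]
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        hi = int(np.searchsorted(starts, interval.end, side="left"))
        return [self.tad_ids[rows[i]] for i in range(lo, hi)]

    def validate(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            starts, ends, _ = self._index[chrom]
            if len(starts) == 0:
                raise ValueError(f"chromosome {chrom} not covered")
            if starts[0] != 0 or ends[-1] != size:
                raise ValueError(f"partition does not span [0, {size}) on {chrom}")
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"partition not disjoint/exhaustive on {chrom}")


def build_tad_partition(
    domains: Iterable[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> TadPartition:
    """Merge called domains and complement against chromosome bounds.

    Overlapping (and book-ended) called domains become a single TAD; the
    uncovered remainder of each chromosome is also split into TADs.
    """
    domains = list(domains)
    for d in domains:
        if d.chrom not in chrom_sizes:
            raise CoordinateError(
                f"domain {d.chrom}:{d.start}-{d.end} on undeclared chromosome"
            )
        if d.end > chrom_sizes[d.chrom]:
            raise CoordinateError(
                f"domain {d.chrom}:{d.start}-{d.end} exceeds chromosome "
                f"length {chrom_sizes[d.chrom]}"
            )
    merged = merge_intervals(domains)
    gaps = complement_intervals(merged, chrom_sizes)
    tagged = [(iv, "called-domain") for iv in merged] + [
        (iv, "complement") for iv in gaps
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start))
    intervals = [iv for iv, _ in tagged]
    origins = [o for _, o in tagged]
    tad_ids = [f"tad_{iv.chrom}_{i}" for i, iv in enumerate(intervals)]
    part = TadPartition(dict(chrom_sizes), intervals, tad_ids, origins)
    part.validate()
    return part


def assign_to_tads(
    features: Mapping[str, GenomicInterval], partition: TadPartition
) -> dict[str, set[str]]:
    """Map each feature to every TAD it overlaps by >= 1 bp."""
    return {name: set(partition.overlapping(iv)) for name, iv in features.items()}


def gene_site_distance(gene: GeneModel, chrom: str, position: int) -> int:
    """Distance (bp) from a 1-bp site to the gene body; 0 if inside it."""
    if chrom != gene.chrom:
        raise UndefinedDistanceError(
            f"site on {chrom} vs gene {gene.gene_id} on {gene.chrom}"
        )
    s, e = gene.body.start, gene.body.end
    if s <= position < e:
        return 0
    return s - position if position < s else position - e


def classify_distance(d: int, within_body: bool = False) -> str:
    """Distance bin: proximal (<=2 kb or within the gene body),
    intermediate (>2 kb and <=500 kb) or long (>500 kb)."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    if within_body or d <= PROXIMAL_BP:
        return "proximal"
    if d <= LONG_BP:
        return "intermediate"
    return "long"


class StepTrack:
    """Piecewise-constant per-base score track (bedGraph semantics).

    Bases not covered by any step have no value and are excluded from
    summaries (missing-aware medians/means).
    """

    def __init__(self, segments: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # per chrom: (starts, ends, values), starts sorted, non-overlapping
        self._seg = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts)
            self._seg[chrom] = (starts[order], ends[order], values[order])

    @property
    def chroms(self) -> list[str]:
        return list(self._seg)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._seg[chrom]

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Track value at each position; NaN where uncovered."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, np.nan)
        if chrom not in self._seg:
            return out
        starts, ends, values = self._seg[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        out[ok] = values[idx[ok]]
        return out

    def _pieces(self, intervals: Sequence[GenomicInterval]):
        """(value, n_bases) pieces covering the intervals, plus total bases."""
        vals, weights, total = [], [], 0
        for iv in intervals:
            total += len(iv)
            if iv.chrom not in self._seg:
                continue
            starts, ends, values = self._seg[iv.chrom]
            lo = int(np.searchsorted(ends, iv.start, side="right"))
            hi = int(np.searchsorted(starts, iv.end, side="left"))
            for i in range(lo, hi):
                ov = min(ends[i], iv.end) - max(starts[i], iv.start)
                if ov > 0:
                    vals.append(values[i])
                    weights.append(ov)
        return np.array(vals), np.array(weights, dtype=float), total

    def mean_over(self, intervals: Sequence[GenomicInterval]) -> float:
        vals, w, _ = self._pieces(intervals)
        if len(vals) == 0:
            return float("nan")
        return float(np.average(vals, weights=w))

    def median_over(self, intervals: Sequence[GenomicInterval]) -> float:
        """Weighted (per-base) median over covered bases only."""
        vals, w, _ = self._pieces(intervals)
        if len(vals) == 0:
            return float("nan")
        order = np.argsort(vals)
        vals, w = vals[order], w[order]
        cum = np.cumsum(w)
        half = cum[-1] / 2.0
        i = int(np.searchsorted(cum, half))
        if cum[i] == half and i + 1 < len(vals):
            return float((vals[i] + vals[i + 1]) / 2.0)
        return float(vals[min(i, len(vals) - 1)])

    def coverage_fraction(self, intervals: Sequence[GenomicInterval]) -> float:
        vals, w, total = self._pieces(intervals)
        return float(w.sum() / total) if total else float("nan")


def overlap_bases(
    intervals: Sequence[GenomicInterval], others: Sequence[GenomicInterval]
) -> int:
    """Total bases of ``intervals`` covered by the merged union of ``others``."""
    merged = merge_intervals(others) if others else []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    total = 0
    for iv in intervals:
        for m in by_chrom.get(iv.chrom, ()):
            ov = min(iv.end, m.end) - max(iv.start, m.start)
            if ov > 0:
                total += ov
    return total
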