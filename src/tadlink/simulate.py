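"""Synthetic genomes and cohorts with planted regulatory structure.

The generator emulates the study design this package analyses: a genome
partitioned into TADs (mean size 1.4 Mb), genes of two architecture classes
("regulatable" genes with GC-rich, weakly conserved, MIR-dense introns vs
"independent" genes), RepeatMasker-like MIR/Alu/L1 annotations, CpG sites
(a fraction on MIR elements and enhancers), conservation and GC tracks,
ChIP-seq-like peak sets for a roster of DNA-binding proteins, and a PPI
edge list.

Cohorts plant gene-mCpG couplings through a per-TAD latent methylation
factor: designated driver sites in a TAD share the latent factor (drawn per
genotype group: DNMT3A-mutant low, IDH-mutant high, double-mutant
intermediate, wild-type mid-range with wider dispersion) and planted genes
read it through log-expression = alpha + beta * m + noise.  Every planted
(gene, driver-site) pair shares a TAD by construction and is recorded in the
ground truth for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    GenomicInterval,
    RepeatElement,
    StepTrack,
    TadPartition,
    build_tad_partition,
    merge_intervals,
)
from .errors import CapacityError, DesignError
from .tables import ExpressionMatrix, MethylationTable

DEFAULT_DBPS = (
    "RUNX1",
    "FLI1",
    "GATA2",
    "TAL1",
    "THRA",
    "MEF2A",
    "BCOR",
    "PTBP1",
    "SMARCA5",
    "EP300",
    "HDAC1",
    "ESRRA",
)

CELL_TYPES_15 = (
    "HSC",
    "MPP",
    "CMP",
    "GMP",
    "MEP",
    "Mono",
    "Gran",
    "Eosin",
    "Baso",
    "Mega",
    "Ery",
    "B",
    "T",
    "NK",
    "NKT",
)

BBOX = "GTTCNANNC"


@dataclass(frozen=True)
class GenomeConfig:
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    tad_mean_bp: float = 1_400_000.0
    tad_gap_prob: float = 0.15  # chance of an unclaimed (complement) gap between domains
    tad_gap_bp: int = 60_000
    n_genes: int = 200
    regulatable_fraction: float = 0.4
    noncoding_fraction: float = 0.1
    n_cpg_sites: int = 2000
    n_cpg_islands: int = 40
    island_site_fraction: float = 0.05
    n_enhancers: int = 120
    enhancer_mir_fraction: float = 0.4
    cpg_on_mir_fraction: float = 0.15
    cpg_on_enhancer_fraction: float = 0.10
    mir_density_regulatable: float = 0.15
    mir_density_independent: float = 0.03
    mir_zero_fraction: float = 0.4  # independent genes with no intronic MIR at all
    alu_density: float = 0.08
    n_intergenic_mir: int = 300
    n_intergenic_alu: int = 300
    n_intergenic_l1: int = 60
    mir_bbox_fraction: float = 0.3
    dbp_names: tuple = DEFAULT_DBPS
    peaks_per_dbp: int = 300
    peak_len_range: tuple = (200, 600)
    track_window_bp: int = 200
    track_gap_fraction: float = 0.02


@dataclass(frozen=True)
class CohortDesign:
    """Two-cohort AML-like design.  Default group sizes follow a
    16/9/11 DNMT3A / IDH / double-mutant layout (36 samples)."""

    group_sizes: dict = field(
        default_factory=lambda: {"DNMT3A": 16, "IDH": 9, "DOUBLE": 11}
    )
    planted_pair_fraction: float = 0.10
    planted_gene_fraction: float = 1.0 / 3.0
    beta: float = 3.0  # log2-expression change per unit methylation (|rho| ~ 0.8)
    noise_sd: float = 0.6
    positive_fraction: float = 0.015  # planted pairs with positive coupling
    site_noise_sd: float = 0.05
    meth_params: dict = field(
        default_factory=lambda: {
            "DNMT3A": (2.0, 8.0),
            "IDH": (8.0, 2.0),
            "DOUBLE": (5.0, 5.0),
            "WT": (2.5, 2.5),  # Beta(5,5) mean with doubled dispersion
        }
    )
    wt_null: bool = True  # wild-type expression is decoupled from methylation
    bridged_tad_fraction: float = 0.7
    mir_enh_driver_fraction: float = 0.1
    driver_mir_fraction: float = 0.25  # drivers preferentially on MIR elements
    driver_enhancer_fraction: float = 0.25  # ... and on enhancers
    coverage_mean: float = 40.0
    coverage_floor: int = 10
    dropout_fraction: float = 0.02
    probe_level: bool = False


@dataclass(frozen=True)
class SeriesConfig:
    """Differentiation-series design: 15 cell types, 211 samples by default."""

    cell_types: tuple = CELL_TYPES_15
    samples_per_type: Optional[tuple] = None  # default: 15 + 14*14 = 211
    de_fraction: float = 0.10
    effect_mean: float = 1.5
    effect_sd: float = 0.3
    noise_sd: float = 0.4
    regulatable_odds: float = 4.0  # odds ratio for upregulated genes being regulatable


@dataclass
class SyntheticGenome:
    config: GenomeConfig
    seed: int
    chrom_sizes: dict
    partition: TadPartition
    genes: list
    gene_classes: pd.Series  # gene_id -> 'regulatable' | 'independent'
    repeats: list
    cpg_sites: pd.DataFrame  # index site_id; chrom, pos, on_mir, on_enhancer, on_island, mir_enh_host
    cpg_islands: list
    enhancers: list
    conservation: StepTrack
    gc: StepTrack
    dbp_peaks: dict
    dbp_targets: dict  # dbp -> set of target gene ids (planted)
    bridge_pairs: list  # [(site_binder, mir_binder), ...]
    ppi_edges: list
    repeat_sequences: dict  # element_id -> str

    @property
    def genes_by_id(self) -> dict:
        return {g.gene_id: g for g in self.genes}

    def intronic_mirs(self, gene: GeneModel) -> list[RepeatElement]:
        out = []
        for r in self.repeats:
            if r.family != "MIR" or r.interval.chrom != gene.chrom:
                continue
            for intron in gene.introns:
                if r.interval.overlaps(intron):
                    out.append(r)
                    break
        return out


@dataclass
class GroundTruth:
    planted_pairs: pd.DataFrame  # gene_id, site_id, beta, sign, tad_id, bridged
    regulated_genes: set
    driver_sites: set
    dbp_targets: dict
    bridge_pairs: list
    bridged_tads: set


@dataclass
class SyntheticCohort:
    methylation: MethylationTable
    expression: ExpressionMatrix
    groups: pd.Series


@dataclass
class SeriesResult:
    expression: ExpressionMatrix  # cell-type labelled samples
    profiles: pd.DataFrame  # gene x cell-type mean log2 profile
    de_sets: dict  # cell type -> {'up': set, 'down': set} vs the root type


# ---------------------------------------------------------------------------
# genome generation


def _draw_domains(cfg: GenomeConfig, rng) -> list[GenomicInterval]:
    domains = []
    for chrom, size in cfg.chrom_sizes.items():
        pos = 0
        while pos < size - 200_000:
            length = max(200_000, int(rng.gamma(4.0, cfg.tad_mean_bp / 4.0)))
            end = min(pos + length, size)
            domains.append(GenomicInterval(chrom, pos, end))
            # boundary gap keeps adjacent called domains from book-ending
            pos = end + int(rng.integers(2_000, 10_000))
            if rng.random() < cfg.tad_gap_prob:
                pos += int(rng.integers(10_000, cfg.tad_gap_bp))
    return domains


def _place_nonoverlapping(
    segment: GenomicInterval, lengths: Sequence[int], rng
) -> list[GenomicInterval]:
    """Place the given lengths inside ``segment`` without overlap, positions
    uniform via Dirichlet gap splitting.  Drops lengths that no longer fit."""
    lengths = [int(l) for l in lengths if l > 0]
    total = sum(lengths)
    free = len(segment) - total
    while free < 0 and lengths:
        lengths.pop()
        total = sum(lengths)
        free = len(segment) - total
    if not lengths:
        return []
    k = len(lengths)
    gaps = rng.dirichlet(np.ones(k + 1)) * free
    out, pos = [], segment.start
    for i, l in enumerate(lengths):
        pos += int(gaps[i])
        out.append(GenomicInterval(segment.chrom, pos, pos + l))
        pos += l
    return out


def _make_genes(cfg: GenomeConfig, partition: TadPartition, rng):
    exp_len = 20_000
    genome_bp = sum(cfg.chrom_sizes.values())
    if cfg.n_genes * exp_len > 0.7 * genome_bp:
        raise CapacityError(
            f"{cfg.n_genes} genes (~{cfg.n_genes * exp_len:,} bp) do not fit a "
            f"{genome_bp:,} bp genome"
        )
    tads = [
        iv
        for iv, origin in zip(partition.intervals, partition.origins)
        if origin == "called-domain"
    ]
    weights = np.array([len(t) for t in tads], dtype=float)
    weights /= weights.sum()
    occupied: dict[int, list] = {i: [] for i in range(len(tads))}
    genes, classes = [], {}
    n_reg = int(round(cfg.n_genes * cfg.regulatable_fraction))
    for gi in range(cfg.n_genes):
        length = int(np.clip(rng.lognormal(np.log(15_000), 0.6), 3_000, 150_000))
        placed = None
        for _ in range(40):
            ti = int(rng.choice(len(tads), p=weights))
            tad = tads[ti]
            if len(tad) < length + 2_000:
                continue
            start = int(rng.integers(tad.start, tad.end - length))
            end = start + length
            ok = all(not (start < oe and os_ < end) for os_, oe in occupied[ti])
            if ok:
                occupied[ti].append((start, end))
                placed = (tad.chrom, start, end)
                break
        if placed is None:
            raise CapacityError(f"could not place gene {gi} after 40 attempts")
        chrom, start, end = placed
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = 1 if rng.random() < 0.05 else int(rng.integers(2, 12))
        exon_lens = rng.integers(100, 301, size=n_exons)
        while exon_lens.sum() > 0.5 * length and n_exons > 1:
            n_exons -= 1
            exon_lens = exon_lens[:n_exons]
        intron_total = length - int(exon_lens.sum())
        if n_exons == 1:
            exons = [GenomicInterval(chrom, start, end, strand)]
        else:
            gaps = rng.dirichlet(np.ones(n_exons - 1)) * intron_total
            gaps = np.maximum(1, gaps.astype(int))
            exons, pos = [], start
            for i in range(n_exons):
                el = int(exon_lens[i])
                if i == n_exons - 1:
                    exons.append(GenomicInterval(chrom, pos, end, strand))
                else:
                    exons.append(GenomicInterval(chrom, pos, pos + el, strand))
                    pos += el + int(gaps[i])
            if exons[-1].start <= exons[-2].end:
                exons = exons[:-1]
                last = exons.pop()
                exons.append(GenomicInterval(chrom, last.start, end, strand))
        gene_id = f"gene_{gi:04d}"
        biotype = (
            "non_coding" if rng.random() < cfg.noncoding_fraction else "protein_coding"
        )
        genes.append(
            GeneModel(gene_id, gene_id.upper(), biotype, chrom, strand, tuple(exons))
        )
        classes[gene_id] = "regulatable" if gi < n_reg else "independent"
    return genes, pd.Series(classes, name="class")


def _make_repeats(cfg: GenomeConfig, genes, classes, rng) -> list[RepeatElement]:
    repeats = []
    counter = 0
    mir_subfams = ("MIRb", "MIRc", "MIR3")
    for g in genes:
        if classes[g.gene_id] == "regulatable":
            dens = cfg.mir_density_regulatable
        elif rng.random() < cfg.mir_zero_fraction:
            dens = 0.0  # MIR-zero gene
        else:
            dens = cfg.mir_density_independent
        dens = max(0.0, rng.normal(dens, dens * 0.25)) if dens else 0.0
        for intron in g.introns:
            mir_bp = dens * len(intron)
            n_mir = int(mir_bp / 195.0 + rng.random())
            n_alu = int(cfg.alu_density * len(intron) / 300.0 + rng.random())
            lens = [int(rng.integers(130, 261)) for _ in range(n_mir)] + [
                300
            ] * n_alu
            fams = ["MIR"] * n_mir + ["Alu"] * n_alu
            order = rng.permutation(len(lens))
            placed = _place_nonoverlapping(
                intron, [lens[i] for i in order], rng
            )
            for iv, oi in zip(placed, order):
                fam = fams[oi]
                counter += 1
                div = max(
                    0.0,
                    rng.normal(32.0, 6.0) if fam == "MIR" else rng.normal(14.0, 6.0),
                )
                sub = (
                    str(rng.choice(mir_subfams)) if fam == "MIR" else "AluSx"
                )
                repeats.append(
                    RepeatElement(f"rep_{counter:05d}", fam, sub, iv, div)
                )
    # intergenic elements
    gene_union = merge_intervals([g.body for g in genes])
    by_chrom: dict[str, list] = {c: [] for c in cfg.chrom_sizes}
    for iv in gene_union:
        by_chrom[iv.chrom].append(iv)
    inter: list[GenomicInterval] = []
    for chrom, size in cfg.chrom_sizes.items():
        pos = 0
        for iv in sorted(by_chrom[chrom], key=lambda x: x.start):
            if iv.start - pos > 10_000:
                inter.append(GenomicInterval(chrom, pos, iv.start))
            pos = iv.end
        if size - pos > 10_000:
            inter.append(GenomicInterval(chrom, pos, size))
    iweights = np.array([len(iv) for iv in inter], dtype=float)
    iweights /= iweights.sum()
    fam_counts = (
        [("MIR", cfg.n_intergenic_mir)]
        + [("Alu", cfg.n_intergenic_alu)]
        + [("L1", cfg.n_intergenic_l1)]
    )
    for fam, n in fam_counts:
        for _ in range(n):
            seg = inter[int(rng.choice(len(inter), p=iweights))]
            if fam == "MIR":
                l, sub, div = int(rng.integers(130, 261)), str(rng.choice(mir_subfams)), max(0.0, rng.normal(32, 6))
            elif fam == "Alu":
                l, sub, div = 300, "AluSx", max(0.0, rng.normal(14, 6))
            else:
                l, sub, div = int(rng.integers(500, 6001)), "L1M", max(0.0, rng.normal(22, 8))
            if len(seg) <= l + 2:
                continue
            start = int(rng.integers(seg.start, seg.end - l))
            counter += 1
            repeats.append(
                RepeatElement(
                    f"rep_{counter:05d}", fam, sub, GenomicInterval(seg.chrom, start, start + l), div
                )
            )
    return repeats


def _make_tracks(cfg: GenomeConfig, genes, classes, rng):
    w = cfg.track_window_bp
    cons_seg, gc_seg = {}, {}
    for chrom, size in cfg.chrom_sizes.items():
        n_win = size // w
        starts = np.arange(n_win, dtype=np.int64) * w
        cons = rng.normal(0.5, 0.4, size=n_win)
        gc = rng.normal(0.41, 0.02, size=n_win)
        for g in genes:
            if g.chrom != chrom:
                continue
            reg = classes[g.gene_id] == "regulatable"
            for ex in g.exons:
                lo, hi = ex.start // w, max(ex.start // w + 1, ex.end // w)
                cons[lo:hi] += 1.5
            for intr in g.introns:
                lo, hi = intr.start // w, max(intr.start // w + 1, intr.end // w)
                if reg:
                    cons[lo:hi] = rng.normal(0.15, 0.15, size=hi - lo)
                    gc[lo:hi] = rng.normal(0.55, 0.02, size=hi - lo)
                else:
                    cons[lo:hi] = rng.normal(0.8, 0.2, size=hi - lo)
                    gc[lo:hi] = rng.normal(0.44, 0.02, size=hi - lo)
        keep = rng.random(n_win) > cfg.track_gap_fraction
        ends = starts + w
        cons_seg[chrom] = (starts[keep], ends[keep], cons[keep])
        gc_seg[chrom] = (starts[keep], ends[keep], np.clip(gc[keep], 0.2, 0.8))
    return StepTrack(cons_seg), StepTrack(gc_seg)


def _random_positions_in(intervals, n, rng) -> list[tuple[str, int]]:
    if not intervals or n <= 0:
        return []
    weights = np.array([len(iv) for iv in intervals], dtype=float)
    weights /= weights.sum()
    out = []
    for _ in range(n):
        iv = intervals[int(rng.choice(len(intervals), p=weights))]
        out.append((iv.chrom, int(rng.integers(iv.start, iv.end))))
    return out


def _random_dna(n: int, rng) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _reverse_complement(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp.get(b, "N") for b in reversed(seq))


def generate_genome(config: GenomeConfig = GenomeConfig(), seed: int = 0) -> SyntheticGenome:
    """Deterministic synthetic genome for a fixed (config, seed)."""
    rng = np.random.default_rng(seed)
    domains = _draw_domains(config, rng)
    partition = build_tad_partition(domains, config.chrom_sizes)
    genes, classes = _make_genes(config, partition, rng)
    repeats = _make_repeats(config, genes, classes, rng)
    conservation, gc = _make_tracks(config, genes, classes, rng)
    genes_by_id = {g.gene_id: g for g in genes}

    # enhancers: a fraction sits exactly over intronic MIRs of regulatable genes
    reg_gene_ids = [g for g in classes.index if classes[g] == "regulatable"]
    intronic_mirs: list[tuple[str, RepeatElement]] = []
    for gid in reg_gene_ids:
        g = genes_by_id[gid]
        for r in repeats:
            if r.family != "MIR" or r.interval.chrom != g.chrom:
                continue
            if any(r.interval.overlaps(i) for i in g.introns):
                intronic_mirs.append((gid, r))
    n_mir_enh = int(round(config.n_enhancers * config.enhancer_mir_fraction))
    rng.shuffle(intronic_mirs)
    enhancers, mir_enh_hosts = [], {}
    for gid, r in intronic_mirs[:n_mir_enh]:
        iv = GenomicInterval(
            r.interval.chrom,
            max(0, r.interval.start - 100),
            min(config.chrom_sizes[r.interval.chrom], r.interval.end + 100),
        )
        enhancers.append(iv)
        mir_enh_hosts[iv] = gid
    genome_ivs = [GenomicInterval(c, 0, s) for c, s in config.chrom_sizes.items()]
    for chrom, pos in _random_positions_in(
        genome_ivs, config.n_enhancers - len(enhancers), rng
    ):
        l = int(rng.integers(500, 2001))
        end = min(pos + l, config.chrom_sizes[chrom])
        if end - pos >= 200:
            enhancers.append(GenomicInterval(chrom, pos, end))

    # CpG islands near gene starts
    islands = []
    for g in rng.choice(genes, size=min(config.n_cpg_islands, len(genes)), replace=False):
        s = max(0, g.body.start - 500)
        islands.append(
            GenomicInterval(g.chrom, s, min(config.chrom_sizes[g.chrom], s + 1_000))
        )

    # CpG sites
    n = config.n_cpg_sites
    mir_ivs = [r.interval for r in repeats if r.family == "MIR"]
    mir_enh_ivs = list(mir_enh_hosts)
    n_mir = int(n * config.cpg_on_mir_fraction)
    n_enh = int(n * config.cpg_on_enhancer_fraction)
    n_isl = int(n * config.island_site_fraction)
    positions: list[tuple[str, int]] = []
    positions += _random_positions_in(mir_enh_ivs, min(n_mir, 2 * len(mir_enh_ivs)), rng)
    positions += _random_positions_in(mir_ivs, n_mir - len(positions), rng)
    positions += _random_positions_in(enhancers, n_enh, rng)
    positions += _random_positions_in(islands, n_isl, rng)
    positions += _random_positions_in(genome_ivs, n - len(positions), rng)
    seen, uniq = set(), []
    for chrom, pos in positions:
        if (chrom, pos) not in seen:
            seen.add((chrom, pos))
            uniq.append((chrom, pos))
    while len(uniq) < n:
        for chrom, pos in _random_positions_in(genome_ivs, n - len(uniq), rng):
            if (chrom, pos) not in seen:
                seen.add((chrom, pos))
                uniq.append((chrom, pos))
    uniq.sort()
    sites = pd.DataFrame(uniq, columns=["chrom", "pos"])
    sites.index = [f"cpg_{i:05d}" for i in range(len(sites))]

    def _flag(intervals) -> np.ndarray:
        flags = np.zeros(len(sites), dtype=bool)
        by_chrom: dict[str, list] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda x: x.start)
            starts = np.array([iv.start for iv in ivs])
            ends_cummax = np.maximum.accumulate(np.array([iv.end for iv in ivs]))
            m = sites["chrom"].to_numpy() == chrom
            pos = sites.loc[m, "pos"].to_numpy()
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends_cummax[np.clip(idx, 0, None)])
            flags[np.where(m)[0][ok]] = True
        return flags

    sites["on_mir"] = _flag(mir_ivs)
    sites["on_enhancer"] = _flag(enhancers)
    sites["on_island"] = _flag(islands)
    sites["on_mir_enh"] = _flag(mir_enh_ivs)
    host = pd.Series("", index=sites.index, dtype=object)
    for iv, gid in mir_enh_hosts.items():
        m = (
            (sites["chrom"] == iv.chrom)
            & (sites["pos"] >= iv.start)
            & (sites["pos"] < iv.end)
        )
        host[m] = gid
    sites["mir_enh_host"] = host

    # DBP peaks
    gene_union = merge_intervals([g.body for g in genes])
    dbp_peaks: dict[str, list] = {}
    dbp_targets: dict[str, set] = {}
    bridge_pairs = [("THRA", "MEF2A"), ("BCOR", "PTBP1")]
    site_binders = {"THRA", "BCOR"}
    mir_binders = {"MEF2A", "PTBP1"}
    target_dbps = {"RUNX1": 0.8, "FLI1": 0.8}
    lo, hi = config.peak_len_range
    all_mir_enh_sites = sites[sites["on_mir_enh"]]
    reg_mirs = [r.interval for _, r in intronic_mirs]
    for name in config.dbp_names:
        peaks = []
        n_p = config.peaks_per_dbp
        if name in target_dbps:
            targets = set(
                rng.choice(reg_gene_ids, size=max(1, len(reg_gene_ids) // 2), replace=False)
            )
            dbp_targets[name] = targets
            tgt_bodies = [genes_by_id[t].body for t in targets]
            n_tgt = int(n_p * target_dbps[name])
            for chrom, pos in _random_positions_in(tgt_bodies, n_tgt, rng):
                l = int(rng.integers(lo, hi))
                peaks.append(_clipped(chrom, pos - l // 2, l, config.chrom_sizes))
            n_p -= n_tgt
        if name in site_binders and len(all_mir_enh_sites):
            n_cov = int(0.85 * len(all_mir_enh_sites))
            chosen = all_mir_enh_sites.sample(n=n_cov, random_state=int(rng.integers(2**31)))
            for _, row in chosen.iterrows():
                l = int(rng.integers(lo, hi))
                peaks.append(_clipped(row["chrom"], int(row["pos"]) - l // 2, l, config.chrom_sizes))
            n_p = max(0, n_p - n_cov)
        if name in mir_binders and mir_enh_ivs:
            # bridged structure: bind the enhancer-MIRs, i.e. the intronic
            # MIRs of the genes hosting MIR-enhancer driver sites
            n_cov = int(0.9 * len(mir_enh_ivs))
            chosen = rng.choice(len(mir_enh_ivs), size=n_cov, replace=False)
            for i in chosen:
                iv = mir_enh_ivs[i]
                l = int(rng.integers(lo, hi))
                mid = (iv.start + iv.end) // 2
                peaks.append(_clipped(iv.chrom, mid - l // 2, l, config.chrom_sizes))
            n_p = max(0, n_p - n_cov)
        if name in site_binders or name in mir_binders:
            # bridging DBPs are specific: modest background binding only
            n_p = min(n_p, config.peaks_per_dbp // 6)
        for chrom, pos in _random_positions_in(gene_union, n_p, rng):
            l = int(rng.integers(lo, hi))
            peaks.append(_clipped(chrom, pos - l // 2, l, config.chrom_sizes))
        dbp_peaks[name] = peaks

    # PPI edges: planted bridges plus random pairs
    ppi = list(bridge_pairs)
    names = list(config.dbp_names)
    attempts = 0
    while len(ppi) < 14 and attempts < 500:
        attempts += 1
        a, b = rng.choice(names, size=2, replace=False)
        if (a, b) not in ppi and (b, a) not in ppi and not (
            (a in site_binders and b in mir_binders)
            or (b in site_binders and a in mir_binders)
        ):
            ppi.append((str(a), str(b)))

    # sequences under repeat footprints (B-box scanning)
    seqs = {}
    for r in repeats:
        seq = _random_dna(len(r.interval), rng)
        seq = seq.replace("GTTC", "GTAC")  # scrub chance sense B-box cores
        seq = seq.replace("GAAC", "GTAC")  # and antisense cores
        if r.family == "MIR" and rng.random() < config.mir_bbox_fraction:
            motif = "".join(
                b if b != "N" else "ACGT"[rng.integers(0, 4)] for b in BBOX
            )
            if rng.random() < 0.5:
                motif = _reverse_complement(motif)
            i = int(rng.integers(0, len(seq) - len(motif) + 1))
            seq = seq[:i] + motif + seq[i + len(motif):]
        seqs[r.element_id] = seq

    return SyntheticGenome(
        config=config,
        seed=seed,
        chrom_sizes=dict(config.chrom_sizes),
        partition=partition,
        genes=genes,
        gene_classes=classes,
        repeats=repeats,
        cpg_sites=sites,
        cpg_islands=islands,
        enhancers=enhancers,
        conservation=conservation,
        gc=gc,
        dbp_peaks=dbp_peaks,
        dbp_targets=dbp_targets,
        bridge_pairs=bridge_pairs,
        ppi_edges=ppi,
        repeat_sequences=seqs,
    )


def _clipped(chrom: str, start: int, length: int, chrom_sizes) -> GenomicInterval:
    start = max(0, start)
    end = min(chrom_sizes[chrom], start + length)
    return GenomicInterval(chrom, start, max(end, start + 1))


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    genome: SyntheticGenome, design: CohortDesign = CohortDesign(), seed: int = 0
) -> tuple[SyntheticCohort, GroundTruth]:
    """Plant gene-mCpG couplings through per-TAD latent methylation factors."""
    rng = np.random.default_rng(seed)
    sites = genome.cpg_sites
    part = genome.partition

    samples, groups = [], []
    for grp, k in design.group_sizes.items():
        for i in range(k):
            samples.append(f"{grp}_{i:02d}")
            groups.append(grp)
    groups = pd.Series(groups, index=samples, name="group")
    n_samp = len(samples)
    if n_samp < 3:
        raise DesignError("need >= 3 samples")

    # TAD membership
    gene_tads = {g.gene_id: part.overlapping(g.body) for g in genome.genes}
    site_tads = {
        sid: part.overlapping(GenomicInterval(row["chrom"], row["pos"], row["pos"] + 1))
        for sid, row in sites.iterrows()
    }
    tad_genes: dict[str, list] = {}
    tad_sites: dict[str, list] = {}
    for gid, tids in gene_tads.items():
        for t in tids:
            tad_genes.setdefault(t, []).append(gid)
    for sid, tids in site_tads.items():
        for t in tids:
            tad_sites.setdefault(t, []).append(sid)
    shared_tads = [t for t in tad_genes if t in tad_sites]
    total_pairs = sum(len(tad_genes[t]) * len(tad_sites[t]) for t in shared_tads)
    if design.planted_pair_fraction > 0:
        site_frac = design.planted_pair_fraction / design.planted_gene_fraction
        if site_frac > 1.0 or total_pairs == 0:
            raise DesignError(
                "planted-pair fraction exceeds the available within-TAD pairs"
            )
    else:
        site_frac = 0.0

    classes = genome.gene_classes
    bridged_candidates = [
        t
        for t in shared_tads
        if any(sites.loc[s, "mir_enh_host"] for s in tad_sites[t])
    ]
    n_bridged = int(round(design.bridged_tad_fraction * len(bridged_candidates)))
    bridged_tads = set(
        rng.choice(bridged_candidates, size=n_bridged, replace=False)
    ) if n_bridged else set()

    planted_rows = []
    driver_sites: dict[str, str] = {}  # site -> tad
    tad_drivers: dict[str, list] = {}
    tad_planted_genes: dict[str, list] = {}
    if design.planted_pair_fraction > 0:
        for t in shared_tads:
            gids, sids = tad_genes[t], tad_sites[t]
            n_pg = int(round(design.planted_gene_fraction * len(gids)))
            n_ds = int(round(site_frac * len(sids)))
            if n_pg == 0 or n_ds == 0:
                continue
            if t in bridged_tads:
                hosts = sorted(
                    {
                        sites.loc[s, "mir_enh_host"]
                        for s in sids
                        if sites.loc[s, "mir_enh_host"]
                    }
                )
                mir_enh = [s for s in sids if sites.loc[s, "mir_enh_host"]]
                chosen_sites = list(
                    rng.choice(mir_enh, size=min(n_ds, len(mir_enh)), replace=False)
                )
                rest = [s for s in sids if s not in set(chosen_sites)]
                if len(chosen_sites) < n_ds:
                    chosen_sites += list(
                        rng.choice(rest, size=n_ds - len(chosen_sites), replace=False)
                    )
                pref_genes = [g for g in hosts if g in set(gids)]
                others = [g for g in gids if g not in set(pref_genes)]
                chosen_genes = pref_genes[:n_pg]
                if len(chosen_genes) < n_pg:
                    chosen_genes += list(
                        rng.choice(others, size=n_pg - len(chosen_genes), replace=False)
                    )
            else:
                # drivers preferentially sit on MIR-enhancers, MIRs and enhancers
                chosen_sites: list = []
                for flag, frac in (
                    ("on_mir_enh", design.mir_enh_driver_fraction),
                    ("on_mir", design.driver_mir_fraction),
                    ("on_enhancer", design.driver_enhancer_fraction),
                ):
                    pool = [
                        s for s in sids
                        if sites.loc[s, flag] and s not in set(chosen_sites)
                    ]
                    want = min(int(round(frac * n_ds)), len(pool),
                               n_ds - len(chosen_sites))
                    if want > 0:
                        chosen_sites += list(rng.choice(pool, size=want, replace=False))
                rest = [s for s in sids if s not in set(chosen_sites)]
                chosen_sites += list(
                    rng.choice(rest, size=n_ds - len(chosen_sites), replace=False)
                )
                reg = [g for g in gids if classes[g] == "regulatable"]
                oth = [g for g in gids if classes[g] != "regulatable"]
                chosen_genes = list(rng.choice(reg, size=min(n_pg, len(reg)), replace=False))
                if len(chosen_genes) < n_pg:
                    chosen_genes += list(
                        rng.choice(oth, size=n_pg - len(chosen_genes), replace=False)
                    )
            tad_drivers[t] = chosen_sites
            tad_planted_genes[t] = chosen_genes
            for s in chosen_sites:
                driver_sites[s] = t

    # methylation matrix
    n_sites = len(sites)
    frac = np.empty((n_sites, n_samp))
    mu = rng.uniform(0.05, 0.95, size=n_sites)
    k = 10.0
    frac[:] = rng.beta(mu[:, None] * k, (1 - mu[:, None]) * k, size=(n_sites, n_samp))
    site_pos = {sid: i for i, sid in enumerate(sites.index)}

    latents: dict[str, np.ndarray] = {}
    grp_arr = groups.to_numpy()
    for t, drivers in tad_drivers.items():
        lat = np.empty(n_samp)
        for grp in design.group_sizes:
            a, b = design.meth_params[grp]
            m = grp_arr == grp
            lat[m] = rng.beta(a, b, size=m.sum())
        latents[t] = lat
        for s in drivers:
            frac[site_pos[s]] = np.clip(
                lat + rng.normal(0, design.site_noise_sd, size=n_samp), 0, 1
            )

    fractions = pd.DataFrame(frac, index=sites.index, columns=samples)

    coverage = None
    if not design.probe_level:
        cov = rng.poisson(
            design.coverage_mean - design.coverage_floor, size=(n_sites, n_samp)
        ) + design.coverage_floor
        n_drop = int(design.dropout_fraction * n_sites)
        if n_drop:
            drop_rows = rng.choice(n_sites, size=n_drop, replace=False)
            drop_cols = rng.integers(0, n_samp, size=n_drop)
            cov[drop_rows, drop_cols] = rng.integers(0, design.coverage_floor, size=n_drop)
        coverage = pd.DataFrame(cov, index=sites.index, columns=samples)

    # expression matrix
    gene_ids = [g.gene_id for g in genome.genes]
    base = rng.uniform(3.0, 8.0, size=len(gene_ids))
    logx = base[:, None] + rng.normal(0, design.noise_sd, size=(len(gene_ids), n_samp))
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    signs: dict[str, int] = {}
    wt_mask = grp_arr == "WT"
    for t, pgenes in tad_planted_genes.items():
        lat_c = latents[t] - latents[t].mean()
        for g in pgenes:
            sgn = 1 if rng.random() < design.positive_fraction else -1
            signs[g] = sgn
            effect = sgn * design.beta * lat_c
            if design.wt_null:
                effect = np.where(wt_mask, 0.0, effect)
            logx[gene_row[g]] += effect
            for s in tad_drivers[t]:
                planted_rows.append(
                    {
                        "gene_id": g,
                        "site_id": s,
                        "beta": sgn * design.beta,
                        "sign": sgn,
                        "tad_id": t,
                        "bridged": t in bridged_tads,
                    }
                )
    values = pd.DataFrame(2.0 ** logx, index=gene_ids, columns=samples)
    biotypes = pd.Series({g.gene_id: g.biotype for g in genome.genes})

    meth = MethylationTable(
        sites[["chrom", "pos"]].copy(), fractions, coverage, groups
    )
    expr = ExpressionMatrix(values, groups, biotypes)
    planted = pd.DataFrame(
        planted_rows,
        columns=["gene_id", "site_id", "beta", "sign", "tad_id", "bridged"],
    )
    truth = GroundTruth(
        planted_pairs=planted,
        regulated_genes=set(planted["gene_id"]) if len(planted) else set(),
        driver_sites=set(planted["site_id"]) if len(planted) else set(),
        dbp_targets=genome.dbp_targets,
        bridge_pairs=genome.bridge_pairs,
        bridged_tads=bridged_tads,
    )
    return SyntheticCohort(meth, expr, groups), truth


# ---------------------------------------------------------------------------
# differentiation series


def generate_differentiation_series(
    genome: SyntheticGenome, config: SeriesConfig = SeriesConfig(), seed: int = 0
) -> SeriesResult:
    """Cell-type labelled expression series (default 211 samples, 15 types).

    Genes upregulated relative to the root cell type are drawn preferentially
    from the regulatable architecture class at ``regulatable_odds``."""
    rng = np.random.default_rng(seed)
    types = list(config.cell_types)
    if len(types) < 2:
        raise DesignError("need >= 2 cell types")
    sizes = (
        list(config.samples_per_type)
        if config.samples_per_type is not None
        else [15] + [14] * (len(types) - 1)
    )
    if len(sizes) != len(types):
        raise DesignError("samples_per_type must match cell_types")

    gene_ids = [g.gene_id for g in genome.genes]
    n_genes = len(gene_ids)
    classes = genome.gene_classes
    reg_w = np.array(
        [config.regulatable_odds if classes[g] == "regulatable" else 1.0 for g in gene_ids]
    )
    base = rng.uniform(3.0, 8.0, size=n_genes)
    profiles = pd.DataFrame(
        np.tile(base[:, None], (1, len(types))), index=gene_ids, columns=types
    )
    de_sets: dict[str, dict[str, set]] = {}
    n_de = int(round(config.de_fraction * n_genes))
    for t in types[1:]:
        n_up = n_de // 2
        n_down = n_de - n_up
        p_up = reg_w / reg_w.sum()
        up_idx = rng.choice(n_genes, size=n_up, replace=False, p=p_up) if n_up else np.array([], int)
        remaining = np.setdiff1d(np.arange(n_genes), up_idx)
        down_idx = rng.choice(remaining, size=n_down, replace=False) if n_down else np.array([], int)
        eff_up = rng.normal(config.effect_mean, config.effect_sd, size=len(up_idx))
        eff_down = rng.normal(config.effect_mean, config.effect_sd, size=len(down_idx))
        profiles.loc[np.array(gene_ids)[up_idx], t] += eff_up
        profiles.loc[np.array(gene_ids)[down_idx], t] -= eff_down
        de_sets[t] = {
            "up": set(np.array(gene_ids)[up_idx]),
            "down": set(np.array(gene_ids)[down_idx]),
        }

    cols, labels = [], []
    for t, k in zip(types, sizes):
        for i in range(k):
            cols.append(f"{t}_{i:02d}")
            labels.append(t)
    noise = rng.normal(0, config.noise_sd, size=(n_genes, len(cols)))
    mat = np.empty((n_genes, len(cols)))
    for j, t in enumerate(labels):
        mat[:, j] = profiles[t].to_numpy()
    values = pd.DataFrame(2.0 ** (mat + noise), index=gene_ids, columns=cols)
    meta = pd.Series(labels, index=cols, name="cell_type")
    biotypes = pd.Series({g.gene_id: g.biotype for g in genome.genes})
    return SeriesResult(ExpressionMatrix(values, meta, biotypes), profiles, de_sets)


def generate_projection_queries(
    series: SeriesResult,
    anchors: dict[str, str],
    n_per_group: int = 10,
    noise_sd: float = 0.4,
    seed: int = 0,
) -> ExpressionMatrix:
    """Query samples (e.g. AML genotype groups) anchored at reference
    cell-type mean profiles, for projection/distance analyses."""
    rng = np.random.default_rng(seed)
    cols, labels, mats = [], [], []
    for grp, ctype in anchors.items():
        prof = series.profiles[ctype].to_numpy()
        for i in range(n_per_group):
            cols.append(f"{grp}_q{i:02d}")
            labels.append(grp)
            mats.append(2.0 ** (prof + rng.normal(0, noise_sd, size=len(prof))))
    values = pd.DataFrame(
        np.column_stack(mats), index=series.profiles.index, columns=cols
    )
    return ExpressionMatrix(values, pd.Series(labels, index=cols, name="group"))
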