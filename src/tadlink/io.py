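"""Readers and writers for the interval, track and matrix formats used by
the pipeline: BED3/6 (TADs, enhancers, peaks), RepeatMasker-style extended
BED for repeats, BED12 or GTF gene models, bedGraph tracks, tab-delimited
methylation and expression tables with sample-metadata sidecars, two-column
PPI edge lists, and FASTA for repeat-footprint sequences."""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GeneModel, GenomicInterval, RepeatElement, StepTrack
from .tables import ExpressionMatrix, MethylationTable


# --- BED intervals ---------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# --- repeats (BED6 + family, subfamily, divergence) ------------------------


def read_repeats(path) -> list[RepeatElement]:
    """BED6 plus columns 7-8 (family, subfamily) and either a single
    divergence column 9 or three columns 9-11 (substitution, insertion,
    deletion percentages, summed into the divergence score)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]),
                                 f[5] if len(f) > 5 and f[5] in "+-" else ".")
            family, subfamily = f[6], f[7]
            if len(f) >= 11:
                div = float(f[8]) + float(f[9]) + float(f[10])
            else:
                div = float(f[8]) if len(f) > 8 else 0.0
            out.append(RepeatElement(f[3], family, subfamily, iv, div))
    return out


def write_repeats(repeats: Sequence[RepeatElement], path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.element_id}\t0\t{iv.strand}"
                f"\t{r.family}\t{r.subfamily}\t{r.divergence:.2f}\n"
            )


# --- gene models -----------------------------------------------------------


def write_genes_bed12(genes: Sequence[GeneModel], path) -> None:
    """BED12; the name field packs gene_id|symbol|biotype."""
    with open(path, "w") as fh:
        for g in genes:
            b = g.body
            sizes = ",".join(str(len(e)) for e in g.exons)
            starts = ",".join(str(e.start - b.start) for e in g.exons)
            fh.write(
                f"{g.chrom}\t{b.start}\t{b.end}\t{g.gene_id}|{g.symbol}|{g.biotype}"
                f"\t0\t{g.strand}\t{b.start}\t{b.end}\t0\t{len(g.exons)}\t{sizes},\t{starts},\n"
            )


def read_genes_bed12(path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            parts = f[3].split("|")
            gene_id = parts[0]
            symbol = parts[1] if len(parts) > 1 else gene_id
            biotype = parts[2] if len(parts) > 2 else "protein_coding"
            strand = f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            )
            out.append(GeneModel(gene_id, symbol, biotype, chrom, strand, exons))
    return out


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_genes_gtf(path) -> list[GeneModel]:
    """Exon features from a GTF; 1-based inclusive coordinates are converted
    to the internal 0-based half-open convention."""
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            gid = attrs["gene_id"]
            rec = exons.setdefault(
                gid,
                {
                    "chrom": f[0],
                    "strand": f[6],
                    "symbol": attrs.get("gene_name", gid),
                    "biotype": attrs.get("gene_biotype", "protein_coding"),
                    "exons": [],
                },
            )
            rec["exons"].append(
                GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6])
            )
    return [
        GeneModel(gid, r["symbol"], r["biotype"], r["chrom"], r["strand"], tuple(r["exons"]))
        for gid, r in exons.items()
    ]


# --- tracks ----------------------------------------------------------------


def read_bedgraph(path) -> StepTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    seg = {
        chrom: (
            g["start"].to_numpy(np.int64),
            g["end"].to_numpy(np.int64),
            g["value"].to_numpy(float),
        )
        for chrom, g in df.groupby("chrom")
    }
    return StepTrack(seg)


def write_bedgraph(track: StepTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.segments(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.4f}\n")


# --- methylation / expression tables ---------------------------------------


def write_methylation(meth: MethylationTable, path) -> None:
    """Tab-delimited: chrom, pos, then per-sample fraction (and coverage in
    site-level mode, as paired <sample>.frac / <sample>.cov columns)."""
    df = meth.sites[["chrom", "pos"]].copy()
    for s in meth.samples:
        if meth.coverage is not None:
            df[f"{s}.frac"] = meth.fractions[s]
            df[f"{s}.cov"] = meth.coverage[s]
        else:
            df[s] = meth.fractions[s]
    df.to_csv(path, sep="\t", index_label="site_id")


def read_methylation(path, sample_groups: Optional[pd.Series] = None) -> MethylationTable:
    df = pd.read_csv(path, sep="\t", index_col="site_id")
    sites = df[["chrom", "pos"]]
    cols = [c for c in df.columns if c not in ("chrom", "pos")]
    if any(c.endswith(".frac") for c in cols):
        samples = [c[:-5] for c in cols if c.endswith(".frac")]
        fractions = df[[f"{s}.frac" for s in samples]]
        fractions.columns = samples
        coverage = df[[f"{s}.cov" for s in samples]]
        coverage.columns = samples
        coverage = coverage.astype(int)
    else:
        fractions, coverage = df[cols], None
    return MethylationTable(sites, fractions, coverage, sample_groups)


def write_expression(expr: ExpressionMatrix, prefix) -> None:
    """<prefix>.tsv (matrix), <prefix>.samples.tsv (metadata sidecar) and
    <prefix>.biotypes.tsv when biotypes are attached."""
    prefix = Path(prefix)
    expr.values.to_csv(f"{prefix}.tsv", sep="\t", index_label="gene_id")
    if expr.sample_meta is not None:
        expr.sample_meta.rename("group").to_csv(
            f"{prefix}.samples.tsv", sep="\t", index_label="sample_id"
        )
    if expr.biotypes is not None:
        expr.biotypes.rename("biotype").to_csv(
            f"{prefix}.biotypes.tsv", sep="\t", index_label="gene_id"
        )


def read_expression(prefix) -> ExpressionMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(f"{prefix}.tsv", sep="\t", index_col="gene_id")
    meta = None
    if Path(f"{prefix}.samples.tsv").exists():
        meta = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col="sample_id")[
            "group"
        ]
    biotypes = None
    if Path(f"{prefix}.biotypes.tsv").exists():
        biotypes = pd.read_csv(
            f"{prefix}.biotypes.tsv", sep="\t", index_col="gene_id"
        )["biotype"]
    return ExpressionMatrix(values, meta, biotypes)


# --- misc ------------------------------------------------------------------


def read_ppi(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [(str(a), str(b)) for a, b in zip(df[0], df[1])]


def write_ppi(edges, path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def write_sequences(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_sequences(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for c, s in chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
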