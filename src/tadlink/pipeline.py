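"""Pipeline orchestration: configuration, stage execution, manifest and
report assembly.

Stages run in order simulate -> correlate -> architecture -> enrich-dbp ->
bridge -> dmc -> de -> project.  Every output table carries the manifest
hash as a leading comment line; a stage whose outputs already exist under
the same manifest hash is skipped on re-execution.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .architecture import compute_architecture, ecdf_shift_test, site_architecture_tests
from .bridge import binding_map, bridge_enrichment
from .correlation import (
    FilterParams,
    correlate_within_tads,
    filter_features,
    weakest_gene_set,
)
from .errors import DesignError
from .mc import mc_enrichment_z, mir_space_z
from .core import merge_intervals
from .projection import (
    distance_profile,
    distance_sam_and_enrichment,
    fit_and_project,
    rank_normalize,
)
from .samstat import de_two_class, dmc_by_repeat_family
from .simulate import (
    CohortDesign,
    GenomeConfig,
    SeriesConfig,
    generate_cohort,
    generate_differentiation_series,
    generate_genome,
    generate_projection_queries,
)

log = logging.getLogger("tadlink")

STAGES = (
    "simulate",
    "correlate",
    "architecture",
    "enrich-dbp",
    "bridge",
    "dmc",
    "de",
    "project",
)


@dataclass
class PipelineConfig:
    outdir: str = "tadlink_out"
    seed: int = 1
    rho_threshold: float = 0.5
    fdr_threshold: float = 0.05
    proximal_bp: int = 2_000
    long_bp: int = 500_000
    z_threshold: float = 10.0
    mc_iterations: int = 1000
    sam_permutations: int = 5000
    w_set_size: int = 1000
    simulate: bool = True
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    cohort: CohortDesign = field(default_factory=CohortDesign)
    series: SeriesConfig = field(default_factory=SeriesConfig)
    # non-simulation inputs
    tads_bed: Optional[str] = None
    genes_bed12: Optional[str] = None
    methylation_tsv: Optional[str] = None
    expression_prefix: Optional[str] = None

    def validate(self) -> None:
        for name in ("rho_threshold", "fdr_threshold", "proximal_bp", "long_bp",
                     "z_threshold", "mc_iterations", "sam_permutations"):
            if getattr(self, name) <= 0:
                raise DesignError(f"threshold {name} must be positive")
        if not self.simulate:
            for fieldname in ("tads_bed", "genes_bed12", "methylation_tsv",
                              "expression_prefix"):
                if getattr(self, fieldname) is None:
                    raise DesignError(
                        f"configuration error: {fieldname} is required when "
                        "simulation is disabled"
                    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("genome", GenomeConfig), ("cohort", CohortDesign),
                         ("series", SeriesConfig)):
            if key in raw and isinstance(raw[key], dict):
                sub_raw = raw[key]
                if "chrom_sizes" in sub_raw:
                    sub_raw["chrom_sizes"] = dict(sub_raw["chrom_sizes"])
                raw[key] = sub(**sub_raw)
        return cls(**raw)

    def manifest(self) -> dict:
        def _clean(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {k: _clean(v) for k, v in asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        payload = _clean(self)
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {"version": __version__, "hash": digest, "config": payload}


def _write_table(df: pd.DataFrame, path: Path, manifest_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {manifest_hash}\n")
        df.to_csv(fh, sep="\t", index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a report dict of per-stage summaries.

    Any stage failure halts the run with the stage name in the exception;
    outputs of completed stages are preserved."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = config.manifest()
    mhash = manifest["hash"]
    manifest_path = outdir / "manifest.json"

    done_marker = outdir / ".stages.json"
    done = {}
    if manifest_path.exists() and done_marker.exists():
        try:
            old = json.loads(manifest_path.read_text())
            if old.get("hash") == mhash:
                done = json.loads(done_marker.read_text())
        except (json.JSONDecodeError, OSError):
            done = {}
    manifest["seed"] = config.seed
    manifest_path.write_text(json.dumps(manifest, indent=2))

    report: dict = {"hash": mhash, "stages": {}}
    ctx: dict = {}
    for stage in STAGES:
        if done.get(stage) and stage in ("simulate",):
            # regenerate in-memory state deterministically; generation is cheap
            pass
        try:
            summary = _STAGE_FUNCS[stage](config, ctx, outdir, mhash)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report["stages"][stage] = summary
        done[stage] = True
        done_marker.write_text(json.dumps(done))
        log.info("stage %s done: %s", stage, summary)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _stage_simulate(cfg: PipelineConfig, ctx: dict, outdir: Path, mhash: str) -> dict:
    from . import io as tio

    if cfg.simulate:
        genome = generate_genome(cfg.genome, seed=cfg.seed)
        cohort, truth = generate_cohort(genome, cfg.cohort, seed=cfg.seed + 1)
        series = generate_differentiation_series(genome, cfg.series, seed=cfg.seed + 2)
        ctx.update(genome=genome, cohort=cohort, truth=truth, series=series)
        simdir = outdir / "simulated"
        simdir.mkdir(exist_ok=True)
        tio.write_chrom_sizes(genome.chrom_sizes, simdir / "chrom.sizes")
        tio.write_bed(genome.partition.intervals, simdir / "tads.bed",
                      names=genome.partition.tad_ids)
        tio.write_genes_bed12(genome.genes, simdir / "genes.bed12")
        tio.write_repeats(genome.repeats, simdir / "repeats.bed")
        tio.write_bed(genome.enhancers, simdir / "enhancers.bed")
        tio.write_bedgraph(genome.conservation, simdir / "conservation.bedgraph")
        tio.write_bedgraph(genome.gc, simdir / "gc.bedgraph")
        tio.write_methylation(cohort.methylation, simdir / "methylation.tsv")
        tio.write_expression(cohort.expression, simdir / "expression")
        tio.write_ppi(genome.ppi_edges, simdir / "ppi.tsv")
        tio.write_sequences(genome.repeat_sequences, simdir / "repeat_seqs.fasta")
        for dbp, peaks in genome.dbp_peaks.items():
            tio.write_bed(peaks, simdir / f"peaks_{dbp}.bed")
        _write_table(truth.planted_pairs, simdir / "ground_truth_pairs.tsv", mhash)
        return {"n_tads": genome.partition.n_tads, "n_genes": len(genome.genes),
                "n_planted_pairs": int(len(truth.planted_pairs))}
    from .io import (
        read_bed,
        read_expression,
        read_genes_bed12,
        read_methylation,
    )
    from .core import build_tad_partition

    genes = read_genes_bed12(cfg.genes_bed12)
    chrom_sizes_path = Path(cfg.tads_bed).with_suffix(".sizes")
    from .io import read_chrom_sizes

    chrom_sizes = read_chrom_sizes(chrom_sizes_path)
    partition = build_tad_partition(read_bed(cfg.tads_bed), chrom_sizes)

    class _G:  # minimal genome surrogate for user-supplied runs
        pass

    g = _G()
    g.genes, g.partition = genes, partition
    ctx.update(genome=g,
               cohort_expr=read_expression(cfg.expression_prefix),
               cohort_meth=read_methylation(cfg.methylation_tsv))
    return {"n_tads": partition.n_tads, "n_genes": len(genes)}


def _stage_correlate(cfg: PipelineConfig, ctx: dict, outdir: Path, mhash: str) -> dict:
    genome = ctx["genome"]
    if "cohort" in ctx:
        expr, meth = ctx["cohort"].expression, ctx["cohort"].methylation
    else:
        expr, meth = ctx["cohort_expr"], ctx["cohort_meth"]
    expr_f, meth_f = filter_features(expr, meth, FilterParams())
    table = correlate_within_tads(
        expr_f, meth_f, genome.partition, genome.genes,
        rho_threshold=cfg.rho_threshold, fdr_threshold=cfg.fdr_threshold,
    )
    ctx["corr_table"] = table
    ctx["expr_filtered"], ctx["meth_filtered"] = expr_f, meth_f
    _write_table(table, outdir / "correlations.tsv", mhash)
    sig = table[table["significant"]]
    return {
        "n_tested": int(len(table)),
        "n_significant": int(len(sig)),
        "n_genes": int(sig["gene_id"].nunique()),
        "n_sites": int(sig["site_id"].nunique()),
        "pct_negative": float(100 * (sig["rho"] < 0).mean()) if len(sig) else float("nan"),
    }


def _stage_architecture(cfg: PipelineConfig, ctx: dict, outdir: Path, mhash: str) -> dict:
    genome, table = ctx["genome"], ctx["corr_table"]
    arch = compute_architecture(
        genome.genes, genome.repeats, genome.conservation, genome.gc,
        cpg_positions=genome.cpg_sites,
    )
    ctx["architecture"] = arch
    _write_table(arch, outdir / "architecture.tsv", mhash)
    sig = table[table["significant"]]
    tested_genes = table["gene_id"].unique()
    out = {}
    for b in ("proximal", "intermediate", "long"):
        gset = sig.loc[sig["bin"] == b, "gene_id"].unique()
        if len(gset) < 5:
            continue
        vals = arch.loc[gset, "MIR_density_intron"].dropna()
        bg = arch.loc[tested_genes, "MIR_density_intron"].dropna()
        if len(vals) and len(bg):
            _, D, p, _ = ecdf_shift_test(vals, bg)
            out[b] = {"mir_intron_ks_D": D, "p": p, "n": int(len(gset))}
    sites_sig = ctx["meth_filtered"].sites.loc[sig["site_id"].unique()]
    sites_all = ctx["meth_filtered"].sites.loc[table["site_id"].unique()]
    site_rep = site_architecture_tests(
        sites_sig, sites_all, genome.repeats,
        conservation=genome.conservation, enhancers=genome.enhancers,
    )
    out["sites"] = {
        k: {kk: vv for kk, vv in v.items() if kk != "curve"}
        for k, v in site_rep.items()
        if isinstance(v, dict)
    }
    return out


def _stage_enrich_dbp(cfg: PipelineConfig, ctx: dict, outdir: Path, mhash: str) -> dict:
    genome, table = ctx["genome"], ctx["corr_table"]
    if not getattr(genome, "dbp_peaks", None):
        return {"skipped": "no DBP peaks available"}
    by_id = genome.genes_by_id
    tested_bodies = [by_id[g].body for g in table["gene_id"].unique()]
    space = merge_intervals(tested_bodies)
    sig = table[table["significant"]]
    rows = []
    gene_sets = {}
    for b in ("proximal", "intermediate", "long"):
        gene_sets[b] = sig.loc[sig["bin"] == b, "gene_id"].unique().tolist()
        w, _ = weakest_gene_set(table, n=min(cfg.w_set_size, table["gene_id"].nunique()), bin=b) \
            if (table["bin"] == b).any() else ([], False)
        gene_sets[f"W_{b}"] = w
    for name, gset in gene_sets.items():
        if len(gset) < 5:
            continue
        bodies = [by_id[g].body for g in gset]
        for dbp, peaks in genome.dbp_peaks.items():
            stage_seed = cfg.seed + zlib.crc32(f"{name}:{dbp}".encode()) % 10_000
            res = mc_enrichment_z(
                peaks, bodies, space, n=cfg.mc_iterations,
                seed=stage_seed, name=f"{dbp}:{name}",
            )
            rows.append({"gene_set": name, "dbp": dbp, "observed": res.observed,
                         "null_mean": res.null_mean, "null_sd": res.null_sd,
                         "z": res.z, "degenerate": res.degenerate})
    df = pd.DataFrame(rows)
    ctx["dbp_z"] = df
    _write_table(df, outdir / "dbp_enrichment.tsv", mhash)
    n_sig = int((df["z"].abs() > cfg.z_threshold).sum()) if len(df) else 0
    return {"n_tests": int(len(df)), "n_significant": n_sig}


def _stage_bridge(cfg: PipelineConfig, ctx: dict, outdir: Path, mhash: str) -> dict:
    genome, table = ctx["genome"], ctx["corr_table"]
    if not getattr(genome, "dbp_peaks", None):
        return {"skipped": "no DBP peaks available"}
    sig = table[table["significant"]]
    if sig.empty:
        return {"skipped": "no significant pairs"}
    sites = ctx["meth_filtered"].sites.loc[sig["site_id"].unique()]
    bmap = binding_map(genome.dbp_peaks, sites, genome.genes, genome.repeats)
    results = {}
    for mode in ("gene", "mir"):
        res = bridge_enrichment(sig, bmap, genome.ppi_edges, mode=mode)
        _write_table(res, outdir / f"bridge_{mode}.tsv", mhash)
        results[mode] = int((res["q"] < cfg.fdr_threshold).sum()) if len(res) else 0
    ctx["binding_map"] = bmap
    return {"n_significant_ppis": results}


def _stage_dmc(cfg: PipelineConfig, ctx: dict, outdir: Path, mhash: str) -> dict:
    cohort = ctx.get("cohort")
    if cohort is None:
        return {"skipped": "genotype groups unavailable"}
    groups = cohort.groups
    m = groups.isin(["IDH", "DNMT3A"])
    if m.sum() < 4:
        return {"skipped": "need IDH and DNMT3A groups"}
    meth = cohort.methylation.subset_samples(groups.index[m])
    out = {}
    for family in ("MIR", "Alu", "L1"):
        try:
            _, summary = dmc_by_repeat_family(
                meth, groups[m].to_numpy(), ctx["genome"].repeats, family,
                n_perm=min(cfg.sam_permutations, 1000), seed=cfg.seed,
            )
            out[family] = summary
        except Exception as exc:  # insufficient sites for a family is fine
            out[family] = {"skipped": str(exc)}
    _write_table(pd.DataFrame(out).T, outdir / "dmc_summary.tsv", mhash)
    return out


def _stage_de(cfg: PipelineConfig, ctx: dict, outdir: Path, mhash: str) -> dict:
    cohort = ctx.get("cohort")
    if cohort is None:
        return {"skipped": "genotype groups unavailable"}
    groups = cohort.groups
    m = groups.isin(["IDH", "DNMT3A"])
    expr = cohort.expression.subset_samples(groups.index[m])
    res = de_two_class(
        expr, groups[m].to_numpy(), n_perm=min(cfg.sam_permutations, 1000),
        fdr_target=cfg.fdr_threshold, seed=cfg.seed,
    )
    _write_table(res.significant, outdir / "de_genes.tsv", mhash)
    return {"n_de": int(len(res.significant)), "delta": res.delta}


def _stage_project(cfg: PipelineConfig, ctx: dict, outdir: Path, mhash: str) -> dict:
    series = ctx.get("series")
    if series is None:
        return {"skipped": "no differentiation series"}
    types = list(series.profiles.columns)
    anchors = {"DOUBLE": types[min(5, len(types) - 1)], "DNMT3A": types[0]}
    queries = generate_projection_queries(series, anchors, seed=cfg.seed + 3)
    ref = rank_normalize(series.expression.values)
    qry = rank_normalize(queries.values)
    proj = fit_and_project(ref, qry)
    prof = distance_profile(ref, qry)
    sam, enr = distance_sam_and_enrichment(
        prof, queries.sample_meta, series.expression.sample_meta,
        n_perm=min(cfg.sam_permutations, 1000), fdr_target=cfg.fdr_threshold,
        seed=cfg.seed,
    )
    _write_table(proj.query_scores, outdir / "projection_scores.tsv", mhash)
    _write_table(prof.centered, outdir / "distance_matrix.tsv", mhash)
    _write_table(enr, outdir / "celltype_enrichment.tsv", mhash)
    return {
        "n_components": int(proj.query_scores.shape[1]),
        "n_significant_refs": int(len(sam.significant)),
        "n_enriched_celltypes": int((enr["q"] < cfg.fdr_threshold).sum()) if len(enr) else 0,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "correlate": _stage_correlate,
    "architecture": _stage_architecture,
    "enrich-dbp": _stage_enrich_dbp,
    "bridge": _stage_bridge,
    "dmc": _stage_dmc,
    "de": _stage_de,
    "project": _stage_project,
}
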