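"""Workflow orchestration and machine-readable result bundles.

Three workflows compose the stages end to end:

- bulk: normalize -> age-bias classification -> conservation scoring ->
  per-sample expression-conservation profiles -> ADICT statistic (whole
  transcriptome and DE-genes-only) -> class comparison, bootstrap CIs, and
  the confound model when an auxiliary gene table is supplied;
- celltype: pseudobulk -> filters -> cross-cell-type profiles -> ANOVA and
  immune mixed model -> per-cell-type ADICT -> MRCS and immune analyses;
- popgen: windowed Tajima's D -> CDS-weighted gene means -> class comparison.

Each run writes a manifest with the config snapshot, seeds, version, SHA-256
checksums of every file read and written, and per-stage row counts, so a run
is reproducible from the manifest alone. All outputs are deterministic given
config + inputs + seed (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import agebias, celltype as ct, conservation, core, immune, normalize, popgen
from .errors import ConfigurationError

_JSON_KW = dict(indent=2, sort_keys=True, allow_nan=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _require(cfg: dict, *keys) -> None:
    for key in keys:
        if key not in cfg or cfg[key] in (None, ""):
            raise ConfigurationError(f"config is missing required field {key!r}")


class _Bundle:
    """Collects outputs and builds the run manifest."""

    def __init__(self, outdir, cfg: dict, seed: int | None):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "software_version": __version__,
            "config": cfg,
            "seed": seed,
            "inputs": {},
            "outputs": {},
            "counts": {},
        }

    def record_input(self, path) -> None:
        self.manifest["inputs"][str(path)] = _sha256(path)

    def write_tsv(self, name: str, df: pd.DataFrame, index=False) -> Path:
        path = self.outdir / name
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        self.manifest["outputs"][str(path)] = _sha256(path)
        return path

    def write_json(self, name: str, obj) -> Path:
        path = self.outdir / name
        with open(path, "w") as fh:
            json.dump(obj, fh, **_JSON_KW)
            fh.write("\n")
        self.manifest["outputs"][str(path)] = _sha256(path)
        return path

    def finish(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, **_JSON_KW)
            fh.write("\n")
        return path


def run_bulk_workflow(config, outdir=None) -> dict:
    """Bulk ADICT workflow; returns the result dict and writes the bundle."""
    cfg = load_config(config)
    _require(cfg, "counts", "metadata", "divergence")
    outdir = Path(outdir or cfg.get("out_dir", "adict_bulk_out"))
    seed = int(cfg.get("seed", 0))
    rho_cutoff = float(cfg.get("rho_cutoff", 0.5))
    q_cutoff = float(cfg.get("q_cutoff", 0.1))
    mode = cfg.get("mode", "bulk")
    bundle = _Bundle(outdir, cfg, seed)
    for key in ("counts", "metadata", "divergence"):
        bundle.record_input(cfg[key])

    counts = normalize.load_counts(cfg["counts"])
    meta = normalize.load_sample_metadata(cfg["metadata"])
    div = conservation.load_divergence_table(cfg["divergence"], cfg.get("dialect"))
    factors = normalize.median_ratio_size_factors(counts)
    expr = normalize.normalize_counts(
        counts, factors, sample_age=meta["age"], sample_tissue=meta.get("tissue")
    )
    stats_ = agebias.expression_age_correlation(expr)
    classes = agebias.classify_genes(stats_, mode=mode, rho_cutoff=rho_cutoff, q_cutoff=q_cutoff)
    sets = agebias.class_gene_sets(classes)
    cons = conservation.compute_conservation_scores(div)
    cons = conservation.relative_conservation(cons, sets["constant"])

    profiles = core.conservation_profiles(expr, cons)
    adict_whole = core.adict_statistic(profiles)
    results = {"adict_whole_transcriptome": adict_whole.to_dict()}
    if len(sets["de"]) >= 3:
        prof_de = core.conservation_profiles(
            expr, cons, gene_subset=sets["de"], gene_set_used="de_genes"
        )
        results["adict_de_genes"] = core.adict_statistic(prof_de).to_dict()
        profiles = pd.concat([profiles, prof_de], ignore_index=True)
    results["class_comparison"] = core.compare_class_conservation(cons, classes)
    results["bootstrap_mrcs"] = {
        lab: core.bootstrap_mean_rcs(cons, sets[lab], B=int(cfg.get("bootstrap_B", 1000)),
                                     seed=seed + i)
        for i, lab in enumerate(("old_biased", "young_biased"))
        if len(sets[lab]) >= 2
    }
    if cfg.get("gene_table"):
        bundle.record_input(cfg["gene_table"])
        aux = pd.read_csv(cfg["gene_table"], sep="\t").set_index("gene_id")
        tab = aux.join(classes["label"], how="inner").join(
            cons.set_index("gene_id")["omega"], how="inner"
        )
        results["confound_model"] = core.confound_model(tab.reset_index(), expression="mean")

    bundle.write_tsv("conservation.tsv", cons)
    bundle.write_tsv("classification.tsv", classes.reset_index(names="gene_id"))
    bundle.write_tsv("profiles.tsv", profiles)
    bundle.write_json("results.json", results)
    bundle.manifest["counts"].update(
        {
            "genes_in": int(len(counts)),
            "genes_expressed": int(len(expr.values)),
            "samples": int(expr.values.shape[1]),
            "genes_scored": int((~cons["excluded"]).sum()),
            "genes_excluded": int(cons["excluded"].sum()),
            "n_old_biased": int(len(sets["old_biased"])),
            "n_young_biased": int(len(sets["young_biased"])),
        }
    )
    bundle.finish()
    return results


def run_celltype_workflow(config, outdir=None) -> dict:
    """Cell-type ADICT workflow on cell-level expression + annotation."""
    cfg = load_config(config)
    _require(cfg, "cells", "annotation", "divergence")
    outdir = Path(outdir or cfg.get("out_dir", "adict_celltype_out"))
    seed = int(cfg.get("seed", 0))
    rho_cutoff = float(cfg.get("rho_cutoff", 0.5))
    bundle = _Bundle(outdir, cfg, seed)
    for key in ("cells", "annotation", "divergence"):
        bundle.record_input(cfg[key])

    matrix = ct.load_cell_matrix(cfg["cells"], cfg.get("genes"), cfg.get("barcodes"))
    ann = ct.load_cell_annotation(cfg["annotation"])
    div = conservation.load_divergence_table(cfg["divergence"], cfg.get("dialect"))
    cons = conservation.compute_conservation_scores(div)

    pb = ct.build_pseudobulk(matrix, ann)
    pb, filter_report = ct.filter_celltypes_and_individuals(
        pb, min_coverage=float(cfg.get("min_coverage", 0.70))
    )
    classifications = ct.per_celltype_classification(pb, rho_cutoff=rho_cutoff)
    constant = set(pb.values.index)
    for cls in classifications.values():
        constant &= set(cls.index[cls["label"] == "constant"])
    anchor = constant or set(pb.values.index)
    cons = conservation.relative_conservation(cons, anchor)

    youngest = float(pb.units["age_months"].min())
    profiles = ct.celltype_conservation_profiles(
        pb, cons, min_individuals=int(cfg.get("min_individuals", 3)), age_group=youngest
    )
    results = {"filtering": filter_report, "anova": ct.celltype_anova(profiles)}
    if "is_immune" in profiles.columns and profiles["is_immune"].nunique() > 1:
        results["immune_mixed_model"] = ct.immune_status_mixed_anova(profiles)
    adict_table = ct.per_celltype_adict(pb, cons, rho_cutoff=rho_cutoff)
    mrcs = immune.mrcs_report(cons, classifications)
    results["n_celltypes_adict"] = int(len(adict_table))
    results["n_celltypes_negative_rho"] = int((adict_table["rho_adict"] < 0).sum())
    if len(mrcs):
        paired = immune.paired_class_test(mrcs)
        results["mrcs_wilcoxon"] = paired.to_dict(orient="records")
    immune_cells = None
    if "is_immune" in pb.units.columns:
        immune_cells = (
            pb.units.groupby("cell_type")["is_immune"].first().astype(bool).to_dict()
        )
    if immune_cells is not None and len(mrcs):
        try:
            results["immune_vs_nonimmune_mrcs"] = immune.immune_vs_nonimmune(
                mrcs.rename(columns={"mrcs_diff": "value"}), immune_cells
            )
            results["immune_vs_nonimmune_adict"] = immune.immune_vs_nonimmune(
                adict_table.rename(columns={"rho_adict": "value"}), immune_cells
            )
        except Exception as exc:  # noqa: BLE001 - degraded gracefully, logged in results
            results["immune_vs_nonimmune_error"] = str(exc)
    if cfg.get("immune_genes"):
        bundle.record_input(cfg["immune_genes"])
        genes = immune.load_gene_list(cfg["immune_genes"])
        try:
            orep = immune.immune_overrepresentation(
                classifications, cons, genes,
                min_class_genes=int(cfg.get("min_class_genes", 20)),
            )
            bundle.write_tsv("immune_odds_ratios.tsv", orep)
        except Exception as exc:  # noqa: BLE001
            results["immune_overrepresentation_error"] = str(exc)

    bundle.write_tsv("profiles.tsv", profiles)
    bundle.write_tsv("per_celltype_adict.tsv", adict_table)
    if len(mrcs):
        bundle.write_tsv("mrcs.tsv", mrcs)
    bundle.write_json("results.json", results)
    bundle.manifest["counts"].update(
        {
            "cells": int(matrix.shape[1]),
            "genes": int(matrix.shape[0]),
            "pseudobulk_units": int(len(pb.units)),
            "celltypes_profiled": int(profiles["cell_type"].nunique()),
        }
    )
    bundle.finish()
    return results


def run_popgen_workflow(config, outdir=None) -> dict:
    """Population-level workflow: windowed D, gene means, class comparison."""
    cfg = load_config(config)
    _require(cfg, "vcf", "bed", "classification")
    outdir = Path(outdir or cfg.get("out_dir", "adict_popgen_out"))
    bundle = _Bundle(outdir, cfg, cfg.get("seed"))
    for key in ("vcf", "bed", "classification"):
        bundle.record_input(cfg[key])

    window = int(cfg.get("window", 10_000))
    bed = popgen.load_bed(cfg["bed"])
    classes = pd.read_csv(cfg["classification"], sep="\t").set_index("gene_id")
    pops = None
    if cfg.get("populations"):
        bundle.record_input(cfg["populations"])
        pops = pd.read_csv(cfg["populations"], sep="\t")

    gene_tables, tracks = {}, {}
    if pops is not None:
        for pop, members in pops.groupby("population"):
            variants, n_chrom = popgen.load_vcf(cfg["vcf"], samples=list(members["sample_id"]))
            track = popgen.window_tajimas_d(variants, n_chrom, window=window)
            tracks[pop] = track
            gene_tables[pop] = popgen.gene_tajima(track, bed, window=window)
    variants, n_chrom = popgen.load_vcf(cfg["vcf"])
    track = popgen.window_tajimas_d(variants, n_chrom, window=window)
    tracks["all"] = track
    gene_all = popgen.gene_tajima(track, bed, window=window)
    comparison = popgen.compare_tajima_classes(
        gene_tables if gene_tables else gene_all, classes
    )

    bundle.write_tsv("windows.tsv", track)
    bundle.write_tsv("gene_tajima.tsv", gene_all)
    bundle.write_tsv("class_comparison.tsv", comparison)
    results = {
        "n_windows": int(len(track)),
        "n_genes": int(len(gene_all)),
        "weighting": "CDS overlap length in bp",
        "comparison": comparison.to_dict(orient="records"),
    }
    bundle.write_json("results.json", results)
    bundle.manifest["counts"].update(
        {"windows": int(len(track)), "genes_with_D": int(gene_all["D_gene"].notna().sum())}
    )
    bundle.finish()
    return results
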