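"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: bulk age-series
count matrices with monotone old-/young-biased gene fractions and a tunable
coupling between age-bias class and dN/dS (the planted ADICT driver),
cell-level expression with cell-type mixtures, optional age-dependent
composition shifts and cell-autonomous ageing terms, and site-frequency data
with a tunable singleton excess for the Tajima's D stage. Emitted files use
the exact formats the pipeline readers expect, and truth tables record what
was planted.

Defaults describe the study conditions the pipeline targets: a bulk design of
five unequal adult ages with three replicates each (ages in weeks, so tied
ranks are exercised), 20% old- and 20% young-biased genes, log-normal dN/dS
centred near 0.22, a class-conservation coupling of 0.4 on ln(dN/dS), and
per-sample sequencing depths spanning 0.5-2x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .popgen import tajima_constants


@dataclass(frozen=True)
class CellTypeSpec:
    """One cell type of the single-cell generator.

    ``base_prop`` is its share of an individual's cells at the youngest age;
    ``prop_slope`` shifts that share per month of age (composition confound);
    ``coupling`` plants a cell-autonomous ADICT trend (expression of lowly
    conserved genes rising with age within the type); ``cons_affinity`` tilts
    the type's baseline profile toward highly (positive) or lowly (negative)
    conserved genes, making cell types differ in transcriptome conservation.
    """

    name: str
    tissue: str
    is_immune: bool = False
    base_prop: float = 0.25
    prop_slope: float = 0.0
    coupling: float = 0.0
    cons_affinity: float = 0.0


def default_celltype_spec() -> tuple[CellTypeSpec, ...]:
    """Two tissues x four cell types, one immune type per tissue."""
    return (
        CellTypeSpec("neuron", "brain", False, 0.40, 0.0, 0.0, 0.30),
        CellTypeSpec("astrocyte", "brain", False, 0.30, 0.0, 0.0, 0.10),
        CellTypeSpec("microglia", "brain", True, 0.20, 0.0, 0.0, -0.30),
        CellTypeSpec("endothelial", "brain", False, 0.10, 0.0, 0.0, 0.00),
        CellTypeSpec("hepatocyte", "liver", False, 0.50, 0.0, 0.0, 0.20),
        CellTypeSpec("kupffer", "liver", True, 0.20, 0.0, 0.0, -0.25),
        CellTypeSpec("stellate", "liver", False, 0.15, 0.0, 0.0, 0.05),
        CellTypeSpec("endothelial", "liver", False, 0.15, 0.0, 0.0, 0.00),
    )


def confound_celltype_spec() -> tuple[CellTypeSpec, ...]:
    """Composition-shift-only scenario: no cell-autonomous ageing anywhere,
    but an immune-like type with a low-conservation profile expands with age."""
    return (
        CellTypeSpec("parenchymal", "brain", False, 0.55, -0.010, 0.0, 0.35),
        CellTypeSpec("immune", "brain", True, 0.15, 0.020, 0.0, -0.35),
        CellTypeSpec("stromal", "brain", False, 0.30, -0.010, 0.0, 0.00),
    )


@dataclass
class SimulationConfig:
    """All knobs of the generators; ``seed`` is required everywhere."""

    seed: int
    # bulk design
    n_genes: int = 5000
    ages: tuple = (8, 8, 8, 26, 26, 26, 52, 52, 52, 78, 78, 78, 104, 104, 104)
    frac_old: float = 0.2
    frac_young: float = 0.2
    expr_effect: float = 0.05   # ln-expression slope per age unit (centred)
    noise_sd: float = 0.3       # ln-scale residual sd
    coupling: float = 0.4       # mean ln(dN/dS) difference, old minus young
    omega_mu: float = -1.5      # ln(dN/dS) location (median omega ~0.22)
    omega_sd: float = 0.5
    base_log_expr_mu: float = 3.5
    base_log_expr_sd: float = 1.0
    depth_range: tuple = (0.5, 2.0)
    dispersion: float | None = None  # NB size parameter; None = Poisson
    frac_not_one2one: float = 0.02
    frac_paralog: float = 0.03
    gene_age_range: tuple = (50.0, 1500.0)  # Myr
    # single-cell design
    celltype_spec: tuple = field(default_factory=default_celltype_spec)
    age_groups: tuple = (3.0, 18.0, 24.0)
    n_individuals_per_age: int = 4
    n_cells_per_individual: int = 100
    sc_noise_sd: float = 0.5
    sc_type_profile_sd: float = 0.3
    immune_gene_frac: float = 0.10
    # variant design
    sfs_mode: str = "neutral"
    singleton_factor: float = 3.0
    theta_per_window: float = 20.0
    n_windows: int = 500
    n_chromosomes: int = 20
    window: int = 10_000

    def __post_init__(self) -> None:
        if self.frac_old < 0 or self.frac_young < 0 or self.frac_old + self.frac_young > 1:
            raise ConfigurationError("class fractions must be >=0 and sum to at most 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.sfs_mode not in ("neutral", "singleton_excess"):
            raise ConfigurationError(f"unknown sfs_mode {self.sfs_mode!r}")
        if self.theta_per_window <= 0:
            raise ConfigurationError("theta_per_window must be positive")
        if self.n_chromosomes < 4:
            raise ConfigurationError("n_chromosomes must be at least 4")


@dataclass
class BulkSimulation:
    counts: pd.DataFrame
    samples: pd.DataFrame
    divergence: pd.DataFrame
    truth: pd.DataFrame


@dataclass
class CellTypeSimulation:
    cell_matrix: pd.DataFrame
    annotation: pd.DataFrame
    divergence: pd.DataFrame
    immune_genes: set
    truth: pd.DataFrame


@dataclass
class VariantSimulation:
    variants: pd.DataFrame
    bed: pd.DataFrame
    n_chromosomes: int
    populations: pd.DataFrame


def _divergence_from_lnomega(gene_ids, ln_omega, rng, cfg: SimulationConfig) -> pd.DataFrame:
    omega = np.exp(ln_omega)
    dS = np.exp(rng.normal(np.log(0.2), 0.3, size=len(gene_ids)))
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "dN": omega * dS,
            "dS": dS,
            "is_one2one": rng.random(len(gene_ids)) >= cfg.frac_not_one2one,
            "has_paralog": rng.random(len(gene_ids)) < cfg.frac_paralog,
        }
    )


def simulate_bulk_dataset(config: SimulationConfig) -> BulkSimulation:
    """Bulk age-series counts with class-conservation coupling.

    Old-biased genes rise (ln-slope +expr_effect per age unit) and carry
    ln(dN/dS) shifted by +coupling/2 (less conserved); young-biased genes
    mirror both. Counts are Poisson (or negative binomial when ``dispersion``
    is set) around depth-scaled log-normal means.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    G, ages = cfg.n_genes, np.asarray(cfg.ages, dtype=float)
    S = len(ages)
    n_old = int(round(cfg.frac_old * G))
    n_young = int(round(cfg.frac_young * G))
    labels = np.array(
        ["old_biased"] * n_old + ["young_biased"] * n_young + ["constant"] * (G - n_old - n_young)
    )
    rng.shuffle(labels)
    slope = np.where(labels == "old_biased", cfg.expr_effect,
                     np.where(labels == "young_biased", -cfg.expr_effect, 0.0))
    base = rng.normal(cfg.base_log_expr_mu, cfg.base_log_expr_sd, size=G)
    cage = ages - ages.mean()
    log_mean = base[:, None] + slope[:, None] * cage[None, :]
    log_mean += rng.normal(0.0, cfg.noise_sd, size=(G, S))
    lo, hi = cfg.depth_range
    depth = np.exp(rng.uniform(np.log(lo), np.log(hi), size=S))
    lam = depth[None, :] * np.exp(log_mean)
    if cfg.dispersion is None:
        counts = rng.poisson(lam)
    else:
        r = cfg.dispersion
        counts = rng.negative_binomial(r, r / (r + lam))
    gene_ids = np.array([f"g{i:05d}" for i in range(G)])
    sample_ids = [f"s{j:02d}" for j in range(S)]
    shift = np.where(labels == "old_biased", cfg.coupling / 2,
                     np.where(labels == "young_biased", -cfg.coupling / 2, 0.0))
    ln_omega = rng.normal(cfg.omega_mu + shift, cfg.omega_sd)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_class": labels,
            "omega": np.exp(ln_omega),
            "expr_slope": slope,
            "gene_age": rng.uniform(*cfg.gene_age_range, size=G),
        }
    )
    return BulkSimulation(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        samples=pd.DataFrame(
            {"sample_id": sample_ids, "age": ages, "tissue": "brain"}
        ),
        divergence=_divergence_from_lnomega(gene_ids, ln_omega, rng, cfg),
        truth=truth,
    )


def simulate_celltype_dataset(config: SimulationConfig) -> CellTypeSimulation:
    """Cell-level expression with cell-type mixtures and planted structure.

    Each type's baseline profile is tilted by its conservation affinity;
    composition follows age-dependent multinomial proportions; a nonzero
    per-type coupling adds a cell-autonomous ageing term that raises the
    expression of lowly conserved genes with age within that type. Values are
    linear-scale (exponentiated Gaussian), so pseudobulk means are defined.
    """
    cfg = config
    if not cfg.celltype_spec:
        raise ConfigurationError("celltype_spec must not be empty")
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(G)])
    ln_omega = rng.normal(cfg.omega_mu, cfg.omega_sd, size=G)
    cs = -ln_omega
    cs_z = (cs - cs.mean()) / cs.std()
    base = rng.normal(2.0, 1.0, size=G)
    immune_genes = set(gene_ids[rng.random(G) < cfg.immune_gene_frac])
    by_tissue: dict[str, list[CellTypeSpec]] = {}
    for spec in cfg.celltype_spec:
        by_tissue.setdefault(spec.tissue, []).append(spec)
    profiles = {
        (s.tissue, s.name): base + s.cons_affinity * cs_z
        + rng.normal(0.0, cfg.sc_type_profile_sd, size=G)
        for specs in by_tissue.values() for s in specs
    }
    ages = np.asarray(cfg.age_groups, dtype=float)
    age_c = (ages - ages.mean()) / (np.ptp(ages) / 2 or 1.0)
    blocks, ann_rows = [], []
    cell_counter = 0
    for tissue, specs in sorted(by_tissue.items()):
        base_props = np.array([s.base_prop for s in specs], dtype=float)
        slopes = np.array([s.prop_slope for s in specs], dtype=float)
        for ai, age in enumerate(ages):
            props = np.clip(base_props + slopes * (age - ages[0]), 0.01, None)
            if not np.isfinite(props).all() or props.sum() <= 0:
                raise ConfigurationError("degenerate cell-type proportions")
            props = props / props.sum()
            for k in range(cfg.n_individuals_per_age):
                ind = f"{tissue}_a{int(age)}_i{k}"
                n_by_type = rng.multinomial(cfg.n_cells_per_individual, props)
                for spec, n_cells in zip(specs, n_by_type):
                    if n_cells == 0:
                        continue
                    mu = profiles[(tissue, spec.name)] - spec.coupling * cs_z * age_c[ai]
                    logx = mu[:, None] + rng.normal(0.0, cfg.sc_noise_sd, size=(G, n_cells))
                    blocks.append(np.exp(logx))
                    for _ in range(n_cells):
                        ann_rows.append(
                            {
                                "cell_id": f"c{cell_counter:06d}",
                                "individual": ind,
                                "age_months": age,
                                "tissue": tissue,
                                "cell_type": spec.name,
                                "is_immune": spec.is_immune,
                            }
                        )
                        cell_counter += 1
    annotation = pd.DataFrame(ann_rows)
    matrix = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=gene_ids, columns=annotation["cell_id"].values
    )
    truth = pd.DataFrame(
        [
            {
                "cell_type": s.name, "tissue": s.tissue, "is_immune": s.is_immune,
                "base_prop": s.base_prop, "prop_slope": s.prop_slope,
                "coupling": s.coupling, "cons_affinity": s.cons_affinity,
            }
            for s in cfg.celltype_spec
        ]
    )
    rng2 = np.random.default_rng(cfg.seed + 1)
    divergence = _divergence_from_lnomega(gene_ids, ln_omega, rng2, cfg)
    return CellTypeSimulation(
        cell_matrix=matrix,
        annotation=annotation,
        divergence=divergence,
        immune_genes=immune_genes,
        truth=truth,
    )


def simulate_variant_windows(config: SimulationConfig) -> VariantSimulation:
    """Per-window segregating sites with a neutral or singleton-inflated SFS.

    S ~ Poisson(theta * a1) per window; allele counts j in 1..n-1 drawn with
    probability proportional to 1/j (the neutral expectation), with the
    singleton class inflated by ``singleton_factor`` in singleton_excess mode.
    Synthetic genes tile the windows with known CDS overlaps: one
    single-window gene per window plus a two-exon gene spanning each pair of
    consecutive windows (3 kb + 7 kb overlap).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, W = cfg.n_chromosomes, cfg.window
    a1 = tajima_constants(n)["a1"]
    j = np.arange(1, n)
    probs = 1.0 / j
    if cfg.sfs_mode == "singleton_excess":
        probs = probs.copy()
        probs[0] *= cfg.singleton_factor
    probs = probs / probs.sum()
    rows = []
    for w in range(cfg.n_windows):
        S = rng.poisson(cfg.theta_per_window * a1)
        S = min(S, W)
        if S == 0:
            continue
        pos = np.sort(rng.choice(W, size=S, replace=False)) + w * W + 1  # 1-based
        counts = rng.choice(j, size=S, p=probs)
        for p, c in zip(pos, counts):
            rows.append(("chr1", int(p), int(c)))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "alt_count"])
    bed_rows = []
    for w in range(cfg.n_windows):
        bed_rows.append(("chr1", w * W + 2000, w * W + 8000, f"gene_w{w:04d}"))
        if w + 1 < cfg.n_windows:
            gid = f"gene_x{w:04d}"
            bed_rows.append(("chr1", w * W + W - 3000, w * W + W, gid))
            bed_rows.append(("chr1", (w + 1) * W, (w + 1) * W + 7000, gid))
    bed = pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "gene_id"])
    n_samples = n // 2
    populations = pd.DataFrame(
        {
            "sample_id": [f"ind{k:03d}" for k in range(n_samples)],
            "population": ["popA" if k < n_samples // 2 else "popB" for k in range(n_samples)],
        }
    )
    return VariantSimulation(variants=variants, bed=bed, n_chromosomes=n, populations=populations)


def simulate_confound_genes(
    n_genes: int,
    class_effect: float,
    seed: int,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Gene table for the dN/dS ~ expression + gene age + class model.

    dN/dS depends linearly on expression and gene age plus Gaussian noise;
    ``class_effect`` is added for old-biased genes (zero = null model).
    """
    rng = np.random.default_rng(seed)
    mean_expr = np.exp(rng.normal(2.0, 1.0, size=n_genes))
    gene_age = rng.uniform(50, 1500, size=n_genes)
    is_old = rng.random(n_genes) < 0.5
    omega = (
        0.25
        - 0.01 * np.log(mean_expr)
        - 0.00003 * gene_age
        + class_effect * is_old
        + rng.normal(0.0, noise_sd, size=n_genes)
    )
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "omega": omega,
            "mean_expr": mean_expr,
            "max_expr": mean_expr * np.exp(rng.normal(0.5, 0.2, size=n_genes)),
            "gene_age": gene_age,
            "label": np.where(is_old, "old_biased", "young_biased"),
        }
    )


# ---------------------------------------------------------------------------
# writers: emit the exact on-disk formats the pipeline readers consume
# ---------------------------------------------------------------------------

def write_bulk_dataset(sim: BulkSimulation, outdir) -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "divergence": out / "divergence.tsv",
        "truth": out / "truth_genes.tsv",
    }
    sim.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    sim.samples.to_csv(paths["samples"], sep="\t", index=False)
    sim.divergence.to_csv(paths["divergence"], sep="\t", index=False, float_format="%.10g")
    sim.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return {k: str(v) for k, v in paths.items()}


def write_celltype_dataset(sim: CellTypeSimulation, outdir, dense: bool = False) -> dict:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "annotation.tsv",
        "divergence": out / "divergence.tsv",
        "immune_genes": out / "immune_genes.tsv",
        "truth": out / "truth_celltypes.tsv",
    }
    if dense:
        paths["cells"] = out / "cells.tsv"
        sim.cell_matrix.rename_axis("gene_id").to_csv(paths["cells"], sep="\t", float_format="%.6g")
    else:
        paths["cells"] = out / "cells.mtx"
        paths["genes"] = out / "genes.txt"
        paths["barcodes"] = out / "cells.txt"
        mmwrite(str(paths["cells"]), csr_matrix(sim.cell_matrix.values), precision=6)
        pd.Series(sim.cell_matrix.index).to_csv(paths["genes"], index=False, header=False)
        pd.Series(sim.cell_matrix.columns).to_csv(paths["barcodes"], index=False, header=False)
    sim.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    sim.divergence.to_csv(paths["divergence"], sep="\t", index=False, float_format="%.10g")
    pd.Series(sorted(sim.immune_genes)).to_csv(paths["immune_genes"], index=False, header=False)
    sim.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return {k: str(v) for k, v in paths.items()}


def write_variant_dataset(sim: VariantSimulation, outdir) -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "variants.vcf",
        "bed": out / "genes.bed",
        "populations": out / "populations.tsv",
    }
    write_vcf(sim.variants, sim.n_chromosomes, paths["vcf"])
    sim.bed.to_csv(paths["bed"], sep="\t", index=False, header=False)
    sim.populations.to_csv(paths["populations"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def write_vcf(variants: pd.DataFrame, n_chromosomes: int, path) -> None:
    """Write biallelic SNPs as a minimal diploid VCF matching alt counts."""
    if n_chromosomes % 2:
        raise ConfigurationError("diploid VCF output needs an even n_chromosomes")
    n_samples = n_chromosomes // 2
    samples = [f"ind{k:03d}" for k in range(n_samples)]
    max_end = int(variants["pos"].max()) + 1 if len(variants) else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(variants["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom},length={max_end + 10000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for r in variants.itertuples():
            hap = np.zeros(n_chromosomes, dtype=int)
            hap[: int(r.alt_count)] = 1
            gts = "\t".join(f"{hap[2 * s]}|{hap[2 * s + 1]}" for s in range(n_samples))
            fh.write(f"{r.chrom}\t{r.pos}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["celltype_spec"] = [asdict(s) if not isinstance(s, dict) else s
                          for s in d["celltype_spec"]]
    return d
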