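"""Cell-type-resolved transcriptome conservation from single-cell data.

Cell-level expression is collapsed to pseudobulk: for every (tissue, cell
type, individual) the per-gene arithmetic mean over that individual's cells of
that type. Cell types absent from any required age group are removed, then
individuals covering too few of a tissue's cell types (<= 70% by default) are
dropped. Per-cell-type expression-conservation profiles, the tissue/cell-type
ANOVA decomposition, the immune-status mixed model, and the per-cell-type
ADICT scan all operate on the filtered pseudobulk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ._stats import benjamini_hochberg, spearman_columns
from .agebias import class_gene_sets, classify_genes, expression_age_correlation
from .core import ADICTResult, adict_statistic, _retained_cs
from .errors import AnalysisError, InputError
from .normalize import ExpressionDataset

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("cell_id", "individual", "age_months", "tissue", "cell_type")


@dataclass
class PseudobulkDataset:
    """Mean expression per (tissue, cell_type, individual) unit.

    ``values``: genes x units; ``units``: one row per unit (indexed by the
    unit id) with tissue, cell_type, individual, age_months, n_cells and,
    when supplied, is_immune.
    """

    values: pd.DataFrame
    units: pd.DataFrame


def load_cell_matrix(path, genes_path=None, cells_path=None) -> pd.DataFrame:
    """Read a cell-level matrix: dense TSV, or MatrixMarket triplet + indexes."""
    path = str(path)
    if path.endswith(".mtx"):
        from scipy.io import mmread

        if genes_path is None or cells_path is None:
            raise InputError("MatrixMarket input needs gene and cell index files")
        m = mmread(path).toarray()
        genes = pd.read_csv(genes_path, header=None)[0].values
        cells = pd.read_csv(cells_path, header=None)[0].values
        return pd.DataFrame(m, index=genes, columns=cells)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise InputError(f"cell matrix {path!r} is empty")
    return df


def load_cell_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "individual": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"cell annotation is missing columns {missing}")
    if "is_immune" in df.columns:
        df["is_immune"] = df["is_immune"].astype(bool)
    return df


def build_pseudobulk(cell_matrix: pd.DataFrame, annotation: pd.DataFrame) -> PseudobulkDataset:
    """Average cells into (tissue, cell_type, individual) pseudobulk units."""
    ann = annotation.set_index("cell_id")
    unknown = ann.index.difference(cell_matrix.columns)
    if len(unknown):
        raise InputError(f"annotation references {len(unknown)} cells absent from the matrix")
    unannotated = cell_matrix.columns.difference(ann.index)
    if len(unannotated):
        raise InputError(f"{len(unannotated)} cells in the matrix lack annotation")
    keys = ["tissue", "cell_type", "individual"]
    groups = ann.groupby(keys, sort=True)
    cols, meta = [], []
    for key, cells in groups.groups.items():
        tissue, cell_type, individual = key
        unit = f"{tissue}|{cell_type}|{individual}"
        cols.append(cell_matrix[list(cells)].mean(axis=1).rename(unit))
        row = {
            "tissue": tissue,
            "cell_type": cell_type,
            "individual": individual,
            "age_months": float(ann.loc[list(cells), "age_months"].iloc[0]),
            "n_cells": len(cells),
        }
        if "is_immune" in ann.columns:
            row["is_immune"] = bool(ann.loc[list(cells), "is_immune"].iloc[0])
        meta.append((unit, row))
    values = pd.concat(cols, axis=1)
    units = pd.DataFrame({u: r for u, r in meta}).T
    units.index.name = "unit_id"
    for col in ("age_months",):
        units[col] = units[col].astype(float)
    units["n_cells"] = units["n_cells"].astype(int)
    return PseudobulkDataset(values=values, units=units)


def filter_celltypes_and_individuals(
    pb: PseudobulkDataset,
    min_coverage: float = 0.70,
    age_groups_required=None,
) -> tuple[PseudobulkDataset, dict]:
    """Apply the two filtering rules, cell types first, then individuals.

    1. Within each tissue, drop cell types not observed in every required age
       group (defaults to all age groups seen in that tissue's data).
    2. Within each tissue x age group, keep only individuals with pseudobulk
       data for strictly more than ``min_coverage`` of the tissue's remaining
       cell types.
    """
    units = pb.units
    report = {"celltypes_dropped": 0, "individuals_dropped": 0}
    keep_units = []
    for tissue, tunits in units.groupby("tissue", sort=True):
        required = set(age_groups_required) if age_groups_required is not None else set(
            tunits["age_months"]
        )
        by_type = tunits.groupby("cell_type")["age_months"].agg(lambda s: set(s))
        good_types = set(by_type.index[[required <= s for s in by_type]])
        report["celltypes_dropped"] += len(by_type) - len(good_types)
        tunits = tunits[tunits["cell_type"].isin(good_types)]
        n_types = tunits["cell_type"].nunique()
        if n_types == 0:
            continue
        for _, gunits in tunits.groupby("age_months"):
            cov = gunits.groupby("individual")["cell_type"].nunique() / n_types
            good_ind = set(cov.index[cov > min_coverage])
            report["individuals_dropped"] += cov.size - len(good_ind)
            keep_units.append(gunits[gunits["individual"].isin(good_ind)])
    if not keep_units:
        raise AnalysisError(f"all pseudobulk data removed by filtering: {report}")
    units_out = pd.concat(keep_units).sort_index()
    out = PseudobulkDataset(values=pb.values[units_out.index], units=units_out)
    report["units_kept"] = len(units_out)
    logger.info("pseudobulk filtering: %s", report)
    return out, report


def common_gene_set(pb: PseudobulkDataset) -> pd.Index:
    """Genes expressed (nonzero in at least one unit) in every tissue."""
    common = None
    for tissue, tunits in pb.units.groupby("tissue"):
        expressed = pb.values.index[(pb.values[tunits.index] > 0).any(axis=1)]
        common = expressed if common is None else common.intersection(expressed)
    if common is None or len(common) == 0:
        raise AnalysisError("no gene is expressed in every tissue")
    return common


def celltype_conservation_profiles(
    pb: PseudobulkDataset,
    cons: pd.DataFrame,
    common_genes=None,
    min_individuals: int = 3,
    age_group: float | None = None,
) -> pd.DataFrame:
    """One expression-conservation rho per (tissue, cell type, individual).

    Computed over the common gene set (intersection of expressed genes across
    tissues) so correlations are comparable across cell types; cell types with
    fewer than ``min_individuals`` values are excluded.
    """
    if common_genes is None:
        common_genes = common_gene_set(pb)
    cs = _retained_cs(cons)
    genes = pd.Index(common_genes).intersection(pb.values.index).intersection(cs.index)
    if len(genes) < 3:
        raise AnalysisError("common gene set shares fewer than 3 genes with the scores")
    logger.info("common gene set size: %d", len(genes))
    units = pb.units
    if age_group is not None:
        units = units[units["age_months"] == age_group]
    if units.empty:
        raise AnalysisError(f"no pseudobulk units in age group {age_group}")
    ec = spearman_columns(pb.values.loc[genes, units.index].values, cs.loc[genes].values)
    prof = units.copy()
    prof["ec_rho"] = ec
    prof["n_genes"] = len(genes)
    sizes = prof.groupby(["tissue", "cell_type"])["individual"].transform("nunique")
    prof = prof[sizes >= min_individuals]
    if prof.empty:
        raise AnalysisError("no cell type has enough individuals after filtering")
    return prof.reset_index()


def celltype_anova(profiles: pd.DataFrame) -> dict:
    """Sequential (type-I) two-way ANOVA: ec_rho ~ tissue + cell_type."""
    for factor in ("tissue", "cell_type"):
        if profiles[factor].nunique() < 2:
            raise AnalysisError(f"factor {factor!r} has a single level")
    if np.ptp(profiles["ec_rho"].values) == 0:  # no variance: no effects
        zero = {"df": np.nan, "sum_sq": 0.0, "F": 0.0, "p": 1.0}
        return {"tissue": dict(zero), "cell_type": dict(zero),
                "residual_df": float(len(profiles))}
    fit = smf.ols("ec_rho ~ C(tissue) + C(cell_type)", data=profiles).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    out = {}
    for row, name in (("C(tissue)", "tissue"), ("C(cell_type)", "cell_type")):
        ss = float(tab.loc[row, "sum_sq"])
        F = float(tab.loc[row, "F"])
        p = float(tab.loc[row, "PR(>F)"])
        if ss == 0 and not np.isfinite(F):  # zero-variance data: no effect
            F, p = 0.0, 1.0
        out[name] = {"df": float(tab.loc[row, "df"]), "sum_sq": ss, "F": F, "p": p}
    out["residual_df"] = float(tab.loc["Residual", "df"])
    return out


def immune_status_mixed_anova(profiles: pd.DataFrame) -> dict:
    """Mixed model: ec_rho ~ immune status with a random tissue intercept."""
    df = profiles.copy()
    if "is_immune" not in df.columns:
        raise AnalysisError("profiles lack an is_immune column")
    df["immune"] = df["is_immune"].astype(float)
    if df["immune"].nunique() < 2:
        raise AnalysisError("immune status is constant across cell types")
    if df["tissue"].nunique() < 2:
        logger.warning("single tissue: falling back to one-way ANOVA for immune status")
        fit = smf.ols("ec_rho ~ immune", data=df).fit()
        return {
            "model": "ols_fallback",
            "immune_coefficient": float(fit.params["immune"]),
            "immune_p": float(fit.pvalues["immune"]),
            "n": int(fit.nobs),
        }
    fit = smf.mixedlm("ec_rho ~ immune", data=df, groups=df["tissue"]).fit(reml=True)
    return {
        "model": "mixedlm",
        "immune_coefficient": float(fit.params["immune"]),
        "immune_p": float(fit.pvalues["immune"]),
        "n": int(fit.nobs),
        "n_tissues": int(df["tissue"].nunique()),
    }


def per_celltype_classification(
    pb: PseudobulkDataset, rho_cutoff: float = 0.5
) -> dict[tuple, pd.DataFrame]:
    """Single-cell-mode age-bias classification per (tissue, cell_type)."""
    out = {}
    for (tissue, ctype), cunits in pb.units.groupby(["tissue", "cell_type"], sort=True):
        if len(cunits) < 3 or cunits["age_months"].nunique() < 2:
            continue
        vals = pb.values[cunits.index]
        expressed = vals.index[(vals > 0).any(axis=1)]
        expr = ExpressionDataset(
            values=vals.loc[expressed],
            sample_age=pd.Series(cunits["age_months"].values, index=cunits.index),
            is_normalized=True,
        )
        stats_ = expression_age_correlation(expr)
        out[(tissue, ctype)] = classify_genes(stats_, mode="single_cell", rho_cutoff=rho_cutoff)
    if not out:
        raise AnalysisError("no cell type has enough units for classification")
    return out


def per_celltype_adict(
    pb: PseudobulkDataset,
    cons: pd.DataFrame,
    rho_cutoff: float = 0.5,
    min_units: int = 3,
    gene_set: str = "de",
    bh_within_tissue: bool = True,
) -> pd.DataFrame:
    """ADICT statistic per cell type, BH-corrected across cell types.

    ``gene_set='de'`` profiles each cell type on its own age-classified genes
    (union of old- and young-biased), falling back to all scored genes when
    fewer than 3 classify; ``'all'`` always uses all scored genes. Shared cell
    types are evaluated per tissue.
    """
    cs = _retained_cs(cons)
    classifications = per_celltype_classification(pb, rho_cutoff=rho_cutoff)
    rows = []
    for (tissue, ctype), cunits in pb.units.groupby(["tissue", "cell_type"], sort=True):
        if len(cunits) < min_units or (tissue, ctype) not in classifications:
            continue
        genes = pb.values.index.intersection(cs.index)
        used = "whole_transcriptome"
        if gene_set == "de":
            de = class_gene_sets(classifications[(tissue, ctype)])["de"]
            de = de.intersection(genes)
            if len(de) >= 3:
                genes, used = de, "de_genes"
        vals = pb.values.loc[genes, cunits.index]
        ec = spearman_columns(vals.values, cs.loc[genes].values)
        prof = pd.DataFrame(
            {"unit_id": cunits.index, "age": cunits["age_months"].values, "ec_rho": ec}
        )
        try:
            res: ADICTResult = adict_statistic(prof)
        except AnalysisError:
            continue
        rows.append(
            {
                "tissue": tissue,
                "cell_type": ctype,
                "rho_adict": res.rho_adict,
                "p_adict": res.p_adict,
                "n_units": res.n_units,
                "n_genes": len(genes),
                "gene_set_used": used,
            }
        )
    if not rows:
        raise AnalysisError("no cell type qualifies for the per-cell-type ADICT scan")
    out = pd.DataFrame(rows)
    if bh_within_tissue:
        out["q_adict"] = np.nan
        for tissue, idx in out.groupby("tissue").groups.items():
            out.loc[idx, "q_adict"] = benjamini_hochberg(out.loc[idx, "p_adict"].values)
    else:
        out["q_adict"] = benjamini_hochberg(out["p_adict"].values)
    return out


def individual_mixture_expression(
    cell_matrix: pd.DataFrame, annotation: pd.DataFrame
) -> ExpressionDataset:
    """Bulk-style matrix: mean over ALL of an individual's cells, per tissue.

    This reconstructs what a bulk sample of the tissue would measure, cell-type
    composition shifts included; used to contrast mixture-level ADICT with the
    per-cell-type view.
    """
    ann = annotation.set_index("cell_id")
    cols, ages = [], {}
    for (tissue, ind), cells in ann.groupby(["tissue", "individual"]).groups.items():
        unit = f"{tissue}|{ind}"
        cols.append(cell_matrix[list(cells)].mean(axis=1).rename(unit))
        ages[unit] = float(ann.loc[list(cells), "age_months"].iloc[0])
    values = pd.concat(cols, axis=1)
    return ExpressionDataset(
        values=values, sample_age=pd.Series(ages), is_normalized=True
    )
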