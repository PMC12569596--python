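"""The ADICT statistic and its supporting comparisons.

For each sample (or pseudobulk unit) the transcriptome-conservation level is
summarised as a single Spearman correlation between expression and per-gene
conservation scores across genes (``ec_rho``). The ADICT statistic is then the
Spearman correlation of those per-unit ``ec_rho`` values with age: a negative
value — transcriptomes drifting toward lowly conserved genes with age — is the
ADICT signature.

Also here: the Welch/Mann-Whitney comparison of conservation scores between
old- and young-biased genes, percentile bootstrap CIs for mean relative
conservation scores, and the linear model controlling the class-conservation
difference for gene age and expression level.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from ._stats import spearman_columns, spearman_pvalue, spearman_with_p
from .errors import AnalysisError, ConfigurationError
from .normalize import ExpressionDataset


@dataclass
class ADICTResult:
    """Spearman correlation of per-unit ec_rho against age."""

    rho_adict: float
    p_adict: float
    n_units: int
    degenerate: bool = False  # ec_rho constant across units; rho undefined

    def to_dict(self) -> dict:
        return asdict(self)


def _retained_cs(cons: pd.DataFrame) -> pd.Series:
    r = cons.loc[~cons["excluded"]]
    return pd.Series(r["cs"].values, index=r["gene_id"].values)


def sample_ec_correlation(
    expr_column: pd.Series, cons: pd.DataFrame, gene_subset=None
) -> tuple[float, int]:
    """Expression-conservation Spearman rho for one unit.

    Returns (ec_rho, n_genes) over the intersection of the unit's genes, the
    retained (scored) genes, and ``gene_subset`` when given.
    """
    cs = _retained_cs(cons)
    genes = expr_column.index.intersection(cs.index)
    if gene_subset is not None:
        genes = genes.intersection(pd.Index(gene_subset))
    if len(genes) < 3:
        raise AnalysisError(
            f"only {len(genes)} genes shared between expression and conservation "
            "table; need at least 3"
        )
    rho, _ = spearman_with_p(expr_column.loc[genes].values, cs.loc[genes].values)
    return rho, len(genes)


def conservation_profiles(
    expr: ExpressionDataset,
    cons: pd.DataFrame,
    gene_subset=None,
    gene_set_used: str = "whole_transcriptome",
) -> pd.DataFrame:
    """Per-sample expression-conservation correlations (one row per unit)."""
    cs = _retained_cs(cons)
    genes = expr.gene_ids.intersection(cs.index)
    if gene_subset is not None:
        genes = genes.intersection(pd.Index(gene_subset))
    if len(genes) < 3:
        raise AnalysisError("fewer than 3 genes shared with the conservation table")
    ec = spearman_columns(expr.values.loc[genes].values, cs.loc[genes].values)
    return pd.DataFrame(
        {
            "unit_id": expr.sample_ids,
            "age": expr.sample_age.values,
            "ec_rho": ec,
            "gene_set_used": gene_set_used,
            "n_genes": len(genes),
        }
    )


def adict_statistic(profiles: pd.DataFrame) -> ADICTResult:
    """Correlate per-unit ec_rho with age across units."""
    df = profiles.dropna(subset=["ec_rho", "age"])
    n = len(df)
    if n < 3:
        raise AnalysisError(f"need at least 3 units for the ADICT statistic, got {n}")
    ec = df["ec_rho"].values
    if np.ptp(ec) == 0:
        return ADICTResult(np.nan, np.nan, n, degenerate=True)
    rho, p = spearman_with_p(ec, df["age"].values)
    return ADICTResult(rho, p, n)


def compare_class_conservation(cons: pd.DataFrame, classes: pd.DataFrame) -> dict:
    """Welch t and Mann-Whitney U on conservation scores, old vs young genes."""
    cs = _retained_cs(cons)
    groups = {}
    for lab in ("old_biased", "young_biased"):
        genes = classes.index[classes["label"] == lab].intersection(cs.index)
        if len(genes) < 2:
            raise AnalysisError(f"class {lab} has fewer than 2 scored genes")
        groups[lab] = cs.loc[genes].values
    old, young = groups["old_biased"], groups["young_biased"]
    t = stats.ttest_ind(old, young, equal_var=False)
    exact = max(len(old), len(young)) <= 8
    u = stats.mannwhitneyu(
        old, young, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return {
        "n_old": len(old),
        "n_young": len(young),
        "mean_cs_old": float(np.mean(old)),
        "mean_cs_young": float(np.mean(young)),
        "mean_difference": float(np.mean(old) - np.mean(young)),
        "welch_t": float(t.statistic),
        "welch_p": float(t.pvalue),
        "mannwhitney_u": float(u.statistic),
        "mannwhitney_p": float(u.pvalue),
    }


def bootstrap_mean_rcs(
    cons: pd.DataFrame,
    gene_set,
    B: int = 1000,
    ci: float = 0.95,
    seed: int | None = None,
) -> dict:
    """Percentile bootstrap CI for the mean relative conservation score."""
    if B < 100:
        raise ConfigurationError("B must be at least 100")
    if seed is None:
        raise ConfigurationError("a seed is required for bootstrap resampling")
    r = cons.loc[~cons["excluded"]]
    vals = r.loc[r["gene_id"].isin(set(gene_set)), "rcs"].dropna().values
    n = len(vals)
    if n < 2:
        raise AnalysisError(f"gene set has only {n} scored genes; need at least 2")
    rng = np.random.default_rng(seed)
    means = vals[rng.integers(0, n, size=(B, n))].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return {
        "mean_rcs": float(vals.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_genes": n,
        "B": B,
        "ci": ci,
        "seed": seed,
    }


def confound_model(gene_table: pd.DataFrame, expression: str = "mean") -> dict:
    """OLS of dN/dS on expression level, gene age, and age-bias class.

    ``gene_table`` needs columns ``omega`` (dN/dS), ``gene_age``, a class
    column ``label`` restricted to old_biased/young_biased, and
    ``mean_expr`` / ``max_expr`` depending on ``expression``.
    """
    if expression not in ("mean", "max"):
        raise ConfigurationError("expression must be 'mean' or 'max'")
    col = f"{expression}_expr"
    df = gene_table.dropna(subset=["omega", "gene_age", col, "label"]).copy()
    df = df[df["label"].isin(["old_biased", "young_biased"])]
    if len(df) < 20:
        raise AnalysisError(f"need at least 20 classified genes, got {len(df)}")
    df["is_old"] = (df["label"] == "old_biased").astype(float)
    for pred in (col, "gene_age", "is_old"):
        if df[pred].nunique() < 2:
            raise AnalysisError(f"predictor {pred!r} is constant")
    fit = smf.ols(f"omega ~ {col} + gene_age + is_old", data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise AnalysisError("design matrix is rank-deficient (collinear predictors)")
    return {
        "expression_variant": expression,
        "n_genes": int(fit.nobs),
        "coefficients": {k: float(v) for k, v in fit.params.items()},
        "std_errors": {k: float(v) for k, v in fit.bse.items()},
        "p_values": {k: float(v) for k, v in fit.pvalues.items()},
        "class_coefficient": float(fit.params["is_old"]),
        "class_p": float(fit.pvalues["is_old"]),
        "r_squared": float(fit.rsquared),
    }
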