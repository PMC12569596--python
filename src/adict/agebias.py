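"""Age-bias classification of genes from age-series expression.

Each expressed gene gets a Spearman correlation between its expression and
sample age. Three classification modes cover the three data situations:

- ``bulk``: age-related iff BH-adjusted p < q_cutoff AND |rho| > rho_cutoff
  (replicated bulk RNA-seq designs);
- ``single_cell``: |rho| > rho_cutoff only (noisier pseudobulk series);
- ``sign_only``: label by the sign of rho alone (unreplicated designs).

The sign of rho decides old-biased (positive) versus young-biased (negative);
everything else — including flat genes, for which rho is undefined — is
"constantly expressed".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import benjamini_hochberg, spearman_pvalue, spearman_rows
from .errors import AnalysisError, ConfigurationError
from .normalize import ExpressionDataset

MODES = ("bulk", "single_cell", "sign_only")


def expression_age_correlation(expr: ExpressionDataset) -> pd.DataFrame:
    """Per-gene Spearman rho and two-sided p of expression versus age."""
    if not expr.is_normalized:
        raise AnalysisError("expression must be normalized before classification")
    ages = expr.sample_age.values
    if expr.values.shape[1] < 2:
        raise AnalysisError("need at least two samples")
    if np.all(ages == ages[0]):
        raise AnalysisError("all sample ages are identical; no age axis to correlate")
    rho = spearman_rows(expr.values.values, ages)
    p = spearman_pvalue(rho, len(ages))
    return pd.DataFrame(
        {"rho_age": rho, "p_age": np.asarray(p, dtype=float)}, index=expr.gene_ids
    )


def classify_genes(
    stats: pd.DataFrame,
    mode: str = "bulk",
    rho_cutoff: float = 0.5,
    q_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Label genes old_biased / young_biased / constant.

    ``stats`` must carry ``rho_age`` and (for bulk mode) ``p_age`` columns as
    returned by :func:`expression_age_correlation`.
    """
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}, got {mode!r}")
    if not 0 < rho_cutoff < 1:
        raise ConfigurationError(f"rho_cutoff must lie in (0, 1), got {rho_cutoff}")
    out = stats.copy()
    rho = out["rho_age"].values
    out["q_age"] = benjamini_hochberg(out["p_age"].values) if "p_age" in out else np.nan
    if mode == "bulk":
        related = (out["q_age"].values < q_cutoff) & (np.abs(rho) > rho_cutoff)
    elif mode == "single_cell":
        related = np.abs(rho) > rho_cutoff
    else:  # sign_only: any nonzero monotone trend counts
        related = np.isfinite(rho) & (rho != 0)
    related = related & np.isfinite(rho)
    label = np.where(related & (rho > 0), "old_biased",
                     np.where(related & (rho < 0), "young_biased", "constant"))
    out["label"] = label
    out["mode"] = mode
    return out


def class_gene_sets(classes: pd.DataFrame) -> dict[str, pd.Index]:
    """Gene ids per label; 'de' is the union of old- and young-biased genes."""
    sets = {
        lab: classes.index[classes["label"] == lab]
        for lab in ("old_biased", "young_biased", "constant")
    }
    sets["de"] = sets["old_biased"].union(sets["young_biased"])
    return sets


def write_classification(classes: pd.DataFrame, path) -> None:
    out = classes.reset_index(names="gene_id")
    out[["gene_id", "rho_age", "p_age", "q_age", "label", "mode"]].to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
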