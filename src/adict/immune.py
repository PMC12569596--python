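"""Immune contributions to the ADICT pattern.

Per cell type, the mean relative conservation scores (MRCS) of old- and
young-biased genes are compared (paired over cell types within a tissue),
immune versus non-immune cell types are compared on MRCS differences or
per-cell-type ADICT correlations (Mann-Whitney + Cohen's d, repeated cell
types collapsed to their cross-tissue mean), and immune-gene
overrepresentation among the low-conserved old-biased (resp. high-conserved
young-biased) genes is quantified with quartile-based odds ratios and Fisher
exact tests, BH-corrected across cell types.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import benjamini_hochberg, cohen_d
from .core import _retained_cs
from .errors import AnalysisError, InputError

logger = logging.getLogger(__name__)


def load_gene_list(path) -> set[str]:
    """Read a one-gene-per-line TSV (e.g. GO immune system process members)."""
    try:
        with open(path) as fh:
            genes = {line.split("\t")[0].strip() for line in fh if line.strip()}
    except OSError as exc:
        raise InputError(f"cannot read gene list {path!r}: {exc}") from exc
    if not genes:
        raise InputError(f"gene list {path!r} is empty")
    return genes


def _rcs_by_gene(cons: pd.DataFrame) -> pd.Series:
    r = cons.loc[~cons["excluded"]]
    return pd.Series(r["rcs"].values, index=r["gene_id"].values)


def mrcs_report(cons: pd.DataFrame, classes_by_celltype: dict) -> pd.DataFrame:
    """Mean RCS of old- and young-biased genes per (tissue, cell type)."""
    rcs = _rcs_by_gene(cons)
    rows = []
    for (tissue, ctype), classes in sorted(classes_by_celltype.items()):
        sets = {}
        for lab in ("old_biased", "young_biased"):
            genes = classes.index[classes["label"] == lab].intersection(rcs.index)
            sets[lab] = rcs.loc[genes].dropna()
        if any(s.empty for s in sets.values()):
            logger.info("skipping %s/%s: an age-bias class is empty", tissue, ctype)
            continue
        mo, my = sets["old_biased"].mean(), sets["young_biased"].mean()
        rows.append(
            {
                "tissue": tissue,
                "cell_type": ctype,
                "mrcs_old": float(mo),
                "mrcs_young": float(my),
                "mrcs_diff": float(my - mo),
                "n_old": len(sets["old_biased"]),
                "n_young": len(sets["young_biased"]),
            }
        )
    return pd.DataFrame(rows)


def paired_class_test(reports: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank on (mrcs_old, mrcs_young) paired by cell type.

    One two-sided p per tissue; below 5 pairs the exact small-sample method is
    used with a warning, and all-zero differences report p = 1 with a flag.
    """
    rows = []
    for tissue, tdf in reports.groupby("tissue", sort=True):
        old, young = tdf["mrcs_old"].values, tdf["mrcs_young"].values
        n = len(tdf)
        degenerate = bool(np.all(old == young))
        if degenerate:
            p = 1.0
        else:
            method = "exact"
            if n < 5:
                warnings.warn(
                    f"tissue {tissue!r}: only {n} cell-type pairs; exact small-sample p",
                    stacklevel=2,
                )
            res = stats.wilcoxon(old, young, alternative="two-sided", method=method,
                                 zero_method="wilcox")
            p = float(res.pvalue)
        rows.append({"tissue": tissue, "n_pairs": n, "p": p, "degenerate": degenerate})
    return pd.DataFrame(rows)


def immune_vs_nonimmune(
    values: pd.DataFrame, is_immune_cell: dict, value_col: str = "value"
) -> dict:
    """Compare a per-cell-type quantity between immune and non-immune types.

    ``values`` has columns cell_type, tissue and ``value_col`` (an MRCS
    difference or a per-cell-type ADICT rho). Cell types appearing in several
    tissues are collapsed to their cross-tissue mean before the two-sided
    Mann-Whitney test and Cohen's d.
    """
    agg = values.groupby("cell_type")[value_col].mean()
    immune_mask = agg.index.map(lambda ct: bool(is_immune_cell.get(ct, False)))
    groups = {True: agg[immune_mask].values, False: agg[~immune_mask].values}
    for flag, vals in groups.items():
        if len(vals) < 2:
            raise AnalysisError(
                f"{'immune' if flag else 'non-immune'} group has fewer than 2 cell types"
            )
    u = stats.mannwhitneyu(groups[True], groups[False], alternative="two-sided")
    return {
        "n_immune": len(groups[True]),
        "n_nonimmune": len(groups[False]),
        "mean_immune": float(groups[True].mean()),
        "mean_nonimmune": float(groups[False].mean()),
        "mannwhitney_u": float(u.statistic),
        "mannwhitney_p": float(u.pvalue),
        "cohen_d": cohen_d(groups[True], groups[False]),
    }


def immune_overrepresentation(
    classes_by_celltype: dict,
    cons: pd.DataFrame,
    immune_genes: set,
    quartile: float = 0.25,
    min_class_genes: int = 20,
) -> pd.DataFrame:
    """Odds ratios for immune-gene prevalence in ADICT-driving gene sets.

    Per cell type and direction: among old-biased genes, the bottom-quartile
    (by conservation score, inclusive threshold) versus the rest is crossed
    with immune membership; among young-biased genes the top quartile is used.
    Quartile boundaries come from that cell type's expressed, scored genes.
    Sample odds ratio ad/bc (0 or inf on zero cells, flagged), two-sided
    Fisher exact p, BH across cell types within each direction.
    """
    cs = _retained_cs(cons)
    rows = []
    for (tissue, ctype), classes in sorted(classes_by_celltype.items()):
        scored = classes.index.intersection(cs.index)
        if len(scored) < 4:
            continue
        scores = cs.loc[scored]
        lo, hi = np.quantile(scores.values, [quartile, 1.0 - quartile])
        for direction, lab in (("old_biased", "old_biased"), ("young_biased", "young_biased")):
            genes = classes.index[classes["label"] == lab].intersection(scored)
            if len(genes) < min_class_genes:
                continue
            in_tail = (
                scores.loc[genes] <= lo if direction == "old_biased" else scores.loc[genes] >= hi
            )
            imm = genes.isin(immune_genes)
            a = int((in_tail.values & imm).sum())        # immune, tail
            b = int((in_tail.values & ~imm).sum())       # non-immune, tail
            c = int((~in_tail.values & imm).sum())       # immune, rest
            d = int((~in_tail.values & ~imm).sum())      # non-immune, rest
            degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
            if degenerate:
                odds = np.nan
            elif b * c == 0:
                odds = np.inf
            else:
                odds = (a * d) / (b * c)
            p = np.nan if degenerate else float(
                stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            )
            rows.append(
                {
                    "tissue": tissue,
                    "cell_type": ctype,
                    "direction": direction,
                    "a": a, "b": b, "c": c, "d": d,
                    "odds_ratio": odds,
                    "fisher_p": p,
                    "degenerate": degenerate,
                }
            )
    if not rows:
        raise AnalysisError("no cell type has enough classified, scored genes")
    out = pd.DataFrame(rows)
    out["bh_q"] = np.nan
    for direction, idx in out.groupby("direction").groups.items():
        out.loc[idx, "bh_q"] = benjamini_hochberg(out.loc[idx, "fisher_p"].values)
    return out
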