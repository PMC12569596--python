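"""Gene-wise sequence conservation scores from dN/dS divergence tables.

The conservation score of a gene is CS = -ln(dN/dS): under purifying selection
dN/dS < 1 and CS > 0, with larger values for more strongly conserved genes.
Genes under putative positive selection (dN/dS >= 0.8), genes where the ratio
is zero or infinite (dN = 0 or dS = 0), and genes with unreliable orthology
(non-one-to-one orthologs, paralog-bearing genes) are excluded rather than
scored. The relative conservation score RCS centres CS on the mean score of
constantly expressed genes of the same dataset, so RCS = 0 means "as conserved
as a typical age-constant gene".
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: exclusion reasons in decreasing precedence (orthology before ratio pathology
#: before threshold); exactly one reason is recorded per excluded gene.
EXCLUSION_PRECEDENCE = ("not_one2one", "has_paralog", "zero_dS", "zero_dN", "high_omega")

_REQUIRED = ("gene_id", "dN", "dS")


def load_divergence_table(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a per-gene divergence TSV (BioMart-style export).

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        Optional mapping from the file's column names to the canonical names
        ``gene_id, dN, dS, is_one2one, has_paralog`` (or ``omega`` for inputs
        that ship a precomputed dN/dS ratio without separate dN and dS, as for
        the killifish branch estimates).

    Returns
    -------
    DataFrame with canonical columns. Rows whose numeric fields fail to parse
    are dropped with a logged count.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read divergence table {path!r}: {exc}") from exc
    if dialect:
        df = df.rename(columns=dict(dialect))
    has_omega = "omega" in df.columns
    required = ("gene_id", "omega") if has_omega else _REQUIRED
    for col in required:
        if col not in df.columns:
            raise ConfigurationError(
                f"divergence table is missing required column {col!r} "
                f"(available: {list(df.columns)}; use a dialect mapping)"
            )
    if df.empty:
        raise InputError(f"divergence table {path!r} has no data rows")
    numeric = ["omega"] if has_omega else ["dN", "dS"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[numeric].isna().any(axis=1)
    if bad.any():
        logger.warning("dropped %d rows with unparseable numeric values", int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise InputError(f"divergence table {path!r} has no parseable rows")
    for col, default in (("is_one2one", True), ("has_paralog", False)):
        if col in df.columns:
            df[col] = (
                df[col].astype(str).str.strip().str.lower().isin(("1", "true", "yes", "t"))
            )
        else:
            df[col] = default
    if not has_omega:
        df["omega"] = np.nan
    else:
        df["dN"] = np.nan
        df["dS"] = np.nan
    keep = ["gene_id", "dN", "dS", "omega", "is_one2one", "has_paralog"]
    return df[keep].reset_index(drop=True)


def compute_conservation_scores(
    div: pd.DataFrame,
    omega_max: float = 0.8,
    require_one2one: bool = True,
    drop_paralogs: bool = True,
) -> pd.DataFrame:
    """Score genes with CS = -ln(dN/dS), excluding unreliable ratios.

    Every input gene appears exactly once in the output, either retained with
    a finite ``cs`` or excluded with a single ``exclusion_reason``. The
    threshold is closed: dN/dS >= ``omega_max`` is excluded (reason
    ``high_omega``). When a precomputed ``omega`` column is supplied (no dN,
    dS), the zero_dN/zero_dS checks cannot be evaluated and are skipped.
    """
    if omega_max <= 0:
        raise ConfigurationError(f"omega_max must be positive, got {omega_max}")
    if div.empty:
        raise InputError("divergence table is empty")
    df = div.copy().reset_index(drop=True)
    if "omega" not in df.columns:
        df["omega"] = np.nan
    precomputed = df["omega"].notna() & df.get("dN", pd.Series(np.nan, index=df.index)).isna()
    for col in ("dN", "dS"):
        if col not in df.columns:
            df[col] = np.nan
    if ((df["dN"] < 0) | (df["dS"] < 0)).any():
        raise InputError("dN and dS must be non-negative")

    reason = pd.Series("none", index=df.index, dtype=object)

    def mark(mask: pd.Series, why: str) -> None:
        mask = mask & (reason == "none")
        reason[mask] = why

    # precedence: orthology problems invalidate the ratio before its value does
    if require_one2one and "is_one2one" in df.columns:
        mark(~df["is_one2one"].astype(bool), "not_one2one")
    if drop_paralogs and "has_paralog" in df.columns:
        mark(df["has_paralog"].astype(bool), "has_paralog")
    mark(~precomputed & (df["dS"] == 0), "zero_dS")
    mark(~precomputed & (df["dN"] == 0), "zero_dN")
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(precomputed, df["omega"], df["dN"] / df["dS"])
    # closed threshold with a relative tolerance so exact ratios like
    # 0.08/0.10 land on the boundary despite floating-point rounding
    at_or_above = omega >= omega_max * (1.0 - 1e-12)
    mark(pd.Series(at_or_above, index=df.index).fillna(False), "high_omega")

    excluded = reason != "none"
    cs = np.full(len(df), np.nan)
    keep = ~excluded.values & np.isfinite(omega) & (omega > 0)
    cs[keep] = -np.log(omega[keep])
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "dN": df["dN"],
            "dS": df["dS"],
            "omega": np.where(excluded, omega, omega),
            "cs": cs,
            "rcs": np.nan,
            "excluded": excluded,
            "exclusion_reason": reason,
        }
    )
    logger.info(
        "conservation scoring: %d genes in, %d retained, %d excluded",
        len(out), int((~excluded).sum()), int(excluded.sum()),
    )
    return out


def relative_conservation(cons: pd.DataFrame, constant_genes: Iterable[str]) -> pd.DataFrame:
    """Centre conservation scores on the mean CS of constantly expressed genes.

    ``rcs_i = cs_i - mean(cs over constant_genes ∩ retained)``; the mean RCS
    over that intersection is 0 by construction.
    """
    constant = set(constant_genes)
    retained = cons.loc[~cons["excluded"]]
    anchor = retained.loc[retained["gene_id"].isin(constant), "cs"]
    if anchor.empty:
        raise AnalysisError(
            "constant gene set does not overlap the retained conservation table"
        )
    out = cons.copy()
    out["rcs"] = out["cs"] - anchor.mean()
    return out


def write_conservation_table(cons: pd.DataFrame, path) -> None:
    cols = ["gene_id", "dN", "dS", "omega", "cs", "rcs", "excluded", "exclusion_reason"]
    cons[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
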