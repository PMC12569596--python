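"""Windowed Tajima's D and CDS-weighted gene-wise aggregation.

Tajima's D contrasts mean pairwise nucleotide diversity (pi) with the scaled
segregating-site count (S/a1); negative values indicate a singleton excess as
expected under purifying selection or population expansion. D is computed in
tiling, non-overlapping 10 kb windows (0-based half-open), and per-gene D is
the mean of overlapping window values weighted by the CDS overlap length in
base pairs. Both pi and S are invariant to folding the frequency spectrum, so
alternate-allele counts are used as-is.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigurationError, InputError

logger = logging.getLogger(__name__)


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> dict:
    """The a1..e2 constants of the D variance normalisation for n chromosomes."""
    if n < 4:
        raise ConfigurationError(f"need at least 4 chromosomes, got {n}")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, pi: float, n: int) -> float:
    """D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)); undefined (NaN) for S = 0."""
    if S == 0:
        return np.nan
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi - S / k["a1"]) / np.sqrt(var))


def load_vcf(path, samples=None) -> tuple[pd.DataFrame, int]:
    """Read biallelic SNPs from a VCF into (chrom, pos, alt_count) rows.

    Positions stay 1-based as in the file. Sites with any missing genotype are
    dropped (counted and logged), as are non-SNP and multiallelic records.
    Returns the variant table and the haplotype sample size (2 x diploids).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), samples=samples)
    except OSError as exc:
        raise InputError(f"cannot read VCF {path!r}: {exc}") from exc
    rows, n_missing, n_skipped = [], 0, 0
    n_chrom = 2 * len(vcf.samples)
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            n_skipped += 1
            continue
        gt = np.array(v.genotypes)[:, :2]
        if (gt < 0).any():
            n_missing += 1
            continue
        rows.append((v.CHROM, v.POS, int(gt.sum())))
    if n_missing or n_skipped:
        logger.info("VCF: dropped %d sites with missing calls, %d non-biallelic-SNP",
                    n_missing, n_skipped)
    if not rows:
        raise InputError(f"VCF {path!r} contains no usable biallelic SNPs")
    return pd.DataFrame(rows, columns=["chrom", "pos", "alt_count"]), n_chrom


def window_tajimas_d(
    variants: pd.DataFrame,
    n_chromosomes: int,
    window: int = 10_000,
    step: int | None = None,
) -> pd.DataFrame:
    """Tajima's D per tiling window.

    ``variants`` carries chrom, pos (1-based), alt_count columns. Monomorphic
    rows (count 0 or n) are dropped with a logged count. Windows tile
    [0, window), [window, 2*window) ... per chromosome up to the last window
    holding a site; windows without segregating sites get D = NaN.
    """
    if n_chromosomes < 4:
        raise ConfigurationError("n_chromosomes must be at least 4")
    step = window if step is None else step
    if step != window:
        raise ConfigurationError("only tiling windows (step == window) are supported")
    n = n_chromosomes
    df = variants.copy()
    mono = (df["alt_count"] <= 0) | (df["alt_count"] >= n)
    if mono.any():
        logger.info("dropped %d monomorphic variant rows", int(mono.sum()))
        df = df[~mono]
    if df.empty:
        raise InputError("no segregating sites after filtering")
    df["win"] = (df["pos"].astype(int) - 1) // window  # VCF 1-based -> 0-based
    j = df["alt_count"].astype(float)
    df["pi_site"] = 2.0 * j * (n - j) / (n * (n - 1))
    rows = []
    for chrom, cdf in df.groupby("chrom", sort=True):
        agg = cdf.groupby("win").agg(S=("pos", "size"), pi=("pi_site", "sum"))
        for w in range(int(agg.index.max()) + 1):
            if w in agg.index:
                S, pi = int(agg.loc[w, "S"]), float(agg.loc[w, "pi"])
            else:
                S, pi = 0, 0.0
            rows.append(
                {
                    "chrom": chrom,
                    "start": w * window,
                    "end": (w + 1) * window,
                    "S": S,
                    "pi": pi,
                    "D": tajimas_d(S, pi, n),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_chromosomes"] = n
    out.attrs["window"] = window
    return out


def load_bed(path) -> pd.DataFrame:
    """Read CDS intervals from BED (0-based half-open; name = gene_id)."""
    try:
        bed = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene_id"],
        )
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read BED {path!r}: {exc}") from exc
    if bed.empty:
        raise InputError(f"BED {path!r} is empty")
    if (bed["start"] >= bed["end"]).any():
        raise InputError("malformed BED: start >= end")
    return bed


def gene_tajima(track: pd.DataFrame, cds: pd.DataFrame, window: int | None = None) -> pd.DataFrame:
    """Per-gene D as the CDS-overlap-bp-weighted mean of window D values.

    Only windows with defined D contribute; a gene overlapping no such window
    gets a missing D_gene. Weights are the number of CDS base pairs of the
    gene falling inside each window, summed across (possibly multiple) CDS
    intervals.
    """
    window = window or track.attrs.get("window") or int(
        (track["end"] - track["start"]).iloc[0]
    )
    dmap = {
        (r.chrom, int(r.start) // window): r.D
        for r in track.itertuples()
        if np.isfinite(r.D)
    }
    acc: dict[str, dict] = {}
    for r in cds.itertuples():
        g = acc.setdefault(r.gene_id, {"wd": 0.0, "w": 0.0, "wins": set()})
        for w in range(int(r.start) // window, (int(r.end) - 1) // window + 1):
            ov = min(int(r.end), (w + 1) * window) - max(int(r.start), w * window)
            if ov <= 0 or (r.chrom, w) not in dmap:
                continue
            g["wd"] += ov * dmap[(r.chrom, w)]
            g["w"] += ov
            g["wins"].add((r.chrom, w))
    rows = []
    for gene, g in sorted(acc.items()):
        rows.append(
            {
                "gene_id": gene,
                "D_gene": g["wd"] / g["w"] if g["w"] > 0 else np.nan,
                "overlap_bp": int(g["w"]),
                "n_windows": len(g["wins"]),
            }
        )
    return pd.DataFrame(rows)


def compare_tajima_classes(
    gene_d: pd.DataFrame | dict[str, pd.DataFrame], classes: pd.DataFrame
) -> pd.DataFrame:
    """Mann-Whitney on gene-wise D, old- vs young-biased, per population.

    ``gene_d`` is a per-gene table or a {population: table} mapping; a pooled
    row (mean D per gene across populations) is always included.
    """
    if isinstance(gene_d, pd.DataFrame):
        gene_d = {"pooled": gene_d}
    tables = dict(gene_d)
    if "pooled" not in tables:
        allpop = pd.concat(tables.values())
        tables["pooled"] = (
            allpop.groupby("gene_id", as_index=False)
            .agg(D_gene=("D_gene", "mean"), overlap_bp=("overlap_bp", "max"),
                 n_windows=("n_windows", "max"))
        )
    labels = classes["label"]
    rows = []
    for pop, tab in tables.items():
        d = tab.dropna(subset=["D_gene"]).set_index("gene_id")["D_gene"]
        old = d.loc[d.index.intersection(labels.index[labels == "old_biased"])]
        young = d.loc[d.index.intersection(labels.index[labels == "young_biased"])]
        if len(old) < 2 or len(young) < 2:
            raise AnalysisError(
                f"population {pop!r}: an age-bias class has <2 genes with defined D"
            )
        u = stats.mannwhitneyu(old.values, young.values, alternative="two-sided")
        rows.append(
            {
                "population": pop,
                "n_old": len(old),
                "n_young": len(young),
                "median_D_old": float(old.median()),
                "median_D_young": float(young.median()),
                "mannwhitney_u": float(u.statistic),
                "p": float(u.pvalue),
            }
        )
    return pd.DataFrame(rows)
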