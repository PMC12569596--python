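"""Median-of-ratios normalization of raw count matrices.

Per-sample size factors are the median, over genes positive in every sample,
of the ratio of a sample's counts to the per-gene geometric-mean reference —
the classic library-size estimator for count RNA-seq data. Genes not expressed
in any sample are discarded after normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with per-sample age/tissue labels."""

    values: pd.DataFrame  # genes (rows) x samples (columns)
    sample_age: pd.Series
    sample_tissue: pd.Series = field(default=None)
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.sample_age = pd.Series(self.sample_age, dtype=float).reindex(
            self.values.columns
        )
        if self.sample_age.isna().any():
            raise InputError("every sample needs a finite age")
        if (self.sample_age <= 0).any():
            raise InputError("sample ages must be positive")
        if self.sample_tissue is None:
            self.sample_tissue = pd.Series("", index=self.values.columns)
        else:
            self.sample_tissue = pd.Series(self.sample_tissue).reindex(self.values.columns)

    @property
    def gene_ids(self):
        return self.values.index

    @property
    def sample_ids(self):
        return self.values.columns


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors via the median-of-ratios method.

    The reference for gene g is the geometric mean of its counts across
    samples, computed (in log space) over genes strictly positive in all
    samples; the factor for sample j is the median of counts_gj / reference_g.
    """
    if counts.shape[1] < 2:
        raise InputError("need at least two samples to estimate size factors")
    if (counts.values < 0).any():
        raise InputError("counts must be non-negative")
    positive = (counts.values > 0).all(axis=1)
    if not positive.any():
        raise AnalysisError(
            "no gene has strictly positive counts in every sample; "
            "pre-filter the matrix before normalization"
        )
    logc = np.log(counts.values[positive].astype(float))
    log_ref = logc.mean(axis=1)
    factors = np.exp(np.median(logc - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    sample_age=None,
    sample_tissue=None,
) -> ExpressionDataset:
    """Divide each sample by its size factor and drop all-zero genes."""
    sf = pd.Series(size_factors).reindex(counts.columns)
    if sf.isna().any():
        raise InputError("size factors must cover every sample")
    if (sf <= 0).any():
        raise InputError("size factors must be strictly positive")
    values = counts / sf
    expressed = (values != 0).any(axis=1)
    dropped = int((~expressed).sum())
    if dropped:
        logger.info("dropped %d genes not expressed in any sample", dropped)
    if sample_age is None:
        sample_age = pd.Series(1.0, index=counts.columns)
    return ExpressionDataset(
        values=values.loc[expressed],
        sample_age=sample_age,
        sample_tissue=sample_tissue,
        is_normalized=True,
    )


def load_counts(path) -> pd.DataFrame:
    """Read a TSV count matrix: gene rows, sample columns, header row."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read count matrix {path!r}: {exc}") from exc
    if df.empty:
        raise InputError(f"count matrix {path!r} is empty")
    return df


def load_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV with at least sample_id and age columns."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read sample metadata {path!r}: {exc}") from exc
    for col in ("sample_id", "age"):
        if col not in df.columns:
            raise InputError(f"sample metadata is missing column {col!r}")
    return df.set_index("sample_id")
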