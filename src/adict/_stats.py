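"""Shared rank-statistic helpers.

Spearman correlations are computed from average ranks with the t-distribution
approximation for the two-sided p-value; vectorised variants rank a whole
matrix at once so per-sample and per-gene sweeps stay cheap.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of X with y; NaN for zero variance."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def spearman_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of each column of ``X`` (n_obs x n_vars) against ``y``."""
    Xr = stats.rankdata(X, axis=0)
    yr = stats.rankdata(y)
    return _pearson_columns(Xr, yr)


def spearman_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of each row of ``X`` (n_vars x n_obs) against ``y``."""
    return spearman_columns(X.T, y)


def spearman_pvalue(rho: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-sided p-value for Spearman rho via the t approximation (df = n-2)."""
    rho = np.asarray(rho, dtype=float)
    p = np.full(rho.shape, np.nan)
    if n >= 3:
        ok = np.isfinite(rho)
        r = rho[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
        pv = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pv[np.isclose(np.abs(r), 1.0)] = 0.0
        p[ok] = np.minimum(pv, 1.0)
    return p if p.ndim else float(p)


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided t-approximation p for two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = float(spearman_columns(x[:, None], y)[0])
    return rho, float(spearman_pvalue(rho, len(x)))


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (q-values); NaNs pass through untouched."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise InputError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def cohen_d(a, b) -> float:
    """Cohen's d with the pooled-variance denominator (n1 + n2 - 2 df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    return float((a.mean() - b.mean()) / np.sqrt(pooled))
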