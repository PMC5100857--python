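"""Expression specificity and the statistical machinery of the analysis:
Pearson and first-order partial correlation, Ks-binned trends, Welch
t-tests, proportion and Fisher tests, BH FDR, and Ks-to-age conversion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EntropyResult",
    "shannon_specificity",
    "pearson",
    "partial_correlation",
    "ks_binned_trend",
    "two_sample_t",
    "two_proportion_cc",
    "fisher_exact",
    "bh_fdr",
    "age_from_ks",
    "log_transform_fpkm",
]

logger = logging.getLogger(__name__)


@dataclass
class EntropyResult:
    H: float            # Shannon entropy, bits
    specificity: float  # 1 - H/log2(N)
    N: int


def shannon_specificity(fpkm_vector) -> EntropyResult:
    """Shannon entropy (bits) and specificity of an expression vector.

    P_i = g_i / g_sum; H = -sum P_i log2 P_i (0 log 0 := 0);
    specificity = 1 - H/log2(N).  An all-zero vector yields NaN (the
    gene is excluded downstream).
    """
    v = np.asarray(fpkm_vector, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two samples")
    if (v < 0).any():
        raise ValueError("FPKM values must be non-negative")
    total = v.sum()
    n = v.size
    if total == 0:
        return EntropyResult(math.nan, math.nan, n)
    p = v / total
    nz = p > 0
    H = float(-(p[nz] * np.log2(p[nz])).sum())
    return EntropyResult(H, 1.0 - H / math.log2(n), n)


def _drop_missing(*arrays):
    cols = [np.asarray(a, dtype=float) for a in arrays]
    ok = np.ones(cols[0].shape, dtype=bool)
    for c in cols:
        ok &= np.isfinite(c)
    return [c[ok] for c in cols]


def pearson(x, y):
    """Pearson correlation with two-sided t-based p-value.

    Pairs with a missing value in either variable are dropped listwise.
    Zero variance in either variable raises ``ValueError``.
    """
    x, y = _drop_missing(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def partial_correlation(x, y, z):
    """First-order partial correlation r_xy.z with a t test on n-3 df.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    """
    x, y, z = _drop_missing(x, y, z)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete observations")
    r_xy = sps.pearsonr(x, y)[0]
    r_xz = sps.pearsonr(x, z)[0]
    r_yz = sps.pearsonr(y, z)[0]
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 1e-24:
        raise ValueError("a control correlation is +/-1; partial correlation undefined")
    r = (r_xy - r_xz * r_yz) / math.sqrt(denom)
    r = min(1.0, max(-1.0, r))
    df = n - 3
    if abs(r) == 1.0:
        return float(r), 0.0
    t = r * math.sqrt(df / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), df)
    return float(r), float(p)


def ks_binned_trend(ks_values, metric_values, n_bins: int = 20, method: str = "quantile"):
    """Bin a per-pair metric into Ks groups and correlate the bin means.

    Pairs with missing values are dropped; bins are equal-count Ks
    quantiles (equal-width available via ``method="width"``).  Each bin
    reports its mean Ks, mean metric, 95% CI (mean +/- 1.96 SE) and
    count; the trend is the Pearson correlation across bin means.

    Returns (bin_table, trend_r, trend_p); the trend is (NaN, NaN) when
    the metric is constant.
    """
    ks, val = _drop_missing(ks_values, metric_values)
    if ks.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} complete pairs, got {ks.size}")
    if method == "quantile":
        edges = np.unique(np.quantile(ks, np.linspace(0, 1, n_bins + 1)))
        if len(edges) - 1 < n_bins:
            logger.info("Ks ties collapsed %d bins to %d", n_bins, len(edges) - 1)
    elif method == "width":
        edges = np.linspace(ks.min(), ks.max(), n_bins + 1)
    else:
        raise ValueError(f"unknown binning method {method!r}")
    idx = np.clip(np.searchsorted(edges, ks, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        cnt = int(sel.sum())
        if cnt == 0:
            continue
        v = val[sel]
        mean = float(v.mean())
        se = float(v.std(ddof=1) / math.sqrt(cnt)) if cnt > 1 else math.nan
        rows.append(
            {
                "bin": b,
                "mean_ks": float(ks[sel].mean()),
                "mean_value": mean,
                "ci95_low": mean - 1.96 * se if cnt > 1 else math.nan,
                "ci95_high": mean + 1.96 * se if cnt > 1 else math.nan,
                "count": cnt,
            }
        )
    table = pd.DataFrame(rows)
    try:
        trend_r, trend_p = pearson(table["mean_ks"], table["mean_value"])
    except ValueError:
        trend_r, trend_p = math.nan, math.nan
    return table, trend_r, trend_p


def two_sample_t(a, b):
    """Welch two-sample t-test (two-sided): (t, df, p)."""
    a, = _drop_missing(a)
    b, = _drop_missing(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def two_proportion_cc(k1: int, n1: int, k2: int, n2: int):
    """Two-sample proportion test with Yates continuity correction.

    Chi-square on the 2x2 success/failure table, matching R's
    ``prop.test``.  Returns (chi2, p).
    """
    for v in (k1, n1, k2, n2):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if k1 > n1 or k2 > n2:
        raise ValueError("successes cannot exceed trials")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def fisher_exact(a: int, b: int, c: int, d: int):
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p); the p-value sums hypergeometric
    probabilities no larger than the observed table's.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    orat, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orat), float(p)


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.isnan(p).any():
        q = np.full(p.shape, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        return q
    return multipletests(p, method="fdr_bh")[1]


def age_from_ks(ks: float, rate_per_site_per_year: float = 4.13e-9, per_lineage: bool = False) -> float:
    """Convert Ks to an age in years given a silent-site substitution rate.

    Default follows the convention age = Ks / rate (a Ks-peak of 1.6 at
    4.13e-9 per site per year dates the teleost whole-genome duplication
    to ~387 MYA).  ``per_lineage=True`` uses Ks / (2 * rate), the
    pairwise convention where each lineage accumulates half the
    divergence.
    """
    if rate_per_site_per_year <= 0:
        raise ValueError("substitution rate must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    denom = 2 * rate_per_site_per_year if per_lineage else rate_per_site_per_year
    return ks / denom


def log_transform_fpkm(fpkm, offset: float = 1.0):
    """log2(FPKM + offset), the expression scale used for correlations."""
    return np.log2(np.asarray(fpkm, dtype=float) + offset)
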