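"""Noise filters and univariate GA screening.

Two sequential filters remove noisy or uninformative features before
modelling: a variance filter (drop features whose across-sample variance is
strictly below the 75th percentile of all feature variances) and a median
filter (drop features whose absolute across-sample median is strictly below
the median of those absolute medians).  Each per-feature statistic uses
conventional defaults — sample variance with an ``n - 1`` denominator and
the linear-interpolation quantile — so survivors are bit-reproducible.

Univariate screening computes, per feature, the Spearman rank correlation
with GA (tie-corrected, two-sided p from the t approximation) and
Benjamini-Hochberg adjusted false-discovery rates across all tested
features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyMatrixError, ValidationError
from .features import FeatureMatrix

__all__ = [
    "variance_filter",
    "median_filter",
    "preprocess",
    "spearman_univariate",
    "bh_fdr",
]


def variance_filter(X: FeatureMatrix | pd.DataFrame, q: float = 75.0) -> list:
    """Feature ids whose across-sample variance reaches the ``q``-th
    percentile of all feature variances.

    Features strictly below the (linearly interpolated) percentile are
    removed; ties with the threshold are kept.
    """
    values = X.values if isinstance(X, FeatureMatrix) else X
    if len(values) < 2:
        raise ValidationError("variance filter requires >= 2 samples")
    var = values.var(axis=0, ddof=1)
    threshold = np.percentile(var.to_numpy(), q)
    return list(var.index[var >= threshold])


def median_filter(X: FeatureMatrix | pd.DataFrame) -> list:
    """Feature ids whose absolute across-sample median reaches the median
    absolute median of all features.  Strictly smaller values are removed."""
    values = X.values if isinstance(X, FeatureMatrix) else X
    if len(values) < 1:
        raise ValidationError("median filter requires >= 1 sample")
    m = values.median(axis=0).abs()
    threshold = np.median(m.to_numpy())
    return list(m.index[m >= threshold])


def preprocess(
    X: FeatureMatrix, sequential: bool = True
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Apply the variance filter then the median filter.

    With ``sequential=True`` (default) the median filter's threshold is
    computed on the variance-filter survivors; with ``sequential=False``
    both filters are computed on the original matrix and the surviving set
    is the intersection.

    Returns the filtered matrix and a provenance log with one row per
    original feature (``kept`` flag and the removing stage).
    """
    keep_var = set(variance_filter(X))
    stage = {}
    for fid in X.feature_ids:
        if fid not in keep_var:
            stage[fid] = "variance"
    if sequential:
        Xv = X.subset([f for f in X.feature_ids if f in keep_var])
        keep_med = set(median_filter(Xv))
    else:
        keep_med = set(median_filter(X))
    survivors = [f for f in X.feature_ids if f in keep_var and f in keep_med]
    for fid in X.feature_ids:
        if fid in keep_var and fid not in keep_med:
            stage[fid] = "median"
    if not survivors:
        raise EmptyMatrixError("all features removed by pre-processing")
    log = pd.DataFrame(
        {
            "feature_id": X.feature_ids,
            "kept": [f in set(survivors) for f in X.feature_ids],
            "removed_by": [stage.get(f, "") for f in X.feature_ids],
        }
    ).set_index("feature_id")
    return X.subset(survivors), log


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the sorted p-values, capped
    at 1.  All inputs must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def spearman_univariate(
    X: FeatureMatrix | pd.DataFrame, ga, tiny: float = 1e-300
) -> pd.DataFrame:
    """Per-feature Spearman correlation with GA plus BH-adjusted FDR.

    Returns a DataFrame indexed by feature id with columns ``rho``, ``p``,
    ``q`` and ``direction`` (sign of rho).  Constant features have
    undefined rank correlation; they are reported with missing statistics
    and excluded from the FDR adjustment.
    """
    values = X.values if isinstance(X, FeatureMatrix) else X
    ga = np.asarray(ga, dtype=float)
    if len(values) != ga.size:
        raise ValidationError("feature matrix and GA vector are misaligned")
    if ga.size < 4:
        raise ValidationError("need at least 4 samples for rank correlation")

    n = ga.size
    ga_rank = stats.rankdata(ga)
    rho = np.full(values.shape[1], np.nan)
    pval = np.full(values.shape[1], np.nan)
    arr = values.to_numpy(float)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if np.all(col == col[0]):
            continue  # constant: rank correlation undefined
        r = np.corrcoef(stats.rankdata(col), ga_rank)[0, 1]
        rho[j] = r
        if abs(r) >= 1.0:
            pval[j] = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            pval[j] = 2.0 * stats.t.sf(abs(t), df=n - 2)

    tested = np.isfinite(pval)
    q = np.full(values.shape[1], np.nan)
    if tested.any():
        q[tested] = bh_fdr(np.clip(pval[tested], tiny, 1.0))
    out = pd.DataFrame(
        {
            "rho": rho,
            "p": pval,
            "q": q,
            "direction": np.sign(rho),
        },
        index=pd.Index(values.columns, name="feature_id"),
    )
    return out
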