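"""Preprocessing transforms on expression matrices.

The standard chain for a cohort is: handle missing values once at load,
log2-transform, quantile-normalize across samples (mRNA arrays), then
feature-wise z-scoring before clustering/classification.  Each step advances
the matrix ``scale_flag`` so illegal orderings fail loudly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, ScaleFlag

__all__ = [
    "handle_missing",
    "log2_transform",
    "quantile_normalize",
    "zscore_rows",
    "ZScoreReport",
    "median_split",
    "xenograft_volume",
]


def handle_missing(m: ExpressionMatrix, max_missing_frac: float = 0.2
                   ) -> ExpressionMatrix:
    """Apply the load-time missing-value policy.

    Features with more than ``max_missing_frac`` missing cells are dropped;
    remaining NAs are imputed with the feature median.
    """
    frac = np.isnan(m.values).mean(axis=1)
    keep = frac <= max_missing_frac
    dropped = [f for f, k in zip(m.feature_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} features with "
                      f">{max_missing_frac:.0%} missing: {dropped[:5]}")
    values = m.values[keep].copy()
    feature_ids = [f for f, k in zip(m.feature_ids, keep) if k]
    for i in range(values.shape[0]):
        row = values[i]
        nan = np.isnan(row)
        if nan.any():
            row[nan] = np.median(row[~nan])
    out = ExpressionMatrix(feature_ids, list(m.sample_ids), values,
                           platform=m.platform, scale_flag=m.scale_flag)
    return out


def log2_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """log2(v + offset); requires raw scale and positive arguments."""
    if m.scale_flag != ScaleFlag.raw:
        raise ValueError(f"log2_transform expects raw scale, got {m.scale_flag.value}")
    shifted = m.values + offset
    if np.nanmin(shifted) <= 0:
        raise ValueError("nonpositive values; supply a positive offset")
    return m.with_values(np.log2(shifted), scale_flag=ScaleFlag.log2)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common rank-mean distribution.

    After normalization each column's sorted values equal the per-rank mean
    across columns; within-column rank order is preserved.  Ties within a
    column receive the mean of the rank-means they span (the standard
    rank-mean tie convention).
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if np.isnan(m.values).any():
        raise ValueError("missing values present; run handle_missing first")
    v = m.values
    order = np.argsort(v, axis=0, kind="mergesort")
    sorted_vals = np.take_along_axis(v, order, axis=0)
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(v)
    csum = np.concatenate([[0.0], np.cumsum(rank_means)])
    for j in range(v.shape[1]):
        # each tie group gets the mean of the rank-means its span covers
        _, inv, counts = np.unique(v[:, j], return_inverse=True,
                                   return_counts=True)
        starts = np.concatenate([[0], np.cumsum(counts)])[:-1]
        group_mean = (csum[starts + counts] - csum[starts]) / counts
        out[:, j] = group_mean[inv]
    return m.with_values(out)


@dataclass
class ZScoreReport:
    dropped_features: list[str]


def zscore_rows(m: ExpressionMatrix, return_report: bool = False):
    """Standardize each feature row to mean 0 and sample (n-1) sd 1.

    Zero-variance features cannot be standardized; they are dropped and
    reported rather than silently zeroed.
    """
    if m.n_samples < 2:
        raise ValueError("z-scoring needs >= 2 samples per feature")
    mean = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    dropped = [f for f, k in zip(m.feature_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance features: "
                      f"{dropped[:5]}")
    z = (m.values[keep] - mean[keep]) / sd[keep]
    out = ExpressionMatrix([f for f, k in zip(m.feature_ids, keep) if k],
                           list(m.sample_ids), z, platform=m.platform,
                           scale_flag=ScaleFlag.zscore)
    if return_report:
        return out, ZScoreReport(dropped)
    return out


def median_split(values) -> np.ndarray:
    """Dichotomize at the median: value > median -> "high", <= median -> "low".

    Values equal to the median go to "low" (deterministic tie convention).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("median_split needs a 1-D vector of >= 2 values")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; no median split exists")
    med = np.median(values)
    return np.where(values > med, "high", "low")


def xenograft_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid-approximation tumor volume L * W^2 * 0.52 (mm^3).

    L is the longest diameter, W the shortest; callers passing W > L almost
    certainly swapped the arguments, so that is rejected.
    """
    if width_mm <= 0:
        raise ValueError("diameters must be positive")
    if width_mm > length_mm:
        raise ValueError("W > L: length must be the longest diameter")
    return length_mm * width_mm ** 2 * 0.52
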