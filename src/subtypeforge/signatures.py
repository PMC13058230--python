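"""Subtype-specific marker selection and related small statistics.

A feature is a subtype-s marker when, in *both* pairwise comparisons
involving s, the two-sample Student t-test is significant, the mean log2
difference clears the fold cutoff, and the direction relative to s agrees
(up in both or down in both).  Thresholds follow the platform: mRNA arrays
use p <= 0.001 with a 2-fold (1 log2 unit) difference, protein arrays use
p <= 0.01 with a 1.3-fold (~0.379 log2 unit) difference, reflecting the very
different feature counts of the two platforms.

No multiple-testing correction is applied to the selection itself (raw-p
thresholds are part of the procedure); a Benjamini-Hochberg adjusted column
is reported alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix

__all__ = [
    "students_t",
    "pairwise_subtype_tests",
    "SignatureSet",
    "select_subtype_markers",
    "select_dependent_genes",
    "pearson_correlation",
    "ddct_fold_change",
    "SubtypeMarkerSelector",
    "MRNA_THRESHOLDS",
    "PROTEIN_THRESHOLDS",
]

# platform defaults: (p cutoff, log2 fold cutoff)
MRNA_THRESHOLDS = (0.001, np.log2(2.0))
PROTEIN_THRESHOLDS = (0.01, np.log2(1.3))


def students_t(x, y) -> tuple[float, float, int]:
    """Classical pooled-variance two-sample t-test (two-sided).

    Returns (t, p, df) with df = n_x + n_y - 2.  Zero pooled variance with
    equal means degenerates to (0, 1); with unequal means the statistic is
    undefined and an error is raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0, df
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / x.size + 1 / y.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def _vectorized_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Row-wise pooled t-test between two feature x sample blocks."""
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=1, ddof=1)
           + (nb - 1) * b.var(axis=1, ddof=1)) / df
    delta = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(sp2 * (1 / na + 1 / nb))
    zero = sp2 == 0
    if zero.any():
        if (delta[zero] != 0).any():
            bad = np.flatnonzero(zero & (delta != 0))[0]
            raise ValueError(f"zero pooled variance with unequal means "
                             f"(feature index {bad})")
        t[zero] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[zero] = 1.0
    return t, p, df


def pairwise_subtype_tests(m: ExpressionMatrix | np.ndarray, labels,
                           feature_ids=None) -> pd.DataFrame:
    """All-pairs two-sample t-tests per feature across subtype groups.

    Returns a tidy frame with one row per (feature, unordered subtype pair):
    columns feature_id, a, b, t_stat, p_value, delta (mean_a - mean_b, log2
    scale), df.
    """
    if isinstance(m, ExpressionMatrix):
        x, feature_ids = m.values, m.feature_ids
    else:
        x = np.asarray(m, dtype=float)
        if feature_ids is None:
            feature_ids = [f"f{i}" for i in range(x.shape[0])]
    labels = np.asarray(labels)
    groups = sorted(np.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("need >= 2 subtype groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"subtype {g!r} has < 2 samples")
    frames = []
    for a, b in combinations(groups, 2):
        xa, xb = x[:, labels == a], x[:, labels == b]
        t, p, df = _vectorized_t(xa, xb)
        frames.append(pd.DataFrame({
            "feature_id": feature_ids, "a": a, "b": b,
            "t_stat": t, "p_value": p,
            "delta": xa.mean(axis=1) - xb.mean(axis=1), "df": df,
        }))
    out = pd.concat(frames, ignore_index=True)
    out["p_bh"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out


@dataclass
class SignatureSet:
    """Per-subtype marker features with directions and mean t-weights."""

    markers: dict[int, pd.DataFrame]  # subtype -> frame(feature_id, direction, mean_t)
    p_cut: float
    fold_cut_log2: float
    platform: str = "mrna"
    collisions: list[str] = field(default_factory=list)

    @property
    def subtypes(self) -> list[int]:
        return sorted(self.markers)

    def features_for(self, subtype) -> list[str]:
        return list(self.markers[subtype]["feature_id"])

    def all_features(self) -> list[str]:
        seen: list[str] = []
        for s in self.subtypes:
            seen.extend(self.features_for(s))
        return seen

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subtypes:
            df = self.markers[s].copy()
            df.insert(0, "subtype", s)
            rows.append(df)
        if not rows:
            return pd.DataFrame(columns=["subtype", "feature_id",
                                         "direction", "mean_t"])
        return pd.concat(rows, ignore_index=True)


def select_subtype_markers(results: pd.DataFrame, p_cut: float,
                           fold_cut_log2: float,
                           require_direction: bool = True) -> SignatureSet:
    """Apply the two-of-three rule to pairwise test results.

    A feature belongs to subtype s iff both comparisons involving s pass
    p <= p_cut and |delta| >= fold_cut_log2, with a consistent direction
    relative to s (unless ``require_direction`` is disabled).  A feature
    qualifying for several subtypes is assigned to the one with the smaller
    worst-case p, and the collision is recorded.
    """
    subtypes = sorted(set(results["a"]) | set(results["b"]))
    feature_ids = list(pd.unique(results["feature_id"]))
    candidates: dict[str, list[tuple[int, float, float, str]]] = {}
    for s in subtypes:
        # stack the comparisons involving s as (n_pairs, n_features) arrays,
        # with delta/t signed relative to s (positive = higher in s)
        p_rows, d_rows, t_rows = [], [], []
        for o in subtypes:
            if o == s:
                continue
            blk = results[((results["a"] == s) & (results["b"] == o))
                          | ((results["a"] == o) & (results["b"] == s))]
            blk = blk.set_index("feature_id").loc[feature_ids]
            sign = np.where(blk["a"].to_numpy() == s, 1.0, -1.0)
            p_rows.append(blk["p_value"].to_numpy())
            d_rows.append(blk["delta"].to_numpy() * sign)
            t_rows.append(blk["t_stat"].to_numpy() * sign)
        p = np.vstack(p_rows)
        d = np.vstack(d_rows)
        t = np.vstack(t_rows)
        ok = ((p <= p_cut) & (np.abs(d) >= fold_cut_log2)).all(axis=0)
        if require_direction:
            ok &= (np.sign(d) == np.sign(d[0])).all(axis=0)
        for i in np.flatnonzero(ok):
            direction = "up" if d[0, i] > 0 else "down"
            candidates.setdefault(feature_ids[i], []).append(
                (s, float(p[:, i].max()), float(t[:, i].mean()), direction))
    markers: dict[int, list[tuple[str, str, float]]] = {s: [] for s in subtypes}
    collisions = []
    for fid, hits in candidates.items():
        if len(hits) > 1:
            collisions.append(fid)
            hits = sorted(hits, key=lambda h: h[1])
        s, _, mean_t, direction = hits[0]
        markers[s].append((fid, direction, mean_t))
    frames = {
        s: pd.DataFrame(markers[s], columns=["feature_id", "direction", "mean_t"])
        for s in subtypes
    }
    return SignatureSet(frames, p_cut, fold_cut_log2, collisions=collisions)


def select_dependent_genes(control: np.ndarray, treated: np.ndarray,
                           p_cut: float = 0.001,
                           feature_ids=None) -> pd.DataFrame:
    """Genes whose expression differs between control and treated replicate
    arms at raw two-sided p <= p_cut (pooled t)."""
    control = np.atleast_2d(np.asarray(control, dtype=float))
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    if control.shape[1] < 2 or treated.shape[1] < 2:
        raise ValueError("need >= 2 replicates per arm")
    if feature_ids is None:
        feature_ids = [f"g{i}" for i in range(control.shape[0])]
    t, p, _ = _vectorized_t(treated, control)
    hit = p <= p_cut
    return pd.DataFrame({
        "feature_id": np.asarray(feature_ids)[hit],
        "t_stat": t[hit], "p_value": p[hit],
        "delta": (treated.mean(axis=1) - control.mean(axis=1))[hit],
    }).reset_index(drop=True)


def pearson_correlation(x, y) -> tuple[float, float, int]:
    """Pearson r with two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def ddct_fold_change(ct_target_treated: float, ct_ref_treated: float,
                     ct_target_control: float, ct_ref_control: float) -> float:
    """Comparative-Ct (delta-delta-Ct) qPCR fold change: 2^-ddCt."""
    ddct = ((ct_target_treated - ct_ref_treated)
            - (ct_target_control - ct_ref_control))
    return float(2.0 ** -ddct)


class SubtypeMarkerSelector(BaseEstimator):
    """Feature selector applying the two-of-three marker rule (sklearn API).

    ``fit(X, y)`` takes X of shape (n_samples, n_features) on log2 scale and
    subtype labels y; afterwards ``signature_`` holds the SignatureSet,
    ``support_`` a boolean mask over features and ``selected_features_``
    their names.
    """

    def __init__(self, p_cut: float = 0.001, fold_cut_log2: float = 1.0,
                 require_direction: bool = True, feature_names=None):
        self.p_cut = p_cut
        self.fold_cut_log2 = fold_cut_log2
        self.require_direction = require_direction
        self.feature_names = feature_names

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        names = (list(self.feature_names) if self.feature_names is not None
                 else [f"f{i}" for i in range(X.shape[1])])
        results = pairwise_subtype_tests(X.T, np.asarray(y), feature_ids=names)
        self.results_ = results
        self.signature_ = select_subtype_markers(
            results, self.p_cut, self.fold_cut_log2,
            require_direction=self.require_direction)
        chosen = set(self.signature_.all_features())
        self.support_ = np.array([n in chosen for n in names])
        self.selected_features_ = [n for n in names if n in chosen]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]
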