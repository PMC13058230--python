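"""Resampling-based consensus clustering with CDF-guided choice of k.

The procedure: for each candidate number of clusters k, repeatedly subsample
the cohort (80% of samples by default, all features), run agglomerative
hierarchical clustering (average linkage on 1 - Pearson correlation between
sample profiles), and record for every sample pair how often it was drawn
together and how often it co-clustered.  The consensus matrix M is the
elementwise ratio.  Crisp structure pushes consensus values to {0, 1}; the
mass left in the ambiguous middle of the empirical CDF of consensus values
(CDF(0.9) - CDF(0.1), the proportion-of-ambiguous-clustering statistic)
measures how far a given k is from that ideal, and the k with the flattest
CDF mid-section is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .io import ExpressionMatrix

__all__ = [
    "ConsensusMatrix",
    "ConsensusScan",
    "base_cluster",
    "build_consensus",
    "consensus_cdf",
    "ambiguity_score",
    "auc_and_delta",
    "select_optimal_k",
    "final_labels",
    "ConsensusCluster",
    "CDF_GRID",
]

# fixed evaluation grid for consensus CDFs: reproducible areas, data-independent
CDF_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)

AMBIGUITY_LOW_CONFIDENCE = 0.5


@dataclass
class ConsensusMatrix:
    """Pairwise consensus for one k: co-cluster counts over co-draw counts."""

    k: int
    M: np.ndarray
    pair_counts: np.ndarray
    co_counts: np.ndarray
    never_paired: np.ndarray = field(default=None)  # flag: pair never co-drawn
    resamples: Optional[list[tuple[np.ndarray, np.ndarray]]] = None

    def __post_init__(self) -> None:
        if self.never_paired is None:
            self.never_paired = self.pair_counts == 0
        if not np.allclose(self.M, self.M.T):
            raise ValueError("consensus matrix must be symmetric")
        if self.M.min() < 0 or self.M.max() > 1 + 1e-12:
            raise ValueError("consensus values must lie in [0, 1]")


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between columns of a feature x sample
    matrix.  Raises on constant sample profiles (correlation undefined)."""
    sd = x.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant sample profile: correlation distance undefined")
    corr = np.corrcoef(x, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return squareform(d, checks=False)


def base_cluster(x: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage hierarchical clustering of sample columns, cut to k.

    ``x`` is a feature x sample array; returns integer labels 0..k-1.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[1]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n} samples")
    d = _correlation_distance(x)
    z = linkage(d, method="average")
    return cut_tree(z, n_clusters=k).ravel()


def build_consensus(m: ExpressionMatrix | np.ndarray, k: int, n_resamples: int = 100,
                    subsample_fraction: float = 0.8, seed: int = 0,
                    keep_resamples: bool = False) -> ConsensusMatrix:
    """Consensus matrix from ``n_resamples`` subsampled clustering runs.

    Each resample draws ceil(fraction * n) samples without replacement and
    clusters them; a resample with fewer than k distinct profiles is redrawn
    (at most 10x the resample budget).  Deterministic for a fixed seed.
    """
    x = m.values if isinstance(m, ExpressionMatrix) else np.asarray(m, float)
    n = x.shape[1]
    if n_resamples < 1:
        raise ValueError("need >= 1 resample")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    n_draw = int(np.ceil(subsample_fraction * n))
    if n_draw < k:
        raise ValueError("subsample smaller than k")
    rng = np.random.default_rng(seed)
    pair_counts = np.zeros((n, n), dtype=int)
    co_counts = np.zeros((n, n), dtype=int)
    recorded: list[tuple[np.ndarray, np.ndarray]] = []
    done = 0
    attempts = 0
    while done < n_resamples:
        if attempts >= 10 * n_resamples:
            raise RuntimeError("too many degenerate resamples; giving up")
        attempts += 1
        idx = np.sort(rng.choice(n, size=n_draw, replace=False))
        sub = x[:, idx]
        if np.unique(sub, axis=1).shape[1] < k:
            continue  # redraw: not enough distinct profiles to form k groups
        labels = base_cluster(sub, k)
        pair_counts[np.ix_(idx, idx)] += 1
        same = labels[:, None] == labels[None, :]
        co_counts[np.ix_(idx, idx)] += same.astype(int)
        if keep_resamples:
            recorded.append((idx, labels))
        done += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(pair_counts > 0, co_counts / np.maximum(pair_counts, 1), 0.0)
    np.fill_diagonal(M, np.where(np.diag(pair_counts) > 0, 1.0, 0.0))
    return ConsensusMatrix(k=k, M=M, pair_counts=pair_counts,
                           co_counts=co_counts,
                           resamples=recorded if keep_resamples else None)


def consensus_cdf(cm: ConsensusMatrix | np.ndarray) -> np.ndarray:
    """Empirical CDF of the off-diagonal upper-triangle consensus values,
    evaluated on the fixed grid {0, 0.01, ..., 1}."""
    M = cm.M if isinstance(cm, ConsensusMatrix) else np.asarray(cm, float)
    n = M.shape[0]
    if n < 2:
        raise ValueError("need >= 2 samples")
    vals = M[np.triu_indices(n, k=1)]
    return (vals[None, :] <= CDF_GRID[:, None]).mean(axis=1)


def ambiguity_score(cdf_curve: np.ndarray) -> float:
    """CDF(0.9) - CDF(0.1): the proportion of sample pairs whose consensus is
    ambiguous (neither ~never nor ~always co-clustered)."""
    cdf_curve = np.asarray(cdf_curve, dtype=float)
    i01 = int(np.argmin(np.abs(CDF_GRID - 0.1)))
    i09 = int(np.argmin(np.abs(CDF_GRID - 0.9)))
    return float(cdf_curve[i09] - cdf_curve[i01])


def auc_and_delta(cdf_curves: dict[int, np.ndarray]) -> tuple[dict[int, float],
                                                              dict[int, float]]:
    """Trapezoidal area under each CDF and the relative change across k.

    delta(k_min) is the raw area; delta(k) = (auc(k) - auc(k-1)) / auc(k-1)
    for subsequent k (missing when the previous k is absent from the scan).
    """
    if len(cdf_curves) < 1:
        raise ValueError("empty scan")
    ks = sorted(cdf_curves)
    auc = {k: float(np.trapezoid(cdf_curves[k], CDF_GRID)) for k in ks}
    delta: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = auc[k]
        elif ks[i - 1] == k - 1 and auc[k - 1] > 0:
            delta[k] = (auc[k] - auc[k - 1]) / auc[k - 1]
        else:
            delta[k] = float("nan")
    return auc, delta


@dataclass
class ConsensusScan:
    """Per-k consensus results plus the selected number of clusters."""

    k_values: list[int]
    matrices: dict[int, ConsensusMatrix]
    cdf_curves: dict[int, np.ndarray]
    auc: dict[int, float]
    delta_auc: dict[int, float]
    ambiguity: dict[int, float]
    chosen_k: int
    low_confidence: bool


DELTA_TIE_THRESHOLD = 0.1


def select_optimal_k(ambiguity: dict[int, float],
                     delta_auc: Optional[dict[int, float]] = None
                     ) -> tuple[int, bool]:
    """k with minimal ambiguity, consulting the delta plot on exact ties.

    Crisp nested structure can leave several k with *identical* minimal
    ambiguity (e.g. a stable 2-way merge of 3 true clusters is as crisp as
    the 3-way split).  The CDF alone cannot rank those, so exact ties are
    resolved by the delta-area plot: starting from the smallest tied k,
    advance to the next tied k while the relative area gain delta_auc(k)
    stays >= 0.1 (a substantial gain means the extra cluster adds real
    structure).  Without a delta plot, ties fall back to the smaller k.

    Returns (chosen_k, low_confidence); the flag marks scans whose best
    ambiguity still exceeds 0.5 (no k gives a crisp consensus).
    """
    if not ambiguity:
        raise ValueError("empty scan")
    ks = sorted(ambiguity)
    best = min(ambiguity.values())
    tied = [k for k in ks if ambiguity[k] == best]
    chosen = tied[0]
    if delta_auc is not None:
        for k in tied[1:]:
            if (k == chosen + 1 and k in delta_auc
                    and delta_auc[k] >= DELTA_TIE_THRESHOLD):
                chosen = k
            else:
                break
    return chosen, best > AMBIGUITY_LOW_CONFIDENCE


def final_labels(cm: ConsensusMatrix) -> np.ndarray:
    """Cluster the consensus matrix itself (average linkage on 1 - M), cut at
    k, and renumber clusters 1..k by descending size."""
    d = 1.0 - cm.M
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    z = linkage(squareform((d + d.T) / 2, checks=False), method="average")
    raw = cut_tree(z, n_clusters=cm.k).ravel()
    sizes = np.bincount(raw, minlength=cm.k)
    assert (sizes > 0).all(), "empty cluster after consensus cut"
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(cm.k, dtype=int)
    remap[order] = np.arange(1, cm.k + 1)
    return remap[raw]


def scan_consensus(x: np.ndarray, k_values: Sequence[int] = range(2, 8),
                   n_resamples: int = 100, subsample_fraction: float = 0.8,
                   seed: int = 0) -> ConsensusScan:
    """Run build_consensus over a k range and select the optimal k."""
    k_values = sorted(k_values)
    if not k_values:
        raise ValueError("empty k range")
    matrices = {}
    cdfs = {}
    amb = {}
    for i, k in enumerate(k_values):
        cm = build_consensus(x, k, n_resamples=n_resamples,
                             subsample_fraction=subsample_fraction,
                             seed=seed + i)
        matrices[k] = cm
        cdfs[k] = consensus_cdf(cm)
        amb[k] = ambiguity_score(cdfs[k])
    auc, delta = auc_and_delta(cdfs)
    chosen, low_conf = select_optimal_k(amb, delta)
    return ConsensusScan(list(k_values), matrices, cdfs, auc, delta, amb,
                         chosen, low_conf)


class ConsensusCluster(ClusterMixin, BaseEstimator):
    """Consensus clustering estimator (scikit-learn API).

    Parameters
    ----------
    k_min, k_max : inclusive range of candidate cluster numbers.
    n_resamples : subsampled clustering runs per k.
    subsample_fraction : fraction of samples drawn per run (no replacement).
    random_state : seed for the resampling stream.

    Attributes (after ``fit``)
    --------------------------
    chosen_k_ : selected number of clusters (minimal CDF ambiguity).
    labels_ : cluster labels 1..k, numbered by descending cluster size.
    scan_ : full per-k ConsensusScan (matrices, CDFs, areas, ambiguity).
    low_confidence_ : True when even the best k has ambiguity > 0.5.

    ``X`` follows the scikit-learn orientation (n_samples, n_features).
    """

    def __init__(self, k_min: int = 2, k_max: int = 7, n_resamples: int = 100,
                 subsample_fraction: float = 0.8, random_state: int = 0):
        self.k_min = k_min
        self.k_max = k_max
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < self.k_min:
            raise ValueError("X must be 2-D with at least k_min samples")
        scan = scan_consensus(X.T, range(self.k_min, self.k_max + 1),
                              n_resamples=self.n_resamples,
                              subsample_fraction=self.subsample_fraction,
                              seed=self.random_state)
        self.scan_ = scan
        self.chosen_k_ = scan.chosen_k
        self.low_confidence_ = scan.low_confidence
        self.labels_ = final_labels(scan.matrices[scan.chosen_k])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
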