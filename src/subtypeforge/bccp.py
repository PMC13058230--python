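"""Bayesian compound covariate predictor (BCCP).

For a binary contrast, each signature feature contributes its training
t-statistic as a weight; a sample's compound covariate is the weighted sum
c = sum_i t_i x_i over its z-scored signature-feature values.  The two
class-conditional distributions of c are modeled as Gaussians, and Bayes'
rule converts a new sample's c into a class posterior.  The multi-class
extension used here is one-vs-rest: one binary model per subtype, each with
its own subtype signature, combined by argmax posterior.

Transfer convention: a validation cohort is z-scored per feature *within
itself* before classification, so the predictor survives platform shifts;
single held-out samples (LOOCV) are standardized with the training fold's
parameters instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import ExpressionMatrix
from .signatures import SignatureSet, _vectorized_t, select_subtype_markers, \
    pairwise_subtype_tests

__all__ = [
    "compound_covariate",
    "BCCPBinaryModel",
    "fit_binary_bccp",
    "posterior",
    "BCCPClassifier",
    "classify_cohort",
    "loocv",
    "CVReport",
]


def compound_covariate(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """c = sum_i t_i x_i for one sample vector or a (n_features, n) block."""
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if x.shape[0] != weights.shape[0]:
        raise ValueError(f"{weights.shape[0]} weights vs {x.shape[0]} features")
    return weights @ x


@dataclass
class BCCPBinaryModel:
    """One-vs-rest compound-covariate model for a focal subtype."""

    feature_ids: list[str]
    weights: np.ndarray              # training t-statistics, focal vs rest
    mean_pos: float
    sd_pos: float
    mean_neg: float
    sd_neg: float
    prior_pos: float = 0.5

    def __post_init__(self) -> None:
        if self.sd_pos <= 0 or self.sd_neg <= 0:
            raise ValueError("class-conditional sds must be positive")
        if not 0 < self.prior_pos < 1:
            raise ValueError("prior must be in (0,1)")


def fit_binary_bccp(x: np.ndarray, positive: np.ndarray,
                    feature_ids: list[str], weights: np.ndarray,
                    prior_pos: float = 0.5) -> BCCPBinaryModel:
    """Fit class-conditional Gaussians of the compound covariate.

    ``x`` is the z-scored (n_signature_features, n_samples) training block,
    ``positive`` the boolean focal-class mask.
    """
    positive = np.asarray(positive, dtype=bool)
    if positive.sum() < 2 or (~positive).sum() < 2:
        raise ValueError("need >= 2 samples per class")
    c = compound_covariate(x, weights)
    cp, cn = c[positive], c[~positive]
    sd_pos, sd_neg = cp.std(ddof=1), cn.std(ddof=1)
    if sd_pos == 0 or sd_neg == 0:
        raise ValueError("degenerate compound covariate (zero within-class sd)")
    return BCCPBinaryModel(list(feature_ids), np.asarray(weights, float),
                           float(cp.mean()), float(sd_pos),
                           float(cn.mean()), float(sd_neg), prior_pos)


def posterior(model: BCCPBinaryModel, c) -> np.ndarray | float:
    """P(focal class | c) via Bayes' rule on the two Gaussians (log-space)."""
    c = np.asarray(c, dtype=float)
    log_pos = np.log(model.prior_pos) + stats.norm.logpdf(
        c, model.mean_pos, model.sd_pos)
    log_neg = np.log(1.0 - model.prior_pos) + stats.norm.logpdf(
        c, model.mean_neg, model.sd_neg)
    m = np.maximum(log_pos, log_neg)
    post = np.exp(log_pos - m) / (np.exp(log_pos - m) + np.exp(log_neg - m))
    return float(post) if post.ndim == 0 else post


class BCCPClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-rest Bayesian compound covariate classifier (scikit-learn API).

    ``fit(X, y)`` expects X of shape (n_samples, n_features) on log2 scale;
    marker selection (two-of-three rule at ``p_cut``/``fold_cut_log2``), the
    z-scoring parameters, the t-weights and the class-conditional Gaussians
    are all learned from the training data.  A pre-computed SignatureSet can
    be supplied to skip in-fit selection.

    Priors are equal per binary model by default: validation-cohort subtype
    prevalence is unknown at transfer time.

    Attributes: ``classes_``, ``signature_``, ``models_`` (subtype ->
    BCCPBinaryModel), ``zscore_mean_``/``zscore_sd_`` (training per-feature
    parameters), ``feature_names_``.
    """

    def __init__(self, p_cut: float = 0.001, fold_cut_log2: float = 1.0,
                 priors: str = "equal", feature_names=None,
                 signature: Optional[SignatureSet] = None,
                 target_normalization: str = "self",
                 max_missing_frac: float = 0.1,
                 fallback_features: int = 10):
        self.p_cut = p_cut
        self.fold_cut_log2 = fold_cut_log2
        self.priors = priors
        self.feature_names = feature_names
        self.signature = signature
        self.target_normalization = target_normalization
        self.max_missing_frac = max_missing_frac
        self.fallback_features = fallback_features

    # -- helpers ------------------------------------------------------------
    def _names(self, n_features: int) -> list[str]:
        if self.feature_names is not None:
            return list(self.feature_names)
        return [f"f{i}" for i in range(n_features)]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        names = self._names(X.shape[1])
        self.classes_ = np.array(sorted(pd.unique(y).tolist()))
        if len(self.classes_) < 2:
            raise ValueError("need >= 2 classes")
        results = None
        if self.signature is not None:
            sig = self.signature
        else:
            results = pairwise_subtype_tests(X.T, y, feature_ids=names)
            sig = select_subtype_markers(results, self.p_cut,
                                         self.fold_cut_log2)
        self.signature_ = sig
        self.fallback_used_ = []
        self.feature_names_ = names
        # training z-score parameters (per feature)
        self.zscore_mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.zscore_sd_ = np.where(sd > 0, sd, 1.0)
        xz = (X - self.zscore_mean_) / self.zscore_sd_   # samples x features
        name_idx = {f: i for i, f in enumerate(names)}
        self.models_ = {}
        for s in self.classes_:
            feats = sig.features_for(s)
            if not feats:
                # no feature cleared the thresholds for this subtype: fall
                # back to the best-ranked features (smallest worst-pair p)
                # so that a classifier is always defined; flagged for audit.
                if results is None or self.fallback_features < 1:
                    raise ValueError(f"empty signature for subtype {s!r}; "
                                     "relax thresholds")
                rel = results[(results["a"] == s) | (results["b"] == s)]
                worst_p = rel.groupby("feature_id", sort=False)["p_value"].max()
                feats = list(worst_p.nsmallest(self.fallback_features).index)
                self.fallback_used_.append(s)
            rows = [name_idx[f] for f in feats]
            positive = y == s
            block = X[:, rows].T  # features x samples, log2 scale
            t, _, _ = _vectorized_t(block[:, positive], block[:, ~positive])
            prior = (float(positive.mean()) if self.priors == "proportional"
                     else 0.5)
            self.models_[s] = fit_binary_bccp(
                xz[:, rows].T, positive, feats, t, prior_pos=prior)
        return self

    def _posterior_matrix(self, xz: np.ndarray, names: list[str],
                          missing_log: list[str]) -> np.ndarray:
        """Per-sample one-vs-rest posteriors; xz is samples x features
        (already standardized)."""
        name_idx = {f: i for i, f in enumerate(names)}
        out = np.empty((xz.shape[0], len(self.classes_)))
        for j, s in enumerate(self.classes_):
            model = self.models_[s]
            present = [f for f in model.feature_ids if f in name_idx]
            missing = [f for f in model.feature_ids if f not in name_idx]
            frac = len(missing) / len(model.feature_ids)
            if frac > self.max_missing_frac:
                raise KeyError(
                    f"{len(missing)}/{len(model.feature_ids)} signature "
                    f"features missing for subtype {s!r}: {missing[:5]}")
            if missing:
                missing_log.extend(missing)
                keep = [i for i, f in enumerate(model.feature_ids)
                        if f in name_idx]
                weights = model.weights[keep]
            else:
                weights = model.weights
            rows = [name_idx[f] for f in present]
            c = compound_covariate(xz[:, rows].T, weights)
            out[:, j] = posterior(model, c)
        return out

    def predict_posteriors(self, X, feature_names=None) -> pd.DataFrame:
        """Raw one-vs-rest posteriors (not normalized across classes)."""
        X = np.asarray(X, dtype=float)
        names = (list(feature_names) if feature_names is not None
                 else self._names(X.shape[1]))
        if self.target_normalization == "self":
            if X.shape[0] < 3:
                raise ValueError("within-cohort z-scoring needs >= 3 samples; "
                                 "use target_normalization='train'")
            mean = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            xz = (X - mean) / sd
        elif self.target_normalization == "train":
            if names != self.feature_names_:
                raise ValueError("'train' normalization requires the training "
                                 "feature space")
            xz = (X - self.zscore_mean_) / self.zscore_sd_
        else:
            raise ValueError(f"unknown normalization {self.target_normalization!r}")
        self.missing_features_ = []
        post = self._posterior_matrix(xz, names, self.missing_features_)
        return pd.DataFrame(post, columns=list(self.classes_))

    def predict(self, X, feature_names=None) -> np.ndarray:
        post = self.predict_posteriors(X, feature_names).to_numpy()
        return self.classes_[np.argmax(post, axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        post = self.predict_posteriors(X).to_numpy()
        return post / post.sum(axis=1, keepdims=True)


@dataclass
class ClassificationResult:
    """Per-sample posteriors, assigned labels and low-confidence flags."""

    sample_ids: list[str]
    posteriors: pd.DataFrame
    labels: np.ndarray
    low_confidence: np.ndarray
    missing_features: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = self.posteriors.copy()
        df.insert(0, "sample_id", self.sample_ids)
        df["label"] = self.labels
        df["low_confidence"] = self.low_confidence
        return df


LOW_CONFIDENCE_POSTERIOR = 0.5


def classify_cohort(clf: BCCPClassifier, cohort: ExpressionMatrix
                    ) -> ClassificationResult:
    """Classify every sample of a cohort matrix (features x samples, log2).

    The cohort is z-scored per feature within itself, each one-vs-rest model
    produces a posterior, and the argmax wins; samples whose best posterior
    is below 0.5 are flagged low-confidence (but still assigned — every
    patient gets a class).
    """
    X = cohort.values.T
    post = clf.predict_posteriors(X, feature_names=cohort.feature_ids)
    labels = clf.classes_[np.argmax(post.to_numpy(), axis=1)]
    low = post.to_numpy().max(axis=1) < LOW_CONFIDENCE_POSTERIOR
    return ClassificationResult(list(cohort.sample_ids), post, labels, low,
                                list(getattr(clf, "missing_features_", [])))


@dataclass
class CVReport:
    """Leave-one-out cross-validation summary."""

    misclassification_rate: float
    confusion: pd.DataFrame
    assignments: pd.DataFrame       # per-fold: sample, truth, predicted
    skipped_folds: list[int] = field(default_factory=list)


def loocv(X: np.ndarray, y: np.ndarray, p_cut: float = 0.001,
          fold_cut_log2: float = 1.0, feature_names=None,
          sample_ids=None) -> CVReport:
    """Leave-one-out CV with full in-fold re-selection.

    For every held-out sample the signature is re-selected and the one-vs-
    rest models are re-fit on the remaining n-1 samples only; the held-out
    sample is standardized with the fold's training parameters and
    classified.  Folds whose training split loses a class are skipped and
    reported.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    classes = sorted(pd.unique(y).tolist())
    if n < len(classes) + 2:
        raise ValueError("too few samples for LOOCV")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    records = []
    skipped = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        counts = pd.Series(y_tr).value_counts()
        if len(counts) < len(classes) or counts.min() < 2:
            skipped.append(i)
            continue
        clf = BCCPClassifier(p_cut=p_cut, fold_cut_log2=fold_cut_log2,
                             feature_names=feature_names,
                             target_normalization="train")
        clf.fit(X[mask], y_tr)
        pred = clf.predict(X[i:i + 1])[0]
        records.append((sample_ids[i], y[i], pred))
    assignments = pd.DataFrame(records, columns=["sample_id", "truth",
                                                 "predicted"])
    confusion = pd.crosstab(assignments["truth"], assignments["predicted"]) \
        .reindex(index=classes, columns=classes, fill_value=0)
    wrong = (assignments["truth"] != assignments["predicted"]).sum()
    rate = wrong / len(assignments) if len(assignments) else float("nan")
    return CVReport(float(rate), confusion, assignments, skipped)
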