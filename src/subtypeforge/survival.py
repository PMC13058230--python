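"""Kaplan-Meier estimation, k-group log-rank test and Cox regression.

KM curves and Cox proportional-hazards fits are delegated to lifelines and
re-packaged into small result containers mirroring the "HR (95% CI), P"
reporting style of clinical tables.  The k-group log-rank statistic is
computed here directly from the hypergeometric moments at each distinct
event time (it also exposes the per-group O-E vector and its covariance,
which the Cox score test at beta = 0 must reproduce for a single binary
covariate — a classical identity used as an internal consistency check).

Convention: samples censored exactly at an event time are still at risk for
that event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .io import ClinicalTable
from .preprocess import median_split

__all__ = [
    "KMCurve",
    "km_estimate",
    "LogRankResult",
    "logrank_test",
    "cox_score_at_zero",
    "CoxResult",
    "cox_fit",
    "stratified_km_report",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    event_times: np.ndarray      # distinct times with >= 1 event
    survival: np.ndarray         # S(t) just after each event time
    n_at_risk: np.ndarray
    censor_times: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times,
                             "survival": self.survival,
                             "n_at_risk": self.n_at_risk})


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    if event_times.size:
        surv = kmf.survival_function_at_times(event_times).to_numpy()
        # at-risk counts with the censored-at-event-time-still-at-risk rule
        n_at_risk = np.array([(times >= t).sum() for t in event_times])
    else:
        surv = np.array([])
        n_at_risk = np.array([], dtype=int)
    return KMCurve(event_times, surv, n_at_risk,
                   np.sort(times[events == 0]), label)


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float
    observed: np.ndarray = field(default=None)   # per-group event counts
    expected: np.ndarray = field(default=None)
    U: np.ndarray = field(default=None)          # (O - E) over first k-1 groups
    V: np.ndarray = field(default=None)          # covariance of U


def logrank_test(groups: Sequence[tuple[np.ndarray, np.ndarray]]
                 ) -> LogRankResult:
    """Standard k-group log-rank test.

    ``groups`` is a list of (times, events) pairs.  At each distinct event
    time the observed events per group are compared with the expectation
    under the hypergeometric null; chi2 = U' V^-1 U over the first k-1
    groups, p from chi-square(k-1).
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    times = []
    events = []
    gid = []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {g} is empty")
        times.append(t)
        events.append(e)
        gid.append(np.full(t.size, g))
    times = np.concatenate(times)
    events = np.concatenate(events)
    gid = np.concatenate(gid)
    if events.sum() == 0:
        raise ValueError("no events: log-rank test undefined")

    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k - 1, k - 1))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n_g = np.array([(at_risk & (gid == g)).sum() for g in range(k)])
        d_g = np.array([((times == t) & (events == 1) & (gid == g)).sum()
                        for g in range(k)])
        O += d_g
        E += d * n_g / n
        if n > 1:
            # hypergeometric covariance of the event-count vector
            frac = n_g / n
            factor = d * (n - d) / (n - 1)
            for i in range(k - 1):
                for j in range(k - 1):
                    V[i, j] += factor * frac[i] * ((i == j) - frac[j])
    U = (O - E)[: k - 1]
    chi2 = float(U @ np.linalg.solve(V, U)) if np.linalg.det(V) != 0 else \
        float(U @ np.linalg.pinv(V) @ U)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return LogRankResult(chi2, k - 1, p, O, E, U, V)


def cox_score_at_zero(times, events, x) -> float:
    """Score of the Cox partial likelihood at beta = 0 for one covariate
    (Breslow form).  For a binary covariate without ties this equals the
    log-rank numerator O - E."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    score = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        d = (times == t) & (events == 1)
        score += x[d].sum() - d.sum() * x[at_risk].mean()
    return float(score)


@dataclass
class CoxResult:
    """Cox proportional-hazards fit in clinical-table layout."""

    table: pd.DataFrame         # index covariate: beta, hr, ci_low, ci_high, se, p
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    ties: str = "efron"
    warnings: list[str] = field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


DIVERGENCE_BETA = 15.0


def cox_fit(clinical: ClinicalTable, covariates: Sequence[str],
            extra: Optional[pd.DataFrame] = None,
            ties: str = "efron") -> CoxResult:
    """Fit a Cox model on clinical covariates (plus optional extra columns).

    Categorical covariates are expanded to indicator columns.  Efron tie
    handling (the lifelines default).  Monotone-likelihood divergence
    (|beta| > 15) is flagged in ``warnings`` rather than silently returned.
    """
    if ties != "efron":
        raise NotImplementedError("only Efron tie handling is provided")
    df = clinical.to_frame()
    if extra is not None:
        extra = extra.reindex(df.index)
        for c in extra.columns:
            df[c] = extra[c].to_numpy()
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise KeyError(f"covariates not found: {missing}")
    model_df = df[["os_time", "os_event"]].copy()
    for c in covariates:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True,
                                     dtype=float)
            for dc in dummies.columns:
                model_df[dc] = dummies[dc]
        else:
            if col.nunique() < 2:
                raise ValueError(f"covariate {c!r} is constant")
            model_df[c] = col.astype(float)
    cph = CoxPHFitter()
    cph.fit(model_df, duration_col="os_time", event_col="os_event",
            fit_options={"precision": 1e-9})
    summ = cph.summary
    table = pd.DataFrame({
        "beta": summ["coef"],
        "hr": np.exp(summ["coef"]),
        "ci_low": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
        "ci_high": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
        "se": summ["se(coef)"],
        "p": summ["p"],
    })
    warnings_ = []
    diverged = table["beta"].abs() > DIVERGENCE_BETA
    if diverged.any():
        warnings_.append("possible monotone likelihood (|beta| > 15) for: "
                         + ", ".join(table.index[diverged]))
    return CoxResult(table, float(cph.log_likelihood_),
                     int(model_df.shape[0]), int(model_df["os_event"].sum()),
                     converged=not diverged.any(), warnings=warnings_)


def stratified_km_report(values, clinical: ClinicalTable,
                         dichotomize: Optional[bool] = None
                         ) -> tuple[dict, LogRankResult]:
    """KM curves per group plus a log-rank test.

    ``values`` is either a per-sample scalar (median-dichotomized into
    low/high first) or categorical group labels, aligned with the clinical
    table's sample order.  ``dichotomize=None`` auto-detects: numeric input
    with more than 6 distinct values is treated as a scalar.
    """
    values = np.asarray(values)
    if values.shape[0] != clinical.n_samples:
        raise ValueError("values do not align with clinical samples")
    if dichotomize is None:
        dichotomize = (np.issubdtype(values.dtype, np.number)
                       and len(np.unique(values)) > 6)
    if dichotomize:
        labels = median_split(values.astype(float))
    else:
        labels = values.astype(str)
    groups = sorted(np.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups after splitting")
    curves = {}
    pairs = []
    for g in groups:
        mask = labels == g
        t, e = clinical.os_time[mask], clinical.os_event[mask]
        curves[g] = km_estimate(t, e, label=str(g))
        pairs.append((t, e))
    return curves, logrank_test(pairs)
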