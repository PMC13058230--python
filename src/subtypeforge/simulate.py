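"""Synthetic HCC-like cohort generator.

Emulates the statistical structure of an RPPA + microarray tumor cohort with
three latent molecular subtypes:

* disjoint blocks of subtype-specific up-regulated markers in both the
  protein and mRNA matrices (mean log2 shift ``effect_size`` on a noise
  background of sd ``noise_sd``);
* one poor-prognosis subtype (subtype 1, mesenchymal-like) whose survival
  median is shortest;
* a driver feature ("DRIVER") amplified in a fraction of subtype-1 tumors,
  with copy number propagating to mRNA (linear in extra copies) and mRNA
  propagating to protein at a configured Pearson correlation;
* exponential survival with subtype-specific medians and independent
  uniform-window censoring calibrated to the requested censoring fraction.

Everything is drawn from one seeded generator in a fixed, documented order,
so equal seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .io import (ClinicalTable, CohortBundle, ExpressionMatrix, Platform,
                 ScaleFlag)

__all__ = [
    "DriverConfig",
    "CohortConfig",
    "KnockdownConfig",
    "generate_cohort",
    "generate_knockdown",
]


@dataclass
class DriverConfig:
    """Copy-number -> mRNA -> protein cascade for the driver feature."""

    amplification_freq_in_subtype1: float = 0.7
    cn_to_mrna_slope: float = 0.8       # log2 units per extra copy
    mrna_to_protein_r: float = 0.83     # target Pearson correlation

    def validate(self) -> None:
        if not 0 <= self.amplification_freq_in_subtype1 <= 1:
            raise ValueError("amplification frequency must be in [0,1]")
        if not 0 < self.mrna_to_protein_r < 1:
            raise ValueError("mrna_to_protein_r must be in (0,1)")


@dataclass
class CohortConfig:
    """Study-condition parameters for one synthetic cohort."""

    n_per_subtype: tuple[int, int, int] = (40, 40, 40)
    n_protein_features: int = 200
    n_mrna_features: int = 2000
    markers_per_subtype: int = 30
    effect_size: float = 1.5            # mean log2 up-shift of a marker
    noise_sd: float = 1.0
    survival_medians: tuple[float, float, float] = (20.0, 40.0, 60.0)
    censor_rate: float = 0.2
    driver: DriverConfig = field(default_factory=DriverConfig)
    baseline_log2: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_subtype) != 3 or min(self.n_per_subtype) < 2:
            raise ValueError("need 3 subtypes with >= 2 samples each")
        if 3 * self.markers_per_subtype + 1 > self.n_mrna_features:
            raise ValueError("marker blocks (plus driver) exceed n_mrna_features")
        if 3 * self.markers_per_subtype + 1 > self.n_protein_features:
            raise ValueError("marker blocks (plus driver) exceed n_protein_features")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size >= 0 and noise_sd > 0 required")
        if min(self.survival_medians) <= 0:
            raise ValueError("survival medians must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0,1)")
        self.driver.validate()


@dataclass
class KnockdownConfig:
    """Control vs knockdown expression experiment with planted responders."""

    n_genes: int = 2000
    n_dependent: int = 500
    n_replicates: int = 3
    effect_size: float = 3.0
    noise_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_dependent > self.n_genes:
            raise ValueError("n_dependent must be <= n_genes")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per arm")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _censor_window(rate_lambda: float, censor_rate: float) -> float:
    """Width W of the U(0, W) censoring window giving the target censoring
    probability for exponential event times: P(C < T) = (1 - e^{-lam W})/(lam W)."""
    if censor_rate <= 0:
        return np.inf

    def f(w: float) -> float:
        return (1.0 - np.exp(-rate_lambda * w)) / (rate_lambda * w) - censor_rate

    return brentq(f, 1e-9, 1e9)


def _marker_ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(cfg: CohortConfig) -> CohortBundle:
    """Draw one cohort (protein, mRNA, copy-number matrices + clinical).

    Draw order (fixed for reproducibility): protein noise, mRNA noise,
    driver copy numbers, driver mRNA noise, driver protein noise, survival
    event times, censoring times.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_sub = list(cfg.n_per_subtype)
    n = sum(n_sub)
    labels = np.repeat([1, 2, 3], n_sub)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    prot_ids = ["DRIVER"] + _marker_ids("p", cfg.n_protein_features - 1)
    mrna_ids = ["DRIVER"] + _marker_ids("g", cfg.n_mrna_features - 1)

    prot = cfg.baseline_log2 + rng.normal(
        0.0, cfg.noise_sd, (cfg.n_protein_features, n))
    mrna = cfg.baseline_log2 + rng.normal(
        0.0, cfg.noise_sd, (cfg.n_mrna_features, n))

    # disjoint up-regulated marker blocks, rows 1.. (row 0 is the driver)
    m = cfg.markers_per_subtype
    marker_rows = {}
    for s in (1, 2, 3):
        rows = np.arange(1 + (s - 1) * m, 1 + s * m)
        cols = labels == s
        prot[np.ix_(rows, cols)] += cfg.effect_size
        mrna[np.ix_(rows, cols)] += cfg.effect_size
        marker_rows[s] = rows

    # driver cascade: CN in {2,3,4,5}; amplification (CN >= 3) only in subtype 1
    cn = np.full(n, 2, dtype=int)
    in_s1 = labels == 1
    amp = in_s1 & (rng.random(n) < cfg.driver.amplification_freq_in_subtype1)
    cn[amp] = rng.choice([3, 4, 5], size=int(amp.sum()))
    drv_mrna = (cfg.baseline_log2 + cfg.driver.cn_to_mrna_slope * (cn - 2)
                + rng.normal(0.0, cfg.noise_sd, n))
    zm = (drv_mrna - drv_mrna.mean()) / drv_mrna.std()
    r = cfg.driver.mrna_to_protein_r
    drv_prot = (cfg.baseline_log2 + cfg.noise_sd *
                (r * zm + np.sqrt(1.0 - r * r) * rng.normal(0.0, 1.0, n)))
    mrna[0] = drv_mrna
    prot[0] = drv_prot

    # survival: exponential per subtype, uniform-window censoring
    medians = np.asarray(cfg.survival_medians, dtype=float)
    lam = np.log(2.0) / medians[labels - 1]
    event_t = rng.exponential(1.0 / lam)
    if cfg.censor_rate > 0:
        windows = np.array([_censor_window(np.log(2.0) / md, cfg.censor_rate)
                            for md in medians])
        censor_t = rng.uniform(0.0, windows[labels - 1])
        os_event = (event_t <= censor_t).astype(int)
        os_time = np.minimum(event_t, censor_t)
    else:
        os_event = np.ones(n, dtype=int)
        os_time = event_t
    os_time = np.maximum(os_time, 1e-6)  # keep times strictly positive

    matrices = {
        Platform.protein: ExpressionMatrix(prot_ids, sample_ids, prot,
                                           platform=Platform.protein,
                                           scale_flag=ScaleFlag.log2),
        Platform.mrna: ExpressionMatrix(mrna_ids, sample_ids, mrna,
                                        platform=Platform.mrna,
                                        scale_flag=ScaleFlag.log2),
        Platform.cnv: ExpressionMatrix(["DRIVER"], sample_ids,
                                       cn[None, :].astype(float),
                                       platform=Platform.cnv,
                                       scale_flag=ScaleFlag.raw),
    }
    clinical = ClinicalTable(sample_ids, os_time, os_event)
    true_labels = dict(zip(sample_ids, labels.tolist()))
    bundle = CohortBundle(matrices, clinical, true_labels)
    # expose planted marker ids for recovery experiments
    bundle.planted_markers = {
        s: [mrna_ids[i] for i in rows] for s, rows in marker_rows.items()
    }
    return bundle


def generate_knockdown(cfg: KnockdownConfig) -> tuple[ExpressionMatrix, list[str]]:
    """Control/knockdown replicate matrix with the first ``n_dependent`` genes
    shifted by ``effect_size`` in the knockdown arm.

    Returns the matrix and the per-column arm labels ("control"/"knockdown").
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    reps = cfg.n_replicates
    gene_ids = _marker_ids("g", cfg.n_genes)
    sample_ids = ([f"ctrl_{i + 1}" for i in range(reps)]
                  + [f"kd_{i + 1}" for i in range(reps)])
    values = 8.0 + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, 2 * reps))
    values[:cfg.n_dependent, reps:] += cfg.effect_size
    arms = ["control"] * reps + ["knockdown"] * reps
    matrix = ExpressionMatrix(gene_ids, sample_ids, values,
                              platform=Platform.mrna,
                              scale_flag=ScaleFlag.log2)
    return matrix, arms
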