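"""End-to-end workflows: subtype discovery and cross-cohort transfer.

``run_discovery`` reproduces the discovery chain on one cohort: consensus
scan over k -> optimal k -> final subtype labels -> platform-specific
signatures -> survival stratification by subtype.  ``run_transfer`` takes a
trained classifier and an independent cohort: z-score within the target,
classify every sample, then stratify its survival by predicted subtype.

All tabular artifacts are TSV; a JSON manifest records the configuration
snapshot, a checksum per output file and per-stage wall-clock, so a re-run
with the same config and seed can be verified byte-for-byte (the manifest
itself carries the only non-deterministic bytes, the timings).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .bccp import BCCPBinaryModel, BCCPClassifier, classify_cohort, loocv
from .consensus import ConsensusCluster
from .io import (ClinicalTable, CohortBundle, ExpressionMatrix, Platform,
                 read_clinical, read_matrix, write_clinical, write_matrix)
from .preprocess import zscore_rows
from .signatures import (MRNA_THRESHOLDS, PROTEIN_THRESHOLDS, SignatureSet,
                         pairwise_subtype_tests, select_subtype_markers)
from .simulate import CohortConfig, generate_cohort
from .survival import stratified_km_report

logger = logging.getLogger("subtypeforge")

__all__ = [
    "RunConfig",
    "RunManifest",
    "run_discovery",
    "run_transfer",
    "save_classifier",
    "load_classifier",
    "write_cohort",
    "load_cohort",
]


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run."""

    out_dir: Path
    seed: int = 0
    # input: either file paths or a synthetic-cohort config
    protein_path: Optional[Path] = None
    mrna_path: Optional[Path] = None
    clinical_path: Optional[Path] = None
    synthetic: Optional[CohortConfig] = None
    # consensus scan
    k_min: int = 2
    k_max: int = 7
    n_resamples: int = 100
    subsample_fraction: float = 0.8
    # signature thresholds (p_cut, log2 fold cut) per platform
    protein_thresholds: tuple[float, float] = PROTEIN_THRESHOLDS
    mrna_thresholds: tuple[float, float] = MRNA_THRESHOLDS

    def validate(self) -> None:
        if self.synthetic is None:
            for p, name in [(self.protein_path, "protein"),
                            (self.clinical_path, "clinical")]:
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"{name} input missing or not found: {p}")


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stage_seconds: dict[str, float] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_snapshot(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return json.loads(json.dumps(d, default=str))


def write_cohort(bundle: CohortBundle, out_dir: Path) -> dict[str, Path]:
    """Write every matrix, the clinical table and (if present) true labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for platform, m in bundle.matrices.items():
        p = out_dir / f"{platform.value}.tsv"
        write_matrix(m, p)
        paths[platform.value] = p
    p = out_dir / "clinical.tsv"
    write_clinical(bundle.clinical, p)
    paths["clinical"] = p
    if bundle.true_labels is not None:
        p = out_dir / "true_labels.tsv"
        pd.Series(bundle.true_labels, name="subtype") \
            .rename_axis("sample_id").to_csv(p, sep="\t")
        paths["true_labels"] = p
    return paths


def load_cohort(cfg: RunConfig) -> CohortBundle:
    if cfg.synthetic is not None:
        return generate_cohort(cfg.synthetic)
    matrices = {Platform.protein: read_matrix(cfg.protein_path,
                                              Platform.protein,
                                              scale_flag="log2")}
    if cfg.mrna_path is not None:
        matrices[Platform.mrna] = read_matrix(cfg.mrna_path, Platform.mrna,
                                              scale_flag="log2")
    clinical = read_clinical(cfg.clinical_path)
    return CohortBundle(matrices, clinical)


def _write_scan(scan, out_dir: Path, sample_ids) -> list[Path]:
    written = []
    for k, cm in scan.matrices.items():
        p = out_dir / f"consensus_k{k}.tsv"
        pd.DataFrame(cm.M, index=sample_ids, columns=sample_ids) \
            .to_csv(p, sep="\t", float_format="%.15g")
        written.append(p)
    from .consensus import CDF_GRID
    cdf = pd.DataFrame({f"k{k}": scan.cdf_curves[k] for k in scan.k_values},
                       index=pd.Index(CDF_GRID, name="consensus_value"))
    p = out_dir / "consensus_cdf.tsv"
    cdf.to_csv(p, sep="\t", float_format="%.15g")
    written.append(p)
    report = pd.DataFrame({
        "k": scan.k_values,
        "auc": [scan.auc[k] for k in scan.k_values],
        "delta_auc": [scan.delta_auc[k] for k in scan.k_values],
        "ambiguity": [scan.ambiguity[k] for k in scan.k_values],
        "chosen": [k == scan.chosen_k for k in scan.k_values],
    })
    p = out_dir / "k_selection.tsv"
    report.to_csv(p, sep="\t", index=False, float_format="%.15g")
    written.append(p)
    return written


def run_discovery(cfg: RunConfig) -> RunManifest:
    """Consensus subtype discovery + signatures + survival on one cohort."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_snapshot(cfg), __version__)
    written: list[Path] = []

    t0 = time.perf_counter()
    bundle = load_cohort(cfg)
    if cfg.synthetic is not None:
        written.extend(write_cohort(bundle, out_dir / "cohort").values())
    manifest.stage_seconds["load"] = time.perf_counter() - t0
    protein = bundle.matrices[Platform.protein]
    logger.info("discovery: %d protein features x %d samples",
                protein.n_features, protein.n_samples)

    t0 = time.perf_counter()
    protein_z = zscore_rows(protein)
    cc = ConsensusCluster(k_min=cfg.k_min, k_max=cfg.k_max,
                          n_resamples=cfg.n_resamples,
                          subsample_fraction=cfg.subsample_fraction,
                          random_state=cfg.seed)
    cc.fit(protein_z.values.T)
    labels = cc.labels_
    written.extend(_write_scan(cc.scan_, out_dir, protein.sample_ids))
    label_path = out_dir / "subtype_labels.tsv"
    pd.DataFrame({"sample_id": protein.sample_ids, "subtype": labels}) \
        .to_csv(label_path, sep="\t", index=False)
    written.append(label_path)
    manifest.stage_seconds["consensus"] = time.perf_counter() - t0
    manifest.summary["chosen_k"] = int(cc.chosen_k_)
    manifest.summary["low_confidence"] = bool(cc.low_confidence_)
    logger.info("chosen k = %d (ambiguity %.3f)", cc.chosen_k_,
                cc.scan_.ambiguity[cc.chosen_k_])

    t0 = time.perf_counter()
    signatures: dict[str, SignatureSet] = {}
    for platform, thresholds in [(Platform.protein, cfg.protein_thresholds),
                                 (Platform.mrna, cfg.mrna_thresholds)]:
        if platform not in bundle.matrices:
            continue
        m = bundle.matrices[platform]
        m_sub = m.subset_samples(protein.sample_ids)
        results = pairwise_subtype_tests(m_sub, labels)
        sig = select_subtype_markers(results, *thresholds)
        sig.platform = platform.value
        signatures[platform.value] = sig
        p = out_dir / f"signature_{platform.value}.tsv"
        sig.to_frame().to_csv(p, sep="\t", index=False, float_format="%.15g")
        written.append(p)
        manifest.summary[f"n_{platform.value}_markers"] = \
            int(len(sig.to_frame()))
    manifest.stage_seconds["signatures"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    clinical = bundle.clinical.subset(protein.sample_ids)
    curves, lr = stratified_km_report(labels, clinical, dichotomize=False)
    km = pd.concat([c.to_frame().assign(group=g) for g, c in curves.items()],
                   ignore_index=True)
    p = out_dir / "km_by_subtype.tsv"
    km.to_csv(p, sep="\t", index=False, float_format="%.15g")
    written.append(p)
    lr_path = out_dir / "logrank_by_subtype.tsv"
    pd.DataFrame([{"chi2": lr.chi2, "df": lr.df, "p": lr.p}]) \
        .to_csv(lr_path, sep="\t", index=False, float_format="%.15g")
    written.append(lr_path)
    manifest.stage_seconds["survival"] = time.perf_counter() - t0
    manifest.summary["logrank_p"] = lr.p

    # train the transfer classifier on the mRNA matrix and discovered labels
    if Platform.mrna in bundle.matrices:
        t0 = time.perf_counter()
        mrna = bundle.matrices[Platform.mrna].subset_samples(protein.sample_ids)
        clf = BCCPClassifier(p_cut=cfg.mrna_thresholds[0],
                             fold_cut_log2=cfg.mrna_thresholds[1],
                             feature_names=mrna.feature_ids,
                             signature=signatures.get("mrna"))
        clf.fit(mrna.values.T, labels)
        model_path = out_dir / "bccp_model.json"
        save_classifier(clf, model_path)
        written.append(model_path)
        manifest.stage_seconds["classifier"] = time.perf_counter() - t0

    for p in written:
        manifest.outputs[str(Path(p).relative_to(out_dir))] = _sha256(p)
    manifest.save(out_dir / "manifest.json")
    return manifest


def run_transfer(cfg: RunConfig, model_path: Path,
                 target: CohortBundle | None = None) -> RunManifest:
    """Classify an independent cohort and stratify its survival."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_snapshot(cfg), __version__)
    written: list[Path] = []

    clf = load_classifier(model_path)
    if target is None:
        target = load_cohort(cfg)
    mrna = target.matrices.get(Platform.mrna)
    if mrna is None:
        raise ValueError("target cohort lacks an mRNA matrix")
    if mrna.n_samples == 0:
        raise ValueError("empty target cohort")

    t0 = time.perf_counter()
    result = classify_cohort(clf, mrna)
    p = out_dir / "predicted_labels.tsv"
    result.to_frame().to_csv(p, sep="\t", index=False, float_format="%.15g")
    written.append(p)
    manifest.stage_seconds["classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    clinical = target.clinical.subset(mrna.sample_ids)
    curves, lr = stratified_km_report(result.labels, clinical,
                                      dichotomize=False)
    km = pd.concat([c.to_frame().assign(group=g) for g, c in curves.items()],
                   ignore_index=True)
    p = out_dir / "km_by_predicted_subtype.tsv"
    km.to_csv(p, sep="\t", index=False, float_format="%.15g")
    written.append(p)
    p = out_dir / "logrank_by_predicted_subtype.tsv"
    pd.DataFrame([{"chi2": lr.chi2, "df": lr.df, "p": lr.p}]) \
        .to_csv(p, sep="\t", index=False, float_format="%.15g")
    written.append(p)
    manifest.stage_seconds["survival"] = time.perf_counter() - t0
    manifest.summary["transfer_logrank_p"] = lr.p
    manifest.summary["n_low_confidence"] = int(result.low_confidence.sum())

    for p in written:
        manifest.outputs[str(Path(p).relative_to(out_dir))] = _sha256(p)
    manifest.save(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# classifier (de)serialization: plain-text JSON for audit
# ---------------------------------------------------------------------------

def save_classifier(clf: BCCPClassifier, path: Path) -> Path:
    payload = {
        "classes": [int(c) for c in clf.classes_],
        "p_cut": clf.p_cut,
        "fold_cut_log2": clf.fold_cut_log2,
        "models": {
            str(s): {
                "feature_ids": m.feature_ids,
                "weights": list(m.weights),
                "mean_pos": m.mean_pos, "sd_pos": m.sd_pos,
                "mean_neg": m.mean_neg, "sd_neg": m.sd_neg,
                "prior_pos": m.prior_pos,
            } for s, m in clf.models_.items()
        },
        "zscore_mean": list(clf.zscore_mean_),
        "zscore_sd": list(clf.zscore_sd_),
        "feature_names": clf.feature_names_,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return Path(path)


def load_classifier(path: Path) -> BCCPClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    clf = BCCPClassifier(p_cut=payload["p_cut"],
                         fold_cut_log2=payload["fold_cut_log2"])
    clf.classes_ = np.array(payload["classes"])
    clf.feature_names_ = payload["feature_names"]
    clf.zscore_mean_ = np.array(payload["zscore_mean"])
    clf.zscore_sd_ = np.array(payload["zscore_sd"])
    clf.models_ = {
        int(s): BCCPBinaryModel(
            d["feature_ids"], np.array(d["weights"]),
            d["mean_pos"], d["sd_pos"], d["mean_neg"], d["sd_neg"],
            d["prior_pos"],
        ) for s, d in payload["models"].items()
    }
    return clf
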