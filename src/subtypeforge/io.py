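"""Domain containers and tab-separated readers/writers.

The package works on two tables throughout:

* an expression matrix — features in rows, samples in columns (the GEO
  series-matrix orientation), log2 scale after preprocessing;
* a clinical table — one row per sample with overall-survival time (months),
  an event indicator and optional covariates.

Both are stored as thin dataclasses wrapping numpy arrays / pandas frames so
that invariants (unique ids, consistent shapes, scale bookkeeping) are
checked once at construction and every downstream stage can rely on them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Platform",
    "ScaleFlag",
    "ExpressionMatrix",
    "ClinicalTable",
    "CohortBundle",
    "MatrixFormatError",
    "ClinicalValidationError",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
]


class MatrixFormatError(ValueError):
    """Malformed expression TSV (duplicate ids, non-numeric cells, ...)."""


class ClinicalValidationError(ValueError):
    """Clinical table violating survival-time / event-indicator constraints."""


class Platform(str, enum.Enum):
    protein = "protein"
    mrna = "mrna"
    cnv = "cnv"


class ScaleFlag(str, enum.Enum):
    raw = "raw"
    log2 = "log2"
    zscore = "zscore"


# legal scale transitions: raw -> log2 -> zscore
_SCALE_ORDER = {ScaleFlag.raw: 0, ScaleFlag.log2: 1, ScaleFlag.zscore: 2}


@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression values with platform and scale metadata."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platform: Platform = Platform.mrna
    scale_flag: ScaleFlag = ScaleFlag.raw

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.platform = Platform(self.platform)
        self.scale_flag = ScaleFlag(self.scale_flag)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixFormatError("values must be a 2-D array")
        nf, ns = self.values.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise MatrixFormatError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != nf:
            raise MatrixFormatError("duplicate feature ids")
        if len(set(self.sample_ids)) != ns:
            raise MatrixFormatError("duplicate sample ids")
        if nf == 0 or ns == 0:
            raise MatrixFormatError("empty matrix (no features or no samples)")
        if np.isnan(self.values).all(axis=1).any():
            bad = [f for f, row in zip(self.feature_ids, self.values)
                   if np.isnan(row).all()]
            raise MatrixFormatError(f"features entirely missing: {bad[:5]}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)

    def with_values(self, values: np.ndarray,
                    scale_flag: Optional[ScaleFlag] = None) -> "ExpressionMatrix":
        """Copy with new values and (optionally) an advanced scale flag."""
        new_flag = self.scale_flag if scale_flag is None else ScaleFlag(scale_flag)
        if _SCALE_ORDER[new_flag] < _SCALE_ORDER[self.scale_flag]:
            raise ValueError(
                f"illegal scale transition {self.scale_flag.value} -> {new_flag.value}"
            )
        return replace(self, values=np.asarray(values, dtype=float),
                       scale_flag=new_flag)

    def subset_features(self, keep: list[str]) -> "ExpressionMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in keep if f not in index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        rows = [index[f] for f in keep]
        return replace(self, feature_ids=list(keep), values=self.values[rows])

    def subset_samples(self, keep: list[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [index[s] for s in keep]
        return replace(self, sample_ids=list(keep), values=self.values[:, cols])


@dataclass
class ClinicalTable:
    """Per-sample overall survival (months), event indicator and covariates."""

    sample_ids: list[str]
    os_time: np.ndarray
    os_event: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.os_time = np.asarray(self.os_time, dtype=float)
        self.os_event = np.asarray(self.os_event)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ClinicalValidationError("duplicate sample ids")
        if self.os_time.shape != (n,) or self.os_event.shape != (n,):
            raise ClinicalValidationError("os_time/os_event length mismatch")
        bad = np.flatnonzero(~(self.os_time > 0))
        if bad.size:
            raise ClinicalValidationError(
                f"os_time must be > 0 (row {bad[0]}, sample {self.sample_ids[bad[0]]})"
            )
        ev = np.unique(self.os_event)
        if not np.isin(ev, [0, 1]).all():
            bad = np.flatnonzero(~np.isin(self.os_event, [0, 1]))[0]
            raise ClinicalValidationError(
                f"os_event must be 0/1 (row {bad}, sample {self.sample_ids[bad]})"
            )
        self.os_event = self.os_event.astype(int)
        if len(self.covariates):
            if list(self.covariates.index) != self.sample_ids:
                self.covariates = self.covariates.loc[self.sample_ids]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"os_time": self.os_time, "os_event": self.os_event},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        return df

    def subset(self, keep: list[str]) -> "ClinicalTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in keep]
        cov = self.covariates.iloc[rows] if len(self.covariates) else pd.DataFrame()
        return ClinicalTable(list(keep), self.os_time[rows], self.os_event[rows], cov)


@dataclass
class CohortBundle:
    """Linked matrices + clinical data for one cohort (plus planted truth)."""

    matrices: dict[Platform, ExpressionMatrix]
    clinical: ClinicalTable
    true_labels: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        self.matrices = {Platform(k): v for k, v in self.matrices.items()}
        all_samples = set()
        for m in self.matrices.values():
            all_samples.update(m.sample_ids)
        orphans = [s for s in self.clinical.sample_ids if s not in all_samples]
        if orphans:
            raise ClinicalValidationError(
                f"clinical samples absent from every matrix: {orphans[:5]}"
            )


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, platform: Platform | str,
                scale_flag: ScaleFlag | str = ScaleFlag.raw) -> ExpressionMatrix:
    """Read a feature-by-sample expression TSV.

    First column is the feature id, header row carries sample ids, body is
    numeric with literal ``NA`` for missing cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise MatrixFormatError(f"{path}: duplicate feature id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col].to_numpy()):
            if cell == "NA" or cell == "":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: non-numeric cell {cell!r} at feature "
                    f"{df.index[i]!r} (row {i + 2}), sample {col!r} (col {j + 2})"
                ) from None
    return ExpressionMatrix(list(df.index), list(df.columns), values,
                            platform=Platform(platform),
                            scale_flag=ScaleFlag(scale_flag))


def write_matrix(m: ExpressionMatrix, path: str | Path) -> Path:
    """Write an expression matrix as TSV with >= 12 significant digits."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(m.sample_ids) + "\n")
        for fid, row in zip(m.feature_ids, m.values):
            cells = ["NA" if np.isnan(v) else format(v, ".15g") for v in row]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")
    return path


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV (sample_id, os_time, os_event, then covariates)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ClinicalValidationError(f"{path}: missing columns {sorted(missing)}")
    cov_cols = [c for c in df.columns if c not in required]
    cov = df[cov_cols].copy()
    cov.index = pd.Index(df["sample_id"].astype(str))
    return ClinicalTable(
        list(df["sample_id"].astype(str)),
        df["os_time"].to_numpy(dtype=float),
        df["os_event"].to_numpy(),
        cov,
    )


def write_clinical(ct: ClinicalTable, path: str | Path) -> Path:
    path = Path(path)
    ct.to_frame().to_csv(path, sep="\t", float_format="%.15g")
    return path
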