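"""Reading, writing and validation of expression / standard-error matrices.

The on-disk format is plain delimited text (TSV or CSV): a header row of
sample identifiers, a first column of feature identifiers, and a numeric
body of intensities.  Matrices are held in memory as :class:`ExpressionMatrix`
(features as rows, samples as columns), the container every metric in this
package consumes.

Intensities are expected on the log2 scale after ingestion.  Raw-scale files
can be transformed at read time (``log2_transform=True``); cells that are
empty, NA, or non-positive before the transform are floor-imputed to the
matrix-wide minimum positive value and counted per sample, since degraded
FFPE samples commonly carry "dead probes" with no signal above background
and dropping rows would desynchronize companion matrices.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SEMatrix",
    "MatrixFormatError",
    "read_matrix",
    "read_se_matrix",
    "write_matrix",
    "write_qc_report",
    "read_qc_report",
]


class MatrixFormatError(ValueError):
    """Raised when a delimited matrix file violates the expected layout."""


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if any(not s for s in ids):
        raise MatrixFormatError(f"empty {what} identifier")
    seen: set[str] = set()
    for s in ids:
        if s in seen:
            raise MatrixFormatError(f"duplicate {what} identifier: {s!r}")
        seen.add(s)
    return ids


@dataclass
class ExpressionMatrix:
    """A feature x sample matrix of log2 background-corrected intensities.

    The underlying data model is the usual log-linear decomposition of a
    background-corrected intensity into a true feature abundance, a
    systematic per-array bias removed by normalization, and mean-zero
    feature-specific noise.  Only the observed sum is stored here; the
    latent terms are estimated (or bounded) by the normalization and QC
    modules.

    Parameters
    ----------
    values
        ``(p, n)`` array of finite reals, features as rows.
    feature_ids, sample_ids
        Unique, non-empty identifiers for rows and columns.
    log_scale
        Provenance flag: whether values are on the log2 scale.
    n_floored
        Per-sample count of cells floor-imputed at ingestion.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    log_scale: bool = True
    n_floored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixFormatError("values must be a 2-D array")
        p, n = self.values.shape
        if p < 2 or n < 2:
            raise MatrixFormatError(
                f"matrix must have at least 2 features and 2 samples, got {p} x {n}"
            )
        self.feature_ids = _check_ids(self.feature_ids, "feature")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if len(self.feature_ids) != p or len(self.sample_ids) != n:
            raise MatrixFormatError(
                "identifier counts do not match matrix shape: "
                f"{len(self.feature_ids)} features / {len(self.sample_ids)} samples "
                f"for a {p} x {n} matrix"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixFormatError(
                f"non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.n_floored is None:
            self.n_floored = np.zeros(n, dtype=int)
        else:
            self.n_floored = np.asarray(self.n_floored, dtype=int)
            if self.n_floored.shape != (n,):
                raise MatrixFormatError("n_floored must have one entry per sample")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Column-subset preserving the order given in ``sample_ids``."""
        idx = [self.sample_index(s) for s in sample_ids]
        return ExpressionMatrix(
            values=self.values[:, idx].copy(),
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            log_scale=self.log_scale,
            n_floored=self.n_floored[idx].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            log_scale=self.log_scale,
            n_floored=self.n_floored.copy(),
        )


@dataclass
class SEMatrix:
    """Per-cell standard errors of normalized intensities, companion to an
    :class:`ExpressionMatrix` (same shape and identifiers, all values >= 0)."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixFormatError("values must be a 2-D array")
        self.feature_ids = _check_ids(self.feature_ids, "feature")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        p, n = self.values.shape
        if len(self.feature_ids) != p or len(self.sample_ids) != n:
            raise MatrixFormatError("identifier counts do not match matrix shape")
        if not np.all(np.isfinite(self.values)):
            raise MatrixFormatError("standard errors must be finite")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise MatrixFormatError(
                f"negative standard error at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    def check_companion(self, em: ExpressionMatrix) -> None:
        if (
            self.feature_ids != em.feature_ids
            or self.sample_ids != em.sample_ids
        ):
            raise MatrixFormatError(
                "SE matrix identifiers do not match the expression matrix"
            )


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_header(path: Path, sep: str) -> None:
    # pandas silently de-duplicates repeated header names, so check them here
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_ids(header[1:], "sample")


def _parse_body(df: pd.DataFrame) -> np.ndarray:
    """Convert a string-typed frame to floats, locating the first bad cell."""
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        raw = df[col]
        # a cell is malformed when it is non-empty text that fails conversion
        bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        bad &= ~raw.astype(str).str.strip().str.upper().isin({"NA", "NAN"})
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise MatrixFormatError(
                f"non-numeric cell {raw.iloc[i]!r} at feature "
                f"{df.index[i]!r}, sample {col!r}"
            )
        out[:, j] = converted.to_numpy(dtype=float)
    return out


def read_matrix(
    path: str | Path,
    delimiter: str | None = None,
    log2_transform: bool = False,
    pseudocount: float = 0.0,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from delimited text.

    The first row holds sample identifiers, the first column feature
    identifiers.  With ``log2_transform`` the body is treated as raw-scale:
    empty/NA/non-positive cells are floor-imputed to the matrix-wide minimum
    positive value, counted per sample, then ``log2(x + pseudocount)`` is
    applied.  Without it the body is taken to be log2 already and only
    empty/NA cells are imputed (to the matrix-wide minimum finite value).

    Parameters
    ----------
    delimiter
        Field separator; inferred from the extension when omitted
        (``.csv`` -> comma, otherwise tab).
    transpose
        Set when the file stores samples as rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    sep = _infer_delimiter(path, delimiter)
    _check_header(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise MatrixFormatError(f"no data columns parsed from {path} (sep={sep!r})")
    if transpose:
        df = df.T
    feature_ids = _check_ids(df.index, "feature")
    sample_ids = _check_ids(df.columns, "sample")
    values = _parse_body(df)

    if log2_transform:
        invalid = ~np.isfinite(values) | (values <= 0)
        n_floored = invalid.sum(axis=0).astype(int)
        if invalid.all():
            raise MatrixFormatError("no positive values to define the floor")
        floor = values[~invalid].min() if invalid.any() else None
        if floor is not None:
            values = np.where(invalid, floor, values)
        values = np.log2(values + pseudocount)
        if not np.all(np.isfinite(values)):
            raise MatrixFormatError(
                "log2 transform produced non-finite values; "
                "use a positive pseudocount"
            )
    else:
        invalid = ~np.isfinite(values)
        n_floored = invalid.sum(axis=0).astype(int)
        if invalid.any():
            if invalid.all():
                raise MatrixFormatError("matrix contains no finite values")
            values = np.where(invalid, values[~invalid].min(), values)

    return ExpressionMatrix(
        values=values,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        log_scale=True,
        n_floored=n_floored,
    )


def read_se_matrix(path: str | Path, delimiter: str | None = None) -> SEMatrix:
    """Read a standard-error matrix (same layout as the expression matrix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    return SEMatrix(
        values=_parse_body(df),
        feature_ids=_check_ids(df.index, "feature"),
        sample_ids=_check_ids(df.columns, "sample"),
    )


def write_matrix(
    em: ExpressionMatrix | SEMatrix,
    path: str | Path,
    delimiter: str | None = None,
) -> None:
    """Write a matrix as delimited text, round-trippable through
    :func:`read_matrix` to better than 1e-9 relative."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.DataFrame(em.values, index=em.feature_ids, columns=em.sample_ids)
    df.to_csv(path, sep=sep, float_format="%.12g")


# ---------------------------------------------------------------------------
# QC report serialization

# Fixed column order for the TSV report; one row per sample.
QC_REPORT_FIELDS = [
    "sample_id",
    "stress",
    "dfarray75",
    "rle_median",
    "rle_iqr",
    "nuse_median",
    "lumi_distance",
    "lumi_flag",
    "iqr",
    "skew",
    "quadrant",
    "n_floored",
    "flags",
]


def _fmt_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    if isinstance(value, (set, frozenset, list, tuple)):
        return ";".join(sorted(str(v) for v in value))
    return str(value)


def write_qc_report(records, path: str | Path, format: str = "tsv") -> None:
    """Write per-sample QC records as TSV (one row per sample, 6 significant
    digits) or JSON (full precision).  Round-trips through
    :func:`read_qc_report`."""
    records = list(records)
    if not records:
        raise ValueError("no QC records to write")
    path = Path(path)
    dicts = [dataclasses.asdict(r) for r in records]
    if format == "tsv":
        lines = ["\t".join(QC_REPORT_FIELDS)]
        for d in dicts:
            lines.append("\t".join(_fmt_cell(d[f]) for f in QC_REPORT_FIELDS))
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        for d in dicts:
            d["flags"] = sorted(d["flags"])
            for k, v in d.items():
                if isinstance(v, float) and math.isnan(v):
                    d[k] = None
        path.write_text(json.dumps(dicts, indent=1) + "\n")
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_qc_report(path: str | Path):
    """Read a QC report written by :func:`write_qc_report` back into
    :class:`~arrayqc.qc_metrics.ArrayQC` records."""
    from .qc_metrics import ArrayQC  # local import to avoid a cycle

    path = Path(path)
    text = path.read_text()
    records = []
    if text.lstrip().startswith("["):
        for d in json.loads(text):
            d["flags"] = set(d.get("flags") or [])
            for k in ("stress", "dfarray75", "rle_median", "rle_iqr",
                      "nuse_median", "lumi_distance", "iqr", "skew"):
                if d.get(k) is None and k != "nuse_median":
                    d[k] = float("nan")
            records.append(ArrayQC(**d))
        return records
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header != QC_REPORT_FIELDS:
        raise MatrixFormatError("unrecognized QC report header")
    for ln in lines[1:]:
        cells = dict(zip(header, ln.split("\t")))
        nuse = cells["nuse_median"]
        records.append(
            ArrayQC(
                sample_id=cells["sample_id"],
                stress=float("nan") if cells["stress"] == "NA" else float(cells["stress"]),
                dfarray75=float("nan") if cells["dfarray75"] == "NA" else float(cells["dfarray75"]),
                rle_median=float(cells["rle_median"]),
                rle_iqr=float(cells["rle_iqr"]),
                nuse_median=None if nuse == "NA" else float(nuse),
                lumi_distance=float("nan") if cells["lumi_distance"] == "NA" else float(cells["lumi_distance"]),
                lumi_flag=cells["lumi_flag"] == "True",
                iqr=float(cells["iqr"]),
                skew=float("nan") if cells["skew"] == "NA" else float(cells["skew"]),
                quadrant=cells["quadrant"],
                n_floored=int(cells["n_floored"]),
                flags=set(cells["flags"].split(";")) - {""},
            )
        )
    return records
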