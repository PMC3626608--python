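"""Per-array quality metrics for expression matrices from degraded samples.

Two metrics are the centerpiece:

* **Stress** — how much an array had to be deformed during normalization.
  For array j with normalization shifts S_ij, the log2 stress is the median
  over features of |S_ij - mean_i(S_ij)|, reported on the fold-change scale
  as 2 to that power.  Mean-centering makes the metric blind to constant
  per-array offsets (a uniformly brighter scan is not a quality problem);
  the absolute value treats up- and down-adjustments as equally stressed.
  A median Stress of 2 means half of the array's features had to be adjusted
  by two-fold or more to fit the experiment.

* **dfArray** — how far an array sits from the rest of the experiment after
  normalization, per feature, in standard-deviation units:
  ``(Y'_ij - center_i(-j)) / spread_i(-j)`` where center and spread are
  either the exact leave-one-out mean / sample sd, or their one-pass robust
  surrogates (across-array median and 1.4826 * MAD).  The per-array summary
  is the 0.75 quantile of |dfArray| — an array whose 25% most deviant
  features sit more than two standard deviations from the consensus is
  suspect.

Alongside these are the comparison metrics in common use — RLE, NUSE (with
a user-supplied standard-error matrix), the distance-to-average-array
outlier rule — plus the IQR/skew quadrant classification of raw intensity
distributions, and the assembly of everything into per-sample
:class:`ArrayQC` records with threshold flags.

All quantiles use linear interpolation between order statistics (the
"type 7" convention), fixed for determinism across implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .io_matrix import ExpressionMatrix, SEMatrix
from .normalization import NormalizationResult

__all__ = [
    "ArrayQC",
    "QCThresholds",
    "stress_from_shifts",
    "compute_stress",
    "compute_dfarray",
    "compute_rle",
    "compute_nuse",
    "compute_lumi_outlier",
    "iqr_skew",
    "classify_quadrant",
    "assemble_array_qc",
]

#: MAD-to-sd consistency factor under normality; keeps the "two standard
#: deviations" reading of the dfArray cutoff literal for the robust variant.
MAD_SCALE = 1.4826


@dataclass
class QCThresholds:
    """Cutoffs for flagging arrays; all comparisons are inclusive (>=).

    Defaults follow the two-stage FFPE workflow: remove arrays with
    Stress >= 1.5, investigate arrays with dfArray75 >= 2, distance-outlier
    threshold Th = 2, median NUSE >= 1.25, and raw-distribution quadrant
    cutoffs IQR > 2 / skew > 0.2.
    """

    stress_cut: float = 1.5
    dfarray_cut: float = 2.0
    lumi_th: float = 2.0
    nuse_cut: float = 1.25
    dfarray_quantile: float = 0.75
    iqr_cut: float = 2.0
    skew_cut: float = 0.2

    def __post_init__(self) -> None:
        for name in ("stress_cut", "dfarray_cut", "lumi_th", "nuse_cut", "iqr_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.dfarray_quantile < 1):
            raise ValueError("dfarray_quantile must be in (0, 1)")
        if not (0 < self.skew_cut < 1):
            raise ValueError("skew_cut must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "QCThresholds":
        """Load thresholds from YAML or plain ``key = value`` lines."""
        import yaml

        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = None
        if not isinstance(data, dict):
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = float(value)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass
class ArrayQC:
    """All per-sample quality summaries and flags for one array."""

    sample_id: str
    stress: float = float("nan")
    dfarray75: float = float("nan")
    rle_median: float = float("nan")
    rle_iqr: float = float("nan")
    nuse_median: float | None = None
    lumi_distance: float = float("nan")
    lumi_flag: bool = False
    iqr: float = float("nan")
    skew: float = float("nan")
    quadrant: str = "R4"
    n_floored: int = 0
    flags: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Stress


def stress_from_shifts(shifts: np.ndarray) -> np.ndarray:
    """Per-array Stress (fold-change scale) from a p x n shift matrix."""
    S = np.asarray(shifts, dtype=float)
    centered = np.abs(S - S.mean(axis=0, keepdims=True))
    return 2.0 ** np.median(centered, axis=0)


def compute_stress(result: NormalizationResult) -> np.ndarray:
    """Stress of each array: 2**(median_i |S_ij - mean_i S_ij|).

    Always >= 1; equals 1 exactly when the array needed only a constant
    shift (or none at all) to match the target distribution.
    """
    return stress_from_shifts(result.shifts)


# ---------------------------------------------------------------------------
# dfArray


def compute_dfarray(
    Yprime: ExpressionMatrix,
    mode: Literal["robust", "exact_loo"] = "robust",
    q: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized deviation of each array from the rest, post-normalization.

    ``exact_loo`` standardizes each cell by the leave-one-out mean and
    sample standard deviation of its feature; ``robust`` replaces these with
    the across-array median and 1.4826 * MAD, computed once per feature.
    Returns the signed p x n grid and the per-array summary: the ``q``
    quantile over features of |dfArray|.

    Cells whose spread estimate is zero are set to 0 when the deviation is
    also zero (a feature constant across arrays carries no evidence either
    way) and otherwise excluded from that array's quantile summary as NaN —
    dead-probe floors make zero MAD common in degraded data.
    """
    X = Yprime.values
    p, n = X.shape
    if n < 3:
        raise ValueError("dfArray requires n >= 3 arrays")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")

    if mode == "robust":
        center = np.median(X, axis=1, keepdims=True)
        mad = np.median(np.abs(X - center), axis=1, keepdims=True)
        spread = MAD_SCALE * mad
        num = X - center
        num = np.broadcast_to(num, X.shape).copy()
        spread = np.broadcast_to(spread, X.shape).copy()
    elif mode == "exact_loo":
        s1 = X.sum(axis=1, keepdims=True)
        s2 = (X**2).sum(axis=1, keepdims=True)
        loo_mean = (s1 - X) / (n - 1)
        # sample variance of the n-1 values excluding column j
        loo_ss = s2 - X**2 - (n - 1) * loo_mean**2
        loo_var = np.maximum(loo_ss, 0.0) / (n - 2)
        num = X - loo_mean
        spread = np.sqrt(loo_var)
    else:
        raise ValueError(f"unknown dfArray mode: {mode!r}")

    grid = np.empty_like(X)
    zero = spread <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        grid = np.where(zero, np.nan, num / np.where(zero, 1.0, spread))
    grid[zero & (np.abs(num) < 1e-12)] = 0.0

    with np.errstate(invalid="ignore"):
        summary = np.nanquantile(np.abs(grid), q, axis=0)
    return grid, summary


# ---------------------------------------------------------------------------
# RLE


def compute_rle(Yprime: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative log expression: deviation from the across-array feature median.

    Returns the p x n grid plus per-array median and IQR of the grid
    columns.  An array whose RLE median sits away from zero has
    predominantly low- or high-expressed features relative to the rest of
    the experiment.
    """
    X = Yprime.values
    grid = X - np.median(X, axis=1, keepdims=True)
    med = np.median(grid, axis=0)
    q1, q3 = np.quantile(grid, [0.25, 0.75], axis=0)
    return grid, med, q3 - q1


# ---------------------------------------------------------------------------
# NUSE


def compute_nuse(
    se: SEMatrix,
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Normalized unscaled standard error relative to the per-feature median.

    Each cell is SE_ij divided by the across-array median SE of its feature
    (or, when ``reference`` is given, by that per-feature reference vector —
    the archive-based global variant).  Returns the grid, the per-array
    median over features, and the number of features dropped because their
    denominator was zero.

    An array whose median NUSE is 1.25 has feature-level variability 25%
    higher than a typical array.
    """
    X = se.values
    if reference is not None:
        denom = np.asarray(reference, dtype=float).reshape(-1)
        if denom.shape[0] != X.shape[0]:
            raise ValueError("reference length must equal the feature count")
    else:
        denom = np.median(X, axis=1)
    usable = denom > 0
    n_dropped = int((~usable).sum())
    if not usable.any():
        raise ValueError("all features have zero median standard error")
    grid = np.full_like(X, np.nan)
    grid[usable] = X[usable] / denom[usable, None]
    medians = np.nanmedian(grid, axis=0)
    return grid, medians, n_dropped


# ---------------------------------------------------------------------------
# distance-to-average-array outlier


def compute_lumi_outlier(
    Y: ExpressionMatrix,
    dissimilarity: Literal["euclidean", "one_minus_correlation"] = "euclidean",
    th: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance of each standardized array profile from the robust average.

    Features are mean-centered and scaled to unit sd across arrays
    (zero-spread features dropped); the target profile is the per-feature
    median of the standardized data.  The dissimilarity of array j from the
    target is either the Euclidean distance or one minus the Pearson
    correlation.  Array j is flagged when its distance exceeds
    ``th * median(distance)`` (and the median distance is positive).

    Flags are invariant to duplicating features and to permuting samples.
    """
    if th <= 0:
        raise ValueError("th must be strictly positive")
    X = Y.values
    p, n = X.shape
    if n < 3:
        raise ValueError("distance outlier detection requires n >= 3 arrays")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if keep.sum() < 2:
        raise ValueError(
            "fewer than 2 features with positive spread; "
            "cannot standardize array profiles"
        )
    Z = (X[keep] - mean[keep]) / sd[keep]
    target = np.median(Z, axis=1)

    if dissimilarity == "euclidean":
        dist = np.sqrt(((Z - target[:, None]) ** 2).sum(axis=0))
    elif dissimilarity == "one_minus_correlation":
        dist = np.empty(n)
        for j in range(n):
            dist[j] = 1.0 - np.corrcoef(Z[:, j], target)[0, 1]
    else:
        raise ValueError(f"unknown dissimilarity: {dissimilarity!r}")

    med = np.median(dist)
    flags = (dist > th * med) & (med > 0)
    return dist, flags


# ---------------------------------------------------------------------------
# raw-distribution quadrants


def iqr_skew(values: np.ndarray) -> tuple[float, float]:
    """IQR and quartile skew of one array's intensity distribution.

    skew = (Q2 - Q1) / (Q3 - Q1); symmetric distributions give 0.5, and
    values near 0 indicate mass piled at the bottom of the range, as when
    most probes sit at the background floor.  Returns NaN skew for a
    degenerate (zero-IQR) distribution.
    """
    q1, q2, q3 = np.quantile(np.asarray(values, dtype=float), [0.25, 0.5, 0.75])
    iqr = q3 - q1
    if iqr <= 0:
        return float(iqr), float("nan")
    return float(iqr), float((q2 - q1) / iqr)


def classify_quadrant(
    Yraw: ExpressionMatrix,
    iqr_cut: float = 2.0,
    skew_cut: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Classify arrays into quality quadrants by raw-distribution shape.

    R1: IQR > iqr_cut and skew > skew_cut (well-behaved); R2: large IQR,
    low skew; R3: small IQR, high skew; R4: small IQR and low skew (worst).
    Arrays with a degenerate zero-IQR distribution get NaN skew and are
    forced to R4; their count is returned as the final element.
    """
    n = Yraw.n_samples
    iqrs = np.empty(n)
    skews = np.empty(n)
    quads: list[str] = []
    n_degenerate = 0
    for j in range(n):
        iqr, skew = iqr_skew(Yraw.values[:, j])
        iqrs[j] = iqr
        skews[j] = skew
        if not np.isfinite(skew):
            n_degenerate += 1
            quads.append("R4")
        elif iqr > iqr_cut:
            quads.append("R1" if skew > skew_cut else "R2")
        else:
            quads.append("R3" if skew > skew_cut else "R4")
    return iqrs, skews, quads, n_degenerate


# ---------------------------------------------------------------------------
# assembly


def assemble_array_qc(
    sample_ids: Sequence[str],
    thresholds: QCThresholds | None = None,
    stress: np.ndarray | None = None,
    dfarray75: np.ndarray | None = None,
    rle_median: np.ndarray | None = None,
    rle_iqr: np.ndarray | None = None,
    nuse_median: np.ndarray | None = None,
    lumi_distance: np.ndarray | None = None,
    lumi_flag: np.ndarray | None = None,
    iqr: np.ndarray | None = None,
    skew: np.ndarray | None = None,
    quadrant: Sequence[str] | None = None,
    n_floored: np.ndarray | None = None,
) -> list[ArrayQC]:
    """Combine metric outputs into one :class:`ArrayQC` record per sample.

    Flags use inclusive thresholds: ``stress_outlier`` when
    stress >= stress_cut, ``dfarray_outlier`` when dfarray75 >= dfarray_cut,
    ``nuse_outlier`` when the median NUSE >= nuse_cut (only if provided),
    and ``lumi_outlier`` as computed by the distance rule.  Metric arrays
    must be aligned with ``sample_ids``; pass only what was computed.
    """
    thresholds = thresholds or QCThresholds()
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    for name, arr in (
        ("stress", stress), ("dfarray75", dfarray75), ("rle_median", rle_median),
        ("rle_iqr", rle_iqr), ("nuse_median", nuse_median),
        ("lumi_distance", lumi_distance), ("lumi_flag", lumi_flag),
        ("iqr", iqr), ("skew", skew), ("n_floored", n_floored),
    ):
        if arr is not None and len(arr) != n:
            raise ValueError(f"{name} is not aligned with sample_ids "
                             f"({len(arr)} values for {n} samples)")
    if quadrant is not None and len(quadrant) != n:
        raise ValueError("quadrant is not aligned with sample_ids")

    records = []
    for j, sid in enumerate(sample_ids):
        flags: set[str] = set()
        rec = ArrayQC(sample_id=sid)
        if stress is not None:
            rec.stress = float(stress[j])
            if rec.stress >= thresholds.stress_cut:
                flags.add("stress_outlier")
        if dfarray75 is not None:
            rec.dfarray75 = float(dfarray75[j])
            if rec.dfarray75 >= thresholds.dfarray_cut:
                flags.add("dfarray_outlier")
        if rle_median is not None:
            rec.rle_median = float(rle_median[j])
        if rle_iqr is not None:
            rec.rle_iqr = float(rle_iqr[j])
        if nuse_median is not None:
            rec.nuse_median = float(nuse_median[j])
            if rec.nuse_median >= thresholds.nuse_cut:
                flags.add("nuse_outlier")
        if lumi_distance is not None:
            rec.lumi_distance = float(lumi_distance[j])
        if lumi_flag is not None and bool(lumi_flag[j]):
            rec.lumi_flag = True
            flags.add("lumi_outlier")
        if iqr is not None:
            rec.iqr = float(iqr[j])
        if skew is not None:
            rec.skew = float(skew[j])
        if quadrant is not None:
            rec.quadrant = str(quadrant[j])
        if n_floored is not None:
            rec.n_floored = int(n_floored[j])
        rec.flags = flags
        records.append(rec)
    return records
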