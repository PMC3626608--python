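"""Cost of keeping questionable arrays: variance inflation and bias.

The evaluation mimics the reference-versus-expanded design used to justify
array removal: normalize a clean reference set alone and record per-feature
means and variances; then add the questionable arrays, renormalize the
expanded set from raw, recompute the per-feature moments, and compare.
Because only a minority of features should be differentially expressed
between samples, the expanded-set moments should match the reference — any
systematic variance inflation or mean shift is damage introduced by the
added arrays.

Features are binned by reference-mean intensity percentile (equal-count
bins) and the per-feature variance ratios and mean differences are
median-smoothed within each bin, so the output reads as "variance inflation
as a function of expression level".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_matrix import ExpressionMatrix
from .normalization import quantile_normalize

__all__ = ["ImpactSummary", "evaluate_impact"]


@dataclass
class ImpactSummary:
    """Binned variance-ratio / bias profile of an expanded set versus its
    reference.

    ``bins`` are percentile edges on the reference-mean scale covering
    [0, 100]; ``variance_ratio`` and ``bias`` are per-bin medians of the
    per-feature expanded/reference variance ratio and expanded - reference
    mean difference.  ``intensity_markers`` gives the 25th/50th/75th
    percentiles of the reference feature means for orientation.
    """

    bins: np.ndarray
    variance_ratio: np.ndarray
    bias: np.ndarray
    n_features_per_bin: np.ndarray
    intensity_markers: tuple[float, float, float]
    n_features_excluded: int = 0

    def to_rows(self) -> list[dict]:
        return [
            {
                "bin_lo_pct": float(self.bins[i]),
                "bin_hi_pct": float(self.bins[i + 1]),
                "variance_ratio": float(self.variance_ratio[i]),
                "bias": float(self.bias[i]),
                "n_features": int(self.n_features_per_bin[i]),
            }
            for i in range(len(self.variance_ratio))
        ]


def evaluate_impact(
    Yraw: ExpressionMatrix,
    reference_ids: Sequence[str],
    added_ids: Sequence[str],
    n_bins: int = 20,
    expanded_reference_only: bool = False,
) -> ImpactSummary:
    """Quantify how adding arrays changes per-feature moments.

    The reference set is quantile-normalized alone; the reference-plus-added
    set is quantile-normalized from raw.  Per-feature means and variances
    are computed on each, the variance ratio (expanded / reference) and mean
    difference (expanded - reference) are formed, and features are binned
    into ``n_bins`` equal-count bins by reference-mean rank with per-bin
    median smoothing.

    Parameters
    ----------
    expanded_reference_only
        When set, expanded-set moments are computed over the reference
        columns only (isolating the distortion the added arrays impose on
        the reference samples through joint normalization) rather than over
        all columns of the expanded set.

    Features with zero reference variance are excluded from the ratio and
    counted in ``n_features_excluded``.
    """
    ref = list(reference_ids)
    add = list(added_ids)
    if not add:
        raise ValueError("added set must be nonempty")
    if set(ref) & set(add):
        raise ValueError("reference and added sets overlap")
    if len(ref) < 3:
        raise ValueError("reference set must contain at least 3 arrays")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    ref_norm = quantile_normalize(Yraw.subset_samples(ref)).normalized.values
    ref_mean = ref_norm.mean(axis=1)
    ref_var = ref_norm.var(axis=1, ddof=1)

    exp_norm = quantile_normalize(Yraw.subset_samples(ref + add)).normalized
    if expanded_reference_only:
        X = exp_norm.subset_samples(ref).values
    else:
        X = exp_norm.values
    exp_mean = X.mean(axis=1)
    exp_var = X.var(axis=1, ddof=1)

    usable = ref_var > 0
    n_excluded = int((~usable).sum())
    if not usable.any():
        raise ValueError("no feature has positive reference variance")
    ratio = exp_var[usable] / ref_var[usable]
    diff = exp_mean[usable] - ref_mean[usable]
    means = ref_mean[usable]

    order = np.argsort(means, kind="stable")
    edges_idx = np.linspace(0, order.size, n_bins + 1).round().astype(int)
    bins = np.linspace(0.0, 100.0, n_bins + 1)
    variance_ratio = np.empty(n_bins)
    bias = np.empty(n_bins)
    counts = np.empty(n_bins, dtype=int)
    for b in range(n_bins):
        idx = order[edges_idx[b] : edges_idx[b + 1]]
        if idx.size == 0:
            variance_ratio[b] = np.nan
            bias[b] = np.nan
            counts[b] = 0
            continue
        variance_ratio[b] = np.median(ratio[idx])
        bias[b] = np.median(diff[idx])
        counts[b] = idx.size

    q25, q50, q75 = np.quantile(means, [0.25, 0.5, 0.75])
    return ImpactSummary(
        bins=bins,
        variance_ratio=variance_ratio,
        bias=bias,
        n_features_per_bin=counts,
        intensity_markers=(float(q25), float(q50), float(q75)),
        n_features_excluded=n_excluded,
    )
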