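"""Synthetic FFPE-like expression data with ground-truth quality labels.

Archival (formalin-fixed, paraffin-embedded) samples degrade heterogeneously:
some arrays fail outright, on others a subset of probes dies while the rest
work, and intensity distributions vary wildly in spread and shape.  This
module generates log2 expression matrices that emulate that phenomenology so
every metric and pipeline in the package can be exercised — with known
labels — without any external data.

Good arrays follow the additive model Y_ij = mu_i + a_j + eps_ij: a
two-component feature baseline (expressed features around ``baseline_mean``,
the rest at a tight background floor), a small constant array offset, and
feature-specific Gaussian noise.  Degradation is then applied per array by
one of five operators, each constructed to trip exactly one failure mode a
specific metric claims to catch:

* ``dead_collapse`` — a severity fraction of the expressed features is
  pulled down to background ("dead probes"); collapses the IQR, so the
  marginal distribution diverges and normalization Stress is large.
* ``range_compression`` — the whole distribution is squeezed toward its
  median by (1 - severity); small IQR, large Stress.
* ``skewed_degradation`` — the lower 70% of the distribution is compressed
  toward background, piling mass at the floor and driving the quartile skew
  statistic (Q2-Q1)/IQR toward 0.
* ``profile_discordant`` — a severity fraction of features swap baselines
  among themselves, so the marginal distribution is preserved (invisible to
  Stress and distribution-shape checks) but the feature profile is broken,
  which dfArray and distance-to-average metrics catch post-normalization.
* ``constant_shift`` — a uniform additive offset (a brighter scan); by
  design *not* a quality defect, and mean-centering makes Stress blind
  to it.

Defaults are chosen so clean arrays land in the well-behaved quadrant
(IQR > 2, skew > 0.2) and :func:`default_ffpe_config` mirrors a plate-sized
study in which roughly 15% of arrays are degraded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .io_matrix import ExpressionMatrix

__all__ = [
    "OutlierSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "generate",
    "generate_monotone_distortion_set",
    "default_ffpe_config",
]

OUTLIER_KINDS = (
    "dead_collapse",
    "range_compression",
    "skewed_degradation",
    "profile_discordant",
    "constant_shift",
)

#: fraction of the distribution compressed toward background by
#: skewed_degradation; 0.7 puts the median well inside the compressed mass
#: so the quartile skew statistic drops below the 0.2 cutoff.
_SKEW_COMPRESS_FRACTION = 0.7

#: log2 offset applied by constant_shift at severity 1 (a scanner twice as
#: bright shifts every probe by +1; we allow up to +2).
_SHIFT_AT_FULL_SEVERITY = 2.0


@dataclass
class OutlierSpec:
    """One batch of degraded arrays: operator kind, count, severity in (0, 1]."""

    kind: str
    n_arrays: int
    severity: float

    def __post_init__(self) -> None:
        if self.kind not in OUTLIER_KINDS:
            raise ValueError(
                f"unknown outlier kind {self.kind!r}; choose from {OUTLIER_KINDS}"
            )
        if self.n_arrays < 1:
            raise ValueError("n_arrays must be >= 1")
        if not (0 < self.severity <= 1):
            raise ValueError("severity must be in (0, 1]")


@dataclass
class SimulationConfig:
    """Generative settings for one synthetic experiment.

    ``frac_expressed`` of the features carry signal around ``baseline_mean``
    (log2 units, sd ``baseline_sd``); the remainder sit at the background
    floor.  Per-feature noise sds are drawn around ``noise_sd`` so the error
    scale is feature specific, and each array receives a small constant
    offset (sd ``array_offset_sd``) emulating scanner brightness variation.
    """

    p: int = 5000
    n: int = 96
    seed: int = 0
    frac_expressed: float = 0.7
    baseline_mean: float = 9.0
    baseline_sd: float = 1.5
    background_level: float = 5.0
    background_sd: float = 0.3
    noise_sd: float = 0.25
    array_offset_sd: float = 0.1
    outlier_specs: list[OutlierSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.p < 10:
            raise ValueError("p must be >= 10")
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if not (0 <= self.frac_expressed <= 1):
            raise ValueError("frac_expressed must be in [0, 1]")
        if self.noise_sd < 0 or self.background_sd < 0 or self.array_offset_sd < 0:
            raise ValueError("noise/offset scales must be nonnegative")
        self.outlier_specs = [
            s if isinstance(s, OutlierSpec) else OutlierSpec(**s)
            for s in self.outlier_specs
        ]
        if sum(s.n_arrays for s in self.outlier_specs) > self.n:
            raise ValueError("more outlier arrays requested than samples")


@dataclass
class SyntheticTruth:
    """Ground truth for a generated matrix: per-sample label ("good" or an
    operator kind), the severity applied (0 for good arrays), and the true
    feature baseline vector."""

    labels: list[str]
    severities: np.ndarray
    mu: np.ndarray

    @property
    def outlier_ids(self) -> set[int]:
        return {j for j, lab in enumerate(self.labels) if lab != "good"}


def default_ffpe_config(seed: int = 0, p: int = 5000, n: int = 96) -> SimulationConfig:
    """A plate-sized degraded-cohort scenario: ~15% of arrays are poor
    quality — mostly dead-probe collapse, plus a handful of
    profile-discordant arrays whose marginal distributions look normal."""
    n_dead = max(1, round(0.104 * n))
    n_disc = max(1, round(0.052 * n))
    return SimulationConfig(
        p=p,
        n=n,
        seed=seed,
        outlier_specs=[
            OutlierSpec("dead_collapse", n_dead, severity=0.7),
            OutlierSpec("profile_discordant", n_disc, severity=0.4),
        ],
    )


def _apply_operator(
    rng: np.random.Generator,
    col: np.ndarray,
    kind: str,
    severity: float,
    mu: np.ndarray,
    sigma: np.ndarray,
    offset: float,
    expressed: np.ndarray,
    background_level: float,
    background_sd: float,
) -> np.ndarray:
    p = col.shape[0]
    if kind == "dead_collapse":
        expr_idx = np.flatnonzero(expressed)
        k = int(round(severity * expr_idx.size))
        dead = rng.choice(expr_idx, size=k, replace=False)
        col = col.copy()
        col[dead] = background_level + offset + background_sd * rng.standard_normal(k)
        return col
    if kind == "range_compression":
        center = np.median(col)
        return center + (1.0 - severity) * (col - center)
    if kind == "skewed_degradation":
        thr = np.quantile(col, _SKEW_COMPRESS_FRACTION)
        col = col.copy()
        low = col < thr
        floor = background_level + offset
        col[low] = floor + (1.0 - severity) * (col[low] - floor)
        return col
    if kind == "profile_discordant":
        sel = rng.choice(p, size=int(round(severity * p)), replace=False)
        perm = rng.permutation(sel)
        col = col.copy()
        col[sel] = mu[perm] + offset + sigma[perm] * rng.standard_normal(sel.size)
        return col
    if kind == "constant_shift":
        return col + _SHIFT_AT_FULL_SEVERITY * severity
    raise ValueError(f"unknown outlier kind: {kind!r}")


def generate(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a synthetic log2 expression matrix with ground-truth labels.

    Deterministic under ``config.seed``: the same configuration yields a
    bitwise-identical matrix and truth.  Outlier arrays are assigned to
    distinct random columns; every other array is labeled "good".
    """
    rng = np.random.default_rng(config.seed)
    p, n = config.p, config.n

    n_expr = int(round(config.frac_expressed * p))
    expressed = np.zeros(p, dtype=bool)
    expressed[rng.choice(p, size=n_expr, replace=False)] = True
    mu = np.where(
        expressed,
        config.baseline_mean + config.baseline_sd * rng.standard_normal(p),
        config.background_level + config.background_sd * rng.standard_normal(p),
    )
    sigma = config.noise_sd * np.exp(0.3 * rng.standard_normal(p))
    offsets = config.array_offset_sd * rng.standard_normal(n)

    Y = mu[:, None] + offsets[None, :] + sigma[:, None] * rng.standard_normal((p, n))

    labels = ["good"] * n
    severities = np.zeros(n)
    n_outliers = sum(s.n_arrays for s in config.outlier_specs)
    chosen = rng.choice(n, size=n_outliers, replace=False)
    cursor = 0
    for spec in config.outlier_specs:
        for j in chosen[cursor : cursor + spec.n_arrays]:
            Y[:, j] = _apply_operator(
                rng, Y[:, j], spec.kind, spec.severity, mu, sigma,
                offsets[j], expressed, config.background_level,
                config.background_sd,
            )
            labels[j] = spec.kind
            severities[j] = spec.severity
        cursor += spec.n_arrays

    em = ExpressionMatrix(
        values=Y,
        feature_ids=[f"F{i:05d}" for i in range(p)],
        sample_ids=[f"S{j:03d}" for j in range(n)],
        log_scale=True,
    )
    return em, SyntheticTruth(labels=labels, severities=severities, mu=mu)


def generate_monotone_distortion_set(
    p: int, n: int, seed: int
) -> ExpressionMatrix:
    """Noiseless arrays that are strictly increasing distortions of one
    latent target profile.

    Each column applies an independent random monotone cubic (a PCHIP
    interpolant through strictly increasing control points) to the same
    latent vector, so all columns are rank-identical to the target.  This
    is the canonical fixture for feature-specific normalization: a scheme
    that corrects intensity-dependent distortion should drive each array's
    median RLE to approximately zero on this input.
    """
    if p < 100:
        raise ValueError("p must be >= 100")
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = np.random.default_rng(seed)
    # latent profile: a continuous two-component mixture, no ties a.s.
    expressed = rng.random(p) < 0.7
    t = np.where(
        expressed,
        9.0 + 1.5 * rng.standard_normal(p),
        5.0 + 0.5 * rng.standard_normal(p),
    )
    lo, hi = t.min(), t.max()
    knots_x = np.linspace(lo - 0.5, hi + 0.5, 6)
    Y = np.empty((p, n))
    for j in range(n):
        # strictly increasing knot values with random spacing and offset
        increments = rng.uniform(0.3, 1.7, size=5)
        increments *= (hi - lo + 1.0) / increments.sum()
        knots_y = (lo + rng.uniform(-1.0, 1.0)) + np.concatenate(
            ([0.0], np.cumsum(increments))
        )
        Y[:, j] = PchipInterpolator(knots_x, knots_y)(t)
    return ExpressionMatrix(
        values=Y,
        feature_ids=[f"F{i:05d}" for i in range(p)],
        sample_ids=[f"S{j:03d}" for j in range(n)],
        log_scale=True,
    )
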