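"""Two-stage array quality workflows and their comparison.

Both workflows follow the same remove-renormalize pattern, differing in the
metric driving removal:

* the Stress/dfArray workflow (:func:`run_mahoney`): quantile-normalize all
  arrays, remove those with Stress >= 1.5 (stage 1), renormalize the
  survivors from the raw matrix, flag arrays with dfArray75 >= 2 on the
  renormalized data (stage 2, "investigate" — removal is opt-in), then run
  a final normalization of the kept set;

* the distance-outlier workflow (:func:`run_chow`): flag arrays whose
  distance to the average array exceeds Th x median on the *raw* log2 data
  (stage 1), remove, renormalize, repeat the distance rule on normalized
  data (stage 2, removed), final normalization.

Renormalization always restarts from the raw matrix of the surviving
samples — normalized data are never normalized again.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .io_matrix import ExpressionMatrix
from .normalization import NormalizationResult, quantile_normalize
from .qc_metrics import (
    ArrayQC,
    QCThresholds,
    assemble_array_qc,
    classify_quadrant,
    compute_dfarray,
    compute_lumi_outlier,
    compute_rle,
    compute_stress,
)

__all__ = ["PipelineResult", "run_mahoney", "run_chow", "concordance", "Concordance"]

#: dfArray's leave-one-out denominator needs at least 3 arrays.
MIN_SURVIVORS = 3


@dataclass
class PipelineResult:
    """Outcome of a two-stage QC workflow.

    ``kept`` always equals all samples minus ``stage1_removed`` minus
    (``stage2_flagged`` when stage 2 removes); ``per_stage_qc`` keeps the
    full metric record computed at each stage for audit.
    """

    method: Literal["mahoney", "chow"]
    all_samples: list[str]
    stage1_removed: set[str]
    stage2_flagged: set[str]
    kept: set[str]
    final: NormalizationResult
    per_stage_qc: dict[str, list[ArrayQC]] = field(default_factory=dict)
    stage2_removed: bool = False

    @property
    def flagged(self) -> set[str]:
        """Union of stage-1 removals and stage-2 flags."""
        return self.stage1_removed | self.stage2_flagged


def _check_survivors(survivors: list[str], stage: str) -> None:
    if len(survivors) < MIN_SURVIVORS:
        raise ValueError(
            f"only {len(survivors)} arrays survive {stage}; "
            f"at least {MIN_SURVIVORS} are required to continue"
        )


def run_mahoney(
    Yraw: ExpressionMatrix,
    thresholds: QCThresholds | None = None,
    remove_stage2: bool = False,
) -> PipelineResult:
    """Stress-then-dfArray two-stage workflow on a raw log2 matrix.

    Stage 0 computes Stress, dfArray, RLE and the distribution quadrants on
    the full quantile-normalized set (the pre-removal dfArray is diagnostic
    only).  Stage 1 removes arrays with Stress >= ``stress_cut``.  The
    survivors are renormalized from raw and arrays with dfArray75 >=
    ``dfarray_cut`` are flagged; they are removed only when
    ``remove_stage2`` is set.  The final result is a fresh quantile
    normalization of the kept samples.
    """
    thresholds = thresholds or QCThresholds()
    if Yraw.n_samples < 4:
        raise ValueError("pipeline requires at least 4 arrays")
    all_samples = list(Yraw.sample_ids)

    # stage 0: full-set normalization and diagnostics
    norm0 = quantile_normalize(Yraw)
    stress0 = compute_stress(norm0)
    _, df0 = compute_dfarray(norm0.normalized, mode="robust",
                             q=thresholds.dfarray_quantile)
    _, rle_med0, rle_iqr0 = compute_rle(norm0.normalized)
    iqr0, skew0, quad0, _ = classify_quadrant(
        Yraw, thresholds.iqr_cut, thresholds.skew_cut
    )
    qc0 = assemble_array_qc(
        all_samples, thresholds, stress=stress0, dfarray75=df0,
        rle_median=rle_med0, rle_iqr=rle_iqr0, iqr=iqr0, skew=skew0,
        quadrant=quad0, n_floored=Yraw.n_floored,
    )

    stage1_removed = {r.sample_id for r in qc0 if "stress_outlier" in r.flags}
    survivors = [s for s in all_samples if s not in stage1_removed]
    _check_survivors(survivors, "stage 1 (Stress)")

    # stage 1 -> 2: renormalize survivors from raw, flag by dfArray
    raw_surv = Yraw.subset_samples(survivors)
    norm1 = quantile_normalize(raw_surv)
    stress1 = compute_stress(norm1)
    _, df1 = compute_dfarray(norm1.normalized, mode="robust",
                             q=thresholds.dfarray_quantile)
    _, rle_med1, rle_iqr1 = compute_rle(norm1.normalized)
    qc1 = assemble_array_qc(
        survivors, thresholds, stress=stress1, dfarray75=df1,
        rle_median=rle_med1, rle_iqr=rle_iqr1, n_floored=raw_surv.n_floored,
    )
    stage2_flagged = {r.sample_id for r in qc1 if "dfarray_outlier" in r.flags}

    if remove_stage2:
        kept = [s for s in survivors if s not in stage2_flagged]
        _check_survivors(kept, "stage 2 (dfArray)")
    else:
        kept = survivors

    final = quantile_normalize(Yraw.subset_samples(kept))
    return PipelineResult(
        method="mahoney",
        all_samples=all_samples,
        stage1_removed=stage1_removed,
        stage2_flagged=stage2_flagged,
        kept=set(kept),
        final=final,
        per_stage_qc={"stage0": qc0, "stage1": qc1},
        stage2_removed=remove_stage2,
    )


def run_chow(
    Yraw: ExpressionMatrix,
    th: float = 2.0,
    dissimilarity: Literal["euclidean", "one_minus_correlation"] = "euclidean",
) -> PipelineResult:
    """Distance-outlier two-stage workflow.

    Stage 1 applies the Th x median distance rule to the raw (un-normalized)
    log2 data and removes flagged arrays.  Survivors are quantile-normalized
    from raw, the rule is applied again on the normalized data (stage 2) and
    flagged arrays are removed.  Final normalization on the kept set.
    """
    if Yraw.n_samples < 4:
        raise ValueError("pipeline requires at least 4 arrays")
    all_samples = list(Yraw.sample_ids)

    dist0, flag0 = compute_lumi_outlier(Yraw, dissimilarity, th)
    qc0 = assemble_array_qc(
        all_samples, lumi_distance=dist0, lumi_flag=flag0,
        n_floored=Yraw.n_floored,
    )
    stage1_removed = {s for s, f in zip(all_samples, flag0) if f}
    survivors = [s for s in all_samples if s not in stage1_removed]
    _check_survivors(survivors, "stage 1 (distance outlier)")

    raw_surv = Yraw.subset_samples(survivors)
    norm1 = quantile_normalize(raw_surv)
    dist1, flag1 = compute_lumi_outlier(norm1.normalized, dissimilarity, th)
    qc1 = assemble_array_qc(
        survivors, lumi_distance=dist1, lumi_flag=flag1,
        n_floored=raw_surv.n_floored,
    )
    stage2_flagged = {s for s, f in zip(survivors, flag1) if f}

    kept = [s for s in survivors if s not in stage2_flagged]
    _check_survivors(kept, "stage 2 (distance outlier)")

    final = quantile_normalize(Yraw.subset_samples(kept))
    return PipelineResult(
        method="chow",
        all_samples=all_samples,
        stage1_removed=stage1_removed,
        stage2_flagged=stage2_flagged,
        kept=set(kept),
        final=final,
        per_stage_qc={"stage0": qc0, "stage1": qc1},
        stage2_removed=True,
    )


@dataclass
class Concordance:
    """2x2 cross-tabulation of flagged/unflagged samples between two runs."""

    both: set[str]
    only_a: set[str]
    only_b: set[str]
    neither: set[str]

    @property
    def counts(self) -> np.ndarray:
        """[[both, only_a], [only_b, neither]] counts."""
        return np.array(
            [[len(self.both), len(self.only_a)],
             [len(self.only_b), len(self.neither)]]
        )


def concordance(a: PipelineResult, b: PipelineResult) -> Concordance:
    """Cross-tabulate which samples each workflow flagged.

    A sample counts as flagged by a run when it was removed at stage 1 or
    flagged at stage 2.  Requires the two runs to share the same sample
    universe; the four id sets are disjoint and exhaust it.
    """
    if set(a.all_samples) != set(b.all_samples):
        raise ValueError("pipeline results cover different sample universes")
    universe = set(a.all_samples)
    fa, fb = a.flagged, b.flagged
    return Concordance(
        both=fa & fb,
        only_a=fa - fb,
        only_b=fb - fa,
        neither=universe - fa - fb,
    )
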