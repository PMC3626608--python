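# Methods

## Data contract

The package operates on background-corrected intensities on the log2
scale, modeled as `Y_ij = mu_ij + S_ij + eps_ij` — a true feature
abundance, a systematic per-array bias, and mean-zero feature-specific
noise. Background correction is upstream and out of scope: the reader
accepts a delimited matrix that has already been corrected (and optionally
log2-transforms it at ingestion). The latent terms are never estimated
individually; the normalization module estimates the bias `S` as a whole,
and the metrics are functions of `S` and of the normalized data
`Y' = Y - S`.

Missing and non-positive cells at ingestion (raw scale) are floor-imputed
to the matrix-wide minimum positive value and counted per sample
(`n_floored` in the QC report). Degraded samples carry "dead probes" with
no signal above background; dropping rows would desynchronize companion
matrices (expression vs standard error), and imputing to the floor keeps
the dead-probe signature visible to the distribution-shape metrics rather
than hiding it. On already-log2 input only missing cells are imputed,
since negative log2 values are legitimate.

## Normalization

**Quantile normalization** maps every column onto the per-rank mean of the
column order statistics. Ties within a column all receive the mean of the
target values over the tied ranks; this keeps the procedure deterministic
and invariant to sample order, which matters because dead-probe floors
create heavy ties. A consequence worth knowing: on tied input the sorted
values of a normalized column are no longer exactly the target (the tie
group is averaged), so the "identical sorted columns" property is exact
only on tie-free data. The quantile target uses the mean (not median) of
order statistics — the standard convention.

**Feature-target normalization** corrects each array toward the
across-array median profile: the per-array deviation from the target is
smoothed as a function of target intensity with a running median (window =
`round(span * p)` features, odd-ized; default span 0.3, minimum window 3 —
a span that yields a smaller window is an error) and the smooth component
subtracted. A running median was chosen over a local-regression fit
because it has one tunable, is monotone-safe, and is robust to the
dead-probe floor. This family of feature-specific schemes is the one for
which RLE is near zero by construction, and the package verifies exactly
that on noiseless monotone-distorted fixtures.

Renormalization after array removal always restarts from the raw matrix
of the survivors; normalized data are never re-normalized.

## Metrics

**Stress** `= 2 ^ median_i |S_ij - mean_i S_ij|`. The array-mean is
subtracted first: arrays differing from the cohort by a constant (scanner
brightness) are explicitly not considered defective, and the package
asserts this immunity property over many seeds. The result is on the
fold-change scale and is always >= 1. Default removal cutoff 1.5
(inclusive), i.e. half the features adjusted by 50% or more.

**dfArray** comes in two variants. `exact_loo` standardizes each cell by
the leave-one-out mean and sample standard deviation of its feature
(vectorized via sum/sum-of-squares identities; requires n >= 3 so the
excluded-sample sd exists). `robust` — the default in the pipelines —
replaces them with the across-array median and `1.4826 * MAD`, computed
once per feature. The MAD is scaled so the denominator estimates the sd
under normality, keeping the "two standard deviations" reading of the
default cutoff literal. The per-array summary is the 0.75 quantile of
`|dfArray_ij|` (sign is kept in the grid; magnitudes are equivalent errors
in the summary). Zero-spread guard: when the denominator is zero the cell
is 0 if the numerator is also zero, otherwise NaN and excluded from that
array's quantile summary — zero MAD is common under dead-probe floors.

The robust and exact variants agree closely when noise is symmetric; note
that their per-sample summaries can only be *rank*-compared meaningfully
when the samples actually differ in quality (on exchangeable replicate
arrays all summaries are near-equal and rank order is noise, even though
the values agree to a few percent).

**RLE** subtracts the across-array median per feature; summarized per
array by median and IQR. **NUSE** divides each standard error by the
across-array median SE of its feature (features with all-zero SE are
dropped and counted); the archive-based global variant is available by
passing an explicit per-feature reference denominator, since no public
archive exists for this platform. **Distance outlier**: features are
mean-centered and unit-scaled across arrays (zero-spread features
dropped; fewer than 2 usable features is an error), the target profile is
the per-feature median of the standardized data (the "robust estimate of
the feature mean"), and an array is flagged when its Euclidean or
1-minus-correlation distance exceeds `Th * median(distance)` with Th = 2.

**Quadrants**: per array, `IQR = Q3 - Q1` and `skew = (Q2 - Q1)/IQR`
(0.5 for symmetric distributions, near 0 when mass piles at the bottom).
R1 = IQR > 2 and skew > 0.2 (well-behaved); R2 large-IQR/low-skew;
R3 small-IQR/high-skew; R4 the rest. Zero-IQR arrays get a NaN skew
sentinel and are forced to R4 with a degenerate-count warning. All
quantiles package-wide use linear interpolation between order statistics
(the "type 7" rule), fixed for determinism.

All threshold comparisons are inclusive (`>=`).

## Pipelines

The Stress/dfArray workflow: quantile-normalize all arrays and compute
the full metric panel (the pre-removal dfArray is diagnostic only and
never drives removal); remove arrays with Stress >= 1.5; renormalize the
survivors from raw; flag arrays with dfArray75 >= 2 on the renormalized
data — stage 2 *flags* by default ("investigate") and removes only when
`remove_stage2` is set; finally quantile-normalize the kept set afresh.
The distance-outlier workflow applies the Th x median rule on the raw
log2 data (scale-sensitive there, deliberately so — that is how the
workflow is specified), removes, renormalizes, applies the rule again on
normalized data, removes again. Both abort with a diagnostic when fewer
than 3 arrays would survive a stage (the leave-one-out denominator needs
3). `concordance` cross-tabulates the flagged sets of two runs over a
common sample universe.

## Synthetic data

The generator emulates the *phenomenology* of archival-tissue cohorts —
heterogeneous distribution shapes, dead probes, bottom-heavy skew, arrays
that fail outright — not any platform's physical noise process. Feature
baselines are a two-component mixture (default: 70% expressed at
N(9, 1.5) log2 units, 30% background floor at N(5, 0.3)); per-feature
noise sds are lognormal around 0.25; each array gets a N(0, 0.1) constant
offset. These defaults put clean arrays in quadrant R1 (IQR ≈ 4,
skew ≈ 0.65). Five degradation operators each target one failure mode:
dead-probe collapse, range compression, skewed degradation (the lower 70%
of the distribution compressed toward the floor — compressing only the
lower half would leave Q2 fixed and *raise* the skew statistic),
profile discordance (a fraction of features swap baselines: marginal
distribution preserved, profile broken), and constant shift (severity 1 =
+2 log2 units; a non-defect used to test Stress immunity). The default
degraded-cohort scenario (`default_ffpe_config`) is a 96-array plate with
10 dead-collapse (severity 0.7) and 5 profile-discordant (severity 0.4)
arrays — about 15% poor quality, the fraction typical of large archival
cohorts.

What passing tests on this generator do **not** show: performance on real
bead-level data (no probe sequences, no replicate-bead structure, no
spatial or batch effects), calibration of the severity scale to real
degradation chemistry, or behavior when degradation is correlated with
biology. The monotone-distortion fixture (random strictly increasing
PCHIP warps of one latent profile, noiseless) isolates the
intensity-dependent distortion that feature-target normalization claims
to remove.

## Impact evaluation

`evaluate_impact` normalizes the reference set alone, then the
reference-plus-added set from raw, and compares per-feature means and
variances. Moments of the expanded set are computed over **all** its
columns by default (the straightforward reading of recomputing the
feature moments on the expanded sample); a flag restricts them to the
reference columns, isolating the distortion the added arrays impose on
the reference samples through joint normalization. Features are binned
into 20 equal-count bins by reference-mean rank with per-bin median
smoothing; features with zero reference variance are excluded and
counted; the 25th/50th/75th percentiles of reference intensity are always
reported as markers.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: recovery
experiments use 96 arrays x 5000 features over 10 seeds, the
normalization stress tests 10^4 x 100, the oracle comparisons 2000 x 20
and 10 x 6 (against a naive O(p·n²) brute force). Cell-exact
reconstruction (`Y' + S = Y`) is asserted at 1e-12 absolute; matrix TSVs
are written at 12 significant digits so read-write round-trips hold to
1e-9 relative; QC report TSVs use 6 significant digits for readability
(JSON keeps full precision). Random generation uses numpy's
`default_rng` with an explicit seed in every public call; there is no
hidden global state.

## Known limitations

No bead-level parsing (IDAT/CEL), no background correction, no
probe-to-gene annotation, no down-weighting scheme for downstream
differential expression (the metrics are exported so users can build
one). The distance-outlier threshold is relative to the current batch by
construction, which is precisely the weakness Stress/dfArray were designed
to avoid — the package implements it for comparison, not endorsement.
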