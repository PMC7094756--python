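# Methods

This note records the statistical model the package implements, the
assumptions behind it, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Statistical primitives

All group comparisons use Student's **pooled-variance** t-test (or the
paired t on differences), not Welch's: demographic tables in this
literature print pooled-form statistics, and the edge-wise tests follow
the same convention so a single code path serves both.  Degenerate
inputs are handled explicitly: zero pooled variance with equal means
gives t = 0; with unequal means it is an error for scalar tests and a
flagged ±∞ inside vectorised permutation loops (where an exception
would abort a valid permutation).

Correlations are Fisher-transformed (z = arctanh r) before every
edge-wise test.  Values with |r| ≥ 1 − 10⁻⁷ are clamped so numerically
saturated edges stay finite; the clamp only matters for degenerate
(duplicated-channel) inputs.

Permutation p-values use the add-one estimator p = (1 + b)/(1 + M)
with ties counted against the observed value.  This never returns 0,
is valid for any M ≥ 1, and resolves the ambiguity of "normalise by M"
when no permutation exceeds the observed statistic.  The same estimator
is used for exhaustively enumerated nulls so sampled and exhaustive
runs are directly comparable.

## Preprocessing

Signal-level cleaning is detrend → band-pass → nuisance regression, in
that order.  The band-pass is an **ideal rectangular DFT filter**
(coefficients with frequency in [0.01, 0.08] Hz kept, all others
zeroed): this is the convention of the widely used resting-state
toolboxes, it is exactly idempotent, and in-band/out-of-band behaviour
is bin-exact, which makes it testable against closed forms.  Nuisance
regressors (the Friston-24 motion expansion — 6 parameters, their
one-frame lags, and both sets squared, lag rows zero-filled at t = 0 —
plus optional tissue signals) are used as supplied and are *not*
themselves filtered; only the series is.  The alternative (filtering
the design matrix too) changes residuals only through the regressors'
out-of-band content and is not implemented.

Framewise displacement follows Jenkinson's formulation: for consecutive
rigid transforms, FD = sqrt((R²/5)·tr(AᵀA) + bᵀb) with [A|b] the
difference transform and R = 80 mm (the conventional head-sized
sphere; the factor R²/5 is the mean squared coordinate over a solid
ball).  Rotations are composed as full rotation matrices in the
T·Rx·Ry·Rz convention.  Note that FD is exactly invariant to a constant
translation offset only when rotations are constant; with varying
rotations the invariance is first-order, which is ample for
milliradian-scale head rotations.

DVARS is the RMS across regions of the frame-to-frame signal change
(first frame 0).  Scrubbing censors frames with DVARS above a
threshold; the threshold is config-exposed with default *median +
1.5·IQR* of the trace, since no universal value exists for
region-averaged signals.  Censored frames are removed outright (no
interpolation) and at least 10 must survive.  Both scrubbed and
unscrubbed paths are first-class, because analyses of this kind report
both.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: two
groups of 28 and 24 subjects, 94 ROIs, 240 volumes at TR = 2 s, with an
optional pre/post condition pair per subject.  Ground truth is a
*planted connected component*: a set of edges (which must form a
connected graph — the alternative hypothesis NBS is built for) whose
correlation is shifted by Δr in the affected group (unpaired mode) or
in the post condition of both groups (paired mode).

Target matrices are compound-symmetric (background correlation 0.1 by
default, a typical magnitude for weakly coupled parcels) with the
planted shift added and then repaired to positive definite by
eigenvalue clipping at 10⁻⁶ and diagonal rescaling; when the shifted
matrix is already PD — the usual case for Δr ≤ 0.3 — nothing else
changes, so off-planted edges are untouched.

Time series are Gaussian innovations with the target covariance, each
channel filtered by the same AR(1) recursion (default coefficient 0.3,
in the range estimated for 2-s-TR BOLD; a common coefficient preserves
the cross-correlation structure), plus a shared sinusoidal drift.  The
drift sits on the DFT bin nearest 0.005 Hz — below the 0.01 Hz cutoff,
so cleaning must remove it, and on an exact bin so the rectangular
filter can remove it completely.  Spectral-leakage realism, hemodynamic
response shapes, and physiological (cardiac/respiratory) noise are
explicitly *not* modelled: passing tests show the pipeline's statistics
behave correctly under the covariance structure the analysis assumes,
not that they are robust to every artifact of real scans.  Motion
parameters are random walks with translation step SD = magnitude (mm)
and rotation step SD = magnitude/80 rad, making mean FD linear in the
magnitude.

Per-subject seeds are spawned deterministically from the design seed,
so cohorts are exactly reproducible.

## Network-based statistic

The primary threshold defaults to the t value of two-sided p = 0.001 at
the design's df, and M = 5,000 permutations, both config-exposed —
standard NBS practice where the source analyses leave both open.
Directional hypotheses are run as separate positive/negative screens
(increases and decreases are scientifically distinct findings); a
two-sided screen is also available.  The unpaired null randomly
reassigns subjects to groups preserving sizes; the paired null flips
each subject's condition labels independently (equivalently, signs of
the paired z differences) — the only exchangeable scheme for a pre/post
design.  The maximal component size of an empty suprathreshold graph
counts as 0 in the null.  A warning is raised when the number of
distinct permutations is below 1/α.  For ≤ 20 pairs the paired null can
be enumerated exhaustively, which the test suite uses to check the
sampled machinery against a brute-force oracle exactly.

Component search is a breadth-first flood over the suprathreshold edge
list; extent (link count) is the only component measure.  The
permutation loop is vectorised: per-permutation group sums and sums of
squares are obtained by a single matrix product over the subject ×
edge matrix, and only the (typically sparse) suprathreshold edge list
reaches the component search.

### Calibration study sizes

The FWE calibration in the test suite runs 200 null cohorts scaled to
20 ROIs, 120 volumes and 12 + 12 subjects with M = 500 — sizes chosen
so the whole suite runs in minutes on one CPU.  At 190 edges a primary
threshold of p = 0.001 leaves the null maximal-component-size
distribution almost entirely at zero, making the component test
conservative (false-positive rate ≈ 0) rather than nominal; the
calibration therefore screens at p = 0.05 (the same threshold as the
edge-wise difference-network screen), where the null distribution is
non-degenerate and the empirical false-positive rate sits inside the
binomial band around α = 0.05.  Recovery is checked at full study
scale (94 ROIs, 240 volumes, 28 vs 24 subjects, Δr = 0.3 on a 6-edge
ring, M = 1,000) over 50 replicates.

## Classification

Feature selection (two-sample t, p < 0.05 by default) is nested
**inside** every leave-one-out fold, as is the feature-wise z-scoring;
selecting on all subjects first leaks the held-out label and inflates
null accuracy well above chance, which the test suite guards against
with a pure-noise regression test.  The biased variant remains
available behind an explicit `leaky=True` flag for demonstration.  When
no feature survives a fold's screen, that fold falls back to the single
smallest-p feature so the fold stays defined.

The SVM grid covers kernels linear / polynomial (degree 3) / RBF with
C ∈ {10⁻³, …, 10⁴} and gamma = 1/n_features (the libsvm defaults).
The grid maximiser is reported with deterministic tie-breaking (smaller
C, then linear < polynomial < rbf); AUC comes from the pooled
cross-validated decision values of the winning grid point.  The
label-permutation test repeats the full grid LOOCV per permutation and
uses the add-one p-value, so its floor at 100 permutations is 1/101.

`metric_roc` sweeps thresholds over the pooled values of a single
metric; orientation is chosen so AUC ≥ 0.5 with the direction recorded,
and AUC equals the Mann–Whitney statistic U/(n₀·n₁).  `lda_screen`
returns the Mahalanobis distance between class means under the pooled
within-class covariance, ridge-regularised relative to its mean
diagonal so the score is invariant to common affine rescaling of the
features.

## Pipeline

Runs are manifest-driven (subject_id, group, condition, file paths):
no metadata is parsed from filenames.  The acute contrast pairs the two
conditions of every subject (conditions are ordered alphabetically and
the ordering is echoed in the report); the chronic contrast compares
the two groups at the first-listed condition.  Every stage writes its
intermediates; the report echoes the config verbatim with a SHA-256
hash, p-values are printed to 4 decimals, and re-running with the same
seed reproduces the report exactly (no timestamps are recorded).

## Known limitations

- Volume-level operations (slice timing, realignment, spatial
  normalisation, smoothing) are out of scope; inputs must already be
  ROI-averaged signals.
- Only component *extent* is implemented as the NBS measure (no
  intensity/mass, no threshold-free variants).
- The generator's realism limits (above) mean simulation-based
  guarantees speak to the assumed covariance model, not to artifact
  robustness.
- Graph metrics beyond node degree (clustering, efficiency, …) are not
  computed.
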