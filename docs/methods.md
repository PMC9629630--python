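# Methods

`mocapskill` re-implements, as a reusable pipeline, a motion-capture-based
credentialing analysis for laparoscopic simulation training: instrument-tip
kinematic metrics are extracted from 30 Hz trajectories, screened with
nonparametric group tests, summarized with PCA, and fed to three classifiers
evaluated under nested repeated cross-validation. Because no recordings of
this kind are publicly deposited, the package also ships a synthetic
trajectory generator whose planted expertise effects make every downstream
stage testable end to end.

## Experience grouping

Participants are grouped by prior laparoscopic caseload: *experts* ≥ 50
surgeries, *intermediates* 10–49, *novices* 0–9. The two-group scheme
collapses intermediates and novices into *non-experts*. Both rules are pure
functions of the caseload and partition the non-negative integers.

## Preprocessing: Savitzky–Golay smoothing and derivatives

Tip coordinates (x, y, z in mm) are smoothed with a Savitzky–Golay filter
and the derivatives up to jerk are taken **from the filter itself** (the
derivative of the local least-squares polynomial), not from finite
differences of the smoothed signal. Defaults: window 9 samples (0.3 s at
30 Hz), polynomial order 3 — the shortest window at 30 Hz that stabilizes
jerk while reproducing polynomials up to the fit order exactly. Boundary
samples come from the polynomial fitted to the first/last window (no
reflection padding), so polynomial exactness holds at the edges too. Order
3 is the minimum admissible because jerk estimation needs a cubic term.
Attitude angles are unwrapped (±180° discontinuities removed) before any
averaging or differencing. These settings are conventions of this package;
results should always be reported alongside them.

## Metric suite

Per instrument (prefixes G/S/C for grasper, scissors, clip applier in the
dissection task; R/L for the needle holders in the suturing task):

- **OT** (s): trial duration (trial-level, reported once).
- **PL** (mm): Σ‖pᵢ₊₁ − pᵢ‖ over smoothed tip positions.
- **DPL** (mm): Σ|dᵢ₊₁ − dᵢ| along the depth axis (z by default — the
  viewing direction; configurable because the recording frame is a
  convention).
- **WA** (mm²): area of the 2-D convex hull of tip positions projected on
  the plane perpendicular to the depth axis ("working area" contrasts with
  the depth metrics DPL/DV).
- **v̄, ā, j̄** (mm/s, mm/s², mm/s³): trapezoidal time-means of the
  per-sample Euclidean norms of derivative orders 1–3.
- **DV** (mm/s): time-mean of |depth-axis velocity|.
- **AGRA, mean Roll/Pitch/Yaw** (deg): arithmetic means of the gripper
  angle and unwrapped attitude angles.
- **AL-Roll** (deg): Σ|Δroll| — accumulated rotation about the shaft axis.
- **AL-PitchYaw** (deg): Σ of great-circle angles between consecutive
  shaft-direction unit vectors u = (cos p sin y, sin p, cos p cos y).

Bimanual metrics (one pair per trial; scissors–grasper in the dissection
task, right–left needle holders in suturing):

- **BD**: Pearson correlation of the two hands' speed profiles on a common
  timebase (zero-lag by default; a max-cross-correlation variant within
  ±1 s is available via `bd_mode: xcorr`).
- **ROB**: right/left ratio of gripper open+close event counts.
- **RPLB**: right/left path-length ratio.
- **ADB** (mm): time-mean inter-tip distance; **ADBO**: that distance
  sampled at the open/close events of either hand.

Gripper open/close events come from hysteresis thresholding (threshold
15°, hysteresis 5° by default): an *open* fires on rising through
threshold+hysteresis after being below threshold−hysteresis, symmetric for
*close*; alternation is inherent in the two-state machine.

The published analysis names these metrics but its exact formulas are not
available in the open text; each definition above is a reconstruction from
the metric's name and the stated hypotheses, and is documented as such.
Undefined values (zero left-hand events → ROB, zero left path length →
RPLB, constant speed → BD) are flagged as missing, never infinite; trials
carrying a missing value are listwise-deleted from screening and
classification. One published metric name ("L_High") has no available
definition and is deliberately not implemented.

## Normalization, screening, PCA

Each metric column is robust-Z normalized:

    z_i = (x_i − x_m) / NIQR,    NIQR = 0.7414 · IQR

with the median x_m and type-7 (linearly interpolated) quartiles, fixed so
the transform is reproducible bit for bit. The 0.7414 factor makes NIQR a
consistent estimator of σ under normality while resisting outliers.
Columns with IQR = 0 map to zeros and are flagged degenerate.

Screening retains a metric iff its three-group Kruskal–Wallis p < α
(α = 0.05 by default, the community convention; the published analysis
reports "significant differences" without a stated level). Pairwise
Mann–Whitney tests are computed for retained metrics only, mirroring the
omnibus-then-pairwise protocol. No multiple-testing correction is applied
across metrics by default (matching the apparent per-metric testing); a
Holm option exists behind `holm: true`.

The rank tests are implemented in-package with explicit policies — exact
Mann–Whitney p by enumerating the null U distribution when n₁n₂ ≤ 400
without ties, exact Wilcoxon p by sign-pattern enumeration for ≤ 25
nonzero pairs (tied |differences| handled by conditioning on mean ranks),
normal approximations with tie and continuity corrections otherwise — and
are cross-checked against an independent implementation in the tests.

PCA is an eigendecomposition of the **covariance** of the robust-Z
features restricted to retained metrics (the data is normalized once, by
the robust Z-score, and not re-standardized to unit variance). Loadings
are eigenvector·√eigenvalue; because NIQR-scaled columns need not have
unit variance, loadings may exceed 1 in magnitude for heavy-tailed
metrics. Component signs are fixed so each component's largest-magnitude
loading is positive; zero-variance components sort last.

## Classification under nested repeated cross-validation

Three classifiers: RBF-kernel SVM, SVM on PCA-reduced features (PCA-SVM),
and a gradient-boosting decision tree (GBDT, LightGBM). Robust-Z
normalization — and, for PCA-SVM, the PCA rotation — is fit on training
rows only, inside every fold.

The evaluation is stratified nested repeated k-fold CV (10 outer × 10
inner folds, 100 repetitions by default): the inner folds grid-search
hyperparameters on the outer-training portion, the winner (ties break to
the first grid point, for determinism) is refit on the full outer-training
portion and scored on the held-out fold, and the repetition's accuracy is
the pooled proportion correct over all outer test folds (pooling is
invariant to unequal fold sizes, unlike fold-averaging). Repetition *r*
uses seed base+r for both fold layers, so the three classifiers run on
identical partitions and their accuracy vectors are paired. Stratification
is this package's choice: unstratified 10-fold on a 70-trial cohort with
an 18-member class risks near-empty classes in folds.

Hyperparameter grids (package defaults; the published grids are not in the
open text): SVM — C ∈ {0.1, 1, 10, 100} × γ ∈ {0.001, 0.01, 0.1, 1};
PCA-SVM — additionally retained variance ∈ {0.7, 0.8, 0.9, 0.95};
GBDT — learning rate ∈ {0.05, 0.1} × trees ∈ {50, 100, 200} × leaves
∈ {7, 15, 31}, with `min_child_samples=5` and `min_data_in_bin=1` because
cohort-sized training sets are two orders of magnitude below LightGBM's
default assumptions.

Model comparison follows the study protocol: Friedman's test over the
3 × repetitions paired accuracy matrix plus three pairwise Wilcoxon
signed-rank tests. **Caveat**: repeated-CV accuracies are not independent
blocks (they reuse the same trials), so these p-values mirror the
procedure rather than provide calibrated inference.

## Synthetic cohort generator

The generator emulates the *structure* of wet-lab instrument recordings:
per trial, two-handed 30 Hz tracks built from minimum-jerk reach segments
(p(t) = start + Δ·(10τ³ − 15τ⁴ + 6τ⁵), the standard motor-control
primitive, chosen because its speed profile is analytically checkable —
peak speed 1.875·D/T) toward goal points uniform in a 120×80×80 mm
workspace box, plus:

- **corrective submovements**: Poisson-distributed per goal (3 → 0.5 with
  skill), each a minimum-jerk hop of 5–15 % of the segment length;
- **tremor**: Gaussian noise low-passed at 8 Hz (physiological tremor lies
  below the 15 Hz Nyquist);
- **depth wobble**: a slow sinusoid (0.2 Hz) on the depth axis, 6 → 1 mm;
- **attitude**: pitch/yaw point the shaft from a fixed trocar to the tip;
  roll performs a bounded random walk with a skill-dependent fidget rate
  (40 → 10 deg/s);
- **gripper**: raised-cosine open–close pulses at goal arrivals plus
  spurious cycles (4 → 0.5 per minute);
- **bimanual coupling**: both hands share the goal schedule with a
  skill-dependent timing jitter (0.5 → 0.08 s).

Skill is a scalar in [0, 1]: an affine function of log10(1 + caseload)
(learning curves saturate), plus Gaussian per-participant aptitude noise
(σ = 0.12) because caseload is an imperfect proxy for actual performance —
without it, the groups are nearly perfectly separable, which no observed
cohort shows. Segment and corrective-hop durations carry a common tempo
multiplier (1.9 → 0.55): novices execute everything more slowly, pause
longer (1.8 → 0.5 s) and correct more often, so operative time, path
length and DPL fall with expertise while mean velocity, acceleration and
jerk rise — the direction pattern of trained-surgeon cohorts.

Calibration notes, fixed at design time: the tremor amplitudes
(0.015 → 0.008 mm RMS) are at the low end of what an optical tracker
records at a fulcrum-stabilized instrument tip. This is deliberate: jerk
is an ω³-weighted quantity, so even modest broadband noise swamps the
deliberate-movement jerk contrast between groups. With these defaults the
planted orderings hold decisively (Kruskal–Wallis p < 0.01 at 20
trials/group) and two-group classification reaches ≈ 0.85–0.90 — the
intended moderate-difficulty regime.

What the generator does **not** emulate: tissue interaction and its force
coupling, endoscope motion, instrument exchanges, realistic sensor noise
floors and dropouts, task-phase structure (dissect vs clip vs cut), or
learning within a session. Passing tests on synthetic cohorts therefore
demonstrates the *pipeline's* correctness and calibration, not that the
classifiers would reach any particular accuracy on human recordings.

A `zero_effect()` configuration collapses every skill map to its midpoint,
yielding a cohort with no planted group differences; it is the null for
screening type-I-error and classifier chance-level calibration.

## Numerical and degenerate-input policies

- Time grids are strictly uniform (spacing validated to 1 µs); track CSVs
  carry 12 significant digits so read∘write round-trips within 1e-9.
- Convex hulls of < 3 points or collinear points have area 0.
- Kruskal–Wallis with all-identical data returns H = 0, p = 1; Friedman
  with fully tied blocks returns statistic 0, p = 1; all-zero Wilcoxon
  differences return p = 1 with a degeneracy flag.
- Grid-search ties break to the first point in declared grid order;
  component signs in PCA are fixed by the largest-magnitude loading —
  both for bit-reproducibility.
- All simulator randomness flows from a single seed through spawned
  child generators; no global state.

## Problem sizes used by the acceptance checks

The chance-level calibration runs permuted-label nested repeated CV (SVM,
10×10 folds, 20 repetitions) on a balanced 70-trial zero-effect cohort;
planted-effect recovery runs all three classifiers at 5 repetitions on the
default 32/18/20 cohort. These repetition counts are the package's
desk-scale choices for a single-CPU run; the pipeline default remains 100
repetitions.
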