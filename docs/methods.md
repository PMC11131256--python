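# Methods

## The measurement model

The package quantifies the restlessness of a seated child from ordinary
consulting-room video that has been run through a 2-D pose estimator
(BODY_25 keypoint model: 25 joints, each `(x, y, confidence)` per frame,
nominally 30 Hz at 1280×720).  The analysis never touches pixels; its
input is the skeleton sequence.

Six bone vectors are read off each frame — right/left shoulder (neck→
shoulder), right/left hip (mid-hip→hip), right thigh (right hip→knee) and
trunk (neck→mid-hip).  The right thigh stands in for both legs because a
seated subject's left thigh is usually occluded by the right.  Each
non-trunk bone yields two per-frame scalars,

    l  = sqrt(dx² + dy²)                      (pixels)
    θ  = |atan(dy/dx)| · 180/π  ∈ [0, 90]     (degrees)

and the trunk contributes only the half-circle angle

    φ  = atan(dy/dx) · 180/π,   θ_trunk = φ if φ ≥ 0 else φ + 180,

giving 11 skeleton-parameter time series (5 lengths, 6 angles).  Only the
initial 4 minutes of recording are analysed (recordings are 4–6 min;
trimming to a common duration keeps variances comparable across
subjects).

Each series is summarised by its **averaged variance**: the series is cut
into K = ⌊T/R⌋ disjoint windows of R frames, the unbiased sample variance
(denominator R−1) is computed within each window, and the K values are
averaged.  The 11 descriptors plus the group label, stacked over
subjects, form the cohort dataset matrix (one row per subject, 12
columns; 96×12 at the default 48+48 design).

### Numerical choices

* **Window size R** defaults to 30 frames (1 s at 30 Hz).  It is the one
  tunable the windowing introduces: small enough to resolve
  within-second fidgeting, large enough to leave ~240 windows per
  4-minute recording for a stable average.  Configurable via
  `WindowConfig`.
* **Windows are disjoint** ("tumbling"): window k starts at frame
  (k−1)·R+1, and the trailing T mod R frames are discarded.
* **Vertical bones** (dx = 0) take the continuous limit θ = 90°; a
  zero-length bone vector has no direction and is marked invalid rather
  than given an angle of 0, so coincident-joint glitches cannot
  masquerade as movement.
* **Missing joints** (confidence 0) invalidate the affected parameters
  for that frame.  Within a window, invalid frames are dropped and the
  variance denominator shrinks accordingly; windows with fewer than two
  valid frames are excluded from the average (a strict
  `drop_window` policy is available).  A subject with any uncomputable
  descriptor is excluded with a per-descriptor reason rather than
  carried with missing cells.
* Window variances use a two-pass computation with an exact-zero
  short-circuit for constant windows, so a motionless subject scores
  exactly 0 on every descriptor.
* **Dropout repair**: per joint, interior runs of ≤ `max_gap` missing
  frames (default 15 ≈ 0.5 s) are linearly interpolated between flanking
  detections, with the smaller flank's confidence; longer runs and runs
  touching the sequence ends stay missing.
* **Person tracking**: when a frame contains several detected people the
  subject is the candidate nearest (mean Euclidean distance over jointly
  detected joints) to the previous frame's skeleton, falling back to the
  largest total confidence when there is no usable history.  Ties break
  to the lowest candidate index.  This is nearest-neighbour tracking,
  deliberately simple — adequate for a seated patient, and deterministic.

## Discriminability analyses

**Group comparison.**  Per descriptor: group means ± SD and a two-sided
two-sample t-test.  Welch's unequal-variance form is the default because
the group SDs differ by factors up to ~5; the pooled test is available by
flag.  No multiplicity adjustment is applied across the 11 marginal
tests.

**Cutoff analysis.**  For one descriptor with samples S = {(f_n, c_n)},
a bootstrap repetition draws N indices with replacement (in-bag set S̃),
finds the optimal cutpoint in-bag, and evaluates it on the out-of-bag
subjects.  The cutpoint candidates are the distinct observed in-bag
values; the decision rule is *ADHD iff f ≥ c* (the high side is fixed:
all 11 descriptors measure movement variance and the hyperactive group
fluctuates more — the test suite still checks both orientations via a
brute-force oracle); the selected candidate maximises the Youden index
J = sensitivity + specificity − 1, ties breaking to the smallest
candidate (favouring sensitivity).  Out-of-bag accuracy, sensitivity,
specificity and AUC are recorded; AUC is computed threshold-free with the
rank (Mann–Whitney) statistic, ties counting ½ — identical to the
trapezoidal ROC area for tie-free data and well defined with ties.
Repetitions with a one-class in-bag or out-of-bag set are redrawn (and
counted) so that exactly the configured number of repetitions — 100 by
default — contribute; more than 1000 consecutive degenerate redraws
aborts.  Ties *at* the cutpoint classify as ADHD, a documented choice.

**Classification analysis.**  17 feature combinations (11 singles;
thigh-, shoulder-, hip-, length-, angle-related; all) × 6 classifier
families × 3 resampling strategies.  The families and their immutable
tuning grids:

| family | grid |
|---|---|
| AdaBoost (CART stumps) | n_estimators ∈ {1, 5, 10, 20, 30, 50} |
| decision tree (CART) | max_depth ∈ {1, 2, 3, 5, 7} |
| k-nearest neighbours | n_neighbors ∈ {1, 2, 3} |
| random forest | max_features {1,2,3} × max_depth {1,2,3,5,7} × n_estimators {1,5,10,20,30,50} |
| SVM (RBF) | gamma {50,100,300,500} × C {0.001,0.01,0.1,1} |
| XGBoost | learning_rate {0.1,0.2,0.3} × max_depth {1,2,3,5,7} × n_estimators {1,5,10,20,30,50} |

On every training set hyperparameters are tuned by exhaustive grid search
with stratified 5-fold CV; the objective is mean accuracy, ties breaking
to the earliest grid point in the documented order (full cartesian
product, last-listed parameter varying fastest).  The tuned model is
refitted on the whole training set.  Resampling strategies — 10-fold
stratified CV repeated 10×, and stratified 8:2 / 6:4 holdouts repeated
100× — each produce exactly 100 train/test pairs (holdouts are stratified
to match the stated CV fold composition of 4–5 subjects per class).  The
four indices are averaged over the 100 test sets; AUC uses the positive-
class probability where a family provides one and the SVM margin
otherwise.  Finally each combination is ranked (descending, average
ties) per classifier and index, and ranks are averaged over the six
families; rank mass is conserved (each column of the ranking table sums
to 1+…+17 = 153).

Implementation notes:

* **Standardisation.**  Every fit standardises features with the
  training-fold mean/SD.  The RBF grid (gamma 50–500) and kNN operate on
  distances and are unusable on raw descriptor scales spanning three
  orders of magnitude; tree ensembles are unaffected by the transform.
* **Prefix tuning of ensembles.**  Boosting is sequential and forests
  draw tree seeds sequentially, so one maximum-size fit per
  (other-params, fold) evaluates every `n_estimators` grid value
  exactly; the equivalence with naive per-point refits is pinned by a
  unit test.
* **max_features clamping.**  Grid values exceeding a combination's
  width clamp to the number of features (narrow subsets would otherwise
  be unevaluable); grid order and tie-breaking are unchanged.
* **Seeding.**  All randomness flows from one master seed through
  `SeedSequence([master, *stream_key])`; split streams are keyed by
  strategy, tuning streams by (strategy, combination, classifier,
  split), so any single cell reproduces bit-identically in isolation.

## The synthetic cohort generator

No clinical recordings accompany the method (none were deposited), so
the generator defines the study conditions at two fidelity tiers.

**Skeleton level** (`generate_cohort`) exercises the io → kinematics →
features path end-to-end.  A stylised seated posture anchors the 25
joints; the six bones are animated in *bone space*: white Gaussian noise
on each bone's direction (degrees) and length (pixels), plus
Poisson-arriving raised-cosine "fidget events" that rotate the lower
body about the mid-hip with partial trunk/shoulder follow-through —
emulating body spin on a swivel chair, the dominant movement of
hyperactive children in a consulting room.  Because the noise acts
directly on the measured parameters, a noise SD of √v produces an
expected averaged-variance descriptor ≈ v; the per-group default SDs are
derived exactly this way from the published clinical reference
statistics (see `REFERENCE_DESCRIPTOR_STATS`), with ADHD fidget events
(4/min, 18° amplitude) dominating the control ones (0.3/min, 5°).  On
top sit detector-like nuisances: per-joint pixel jitter, missing-joint
dropout, and (on pose-JSON export) an occasional second person.
Measured cohort descriptor means land within ~10–20 % of the reference
values; the residual gap comes from angle folding at the 0°/90°/180°
boundaries and from event bursts, and is deliberate — the tier aims for
realistic *shape*, not exact moments.

What this tier does **not** emulate: correlated smooth limb
trajectories, camera motion, perspective, occlusion-correlated dropout,
or any attention/inattention phenotype.  Passing tests on it demonstrate
pipeline correctness and qualitative group contrasts, not clinical
validity.

**Feature level** (`generate_feature_table`) gives exact distributional
control for the cutoff/classification analyses: each descriptor is drawn
from a truncated-at-zero Gaussian at its group's reference mean/SD
(truncation by redrawing offending cells; at the reference parameters
the truncated mass is negligible).  Descriptors are independent by
default — the true between-descriptor correlation is unrecoverable from
published marginals — with an optional equicorrelated common-factor knob.
The analytic companion `expected_auc_gaussian` (Φ(Δμ/√(σ₁²+σ₀²)))
predicts cutoff AUCs on such tables; at the reference thigh-angle
parameters it gives ≈ 0.99998, which is why near-perfect recovered AUCs
on synthetic tables are expected rather than suspicious.

## Problem sizes used by the shipped checks

The full published design (17 combinations × 6 families × 3 strategies ×
100 resampling pairs, each pair grid-tuned by 5-fold CV) costs CPU-days
with the printed grids; the library defaults keep the full replication,
and the shipped test suite and `scripts/acceptance.py` run the identical
code paths at reduced replication, a deliberate reporting choice:
10 CV folds / 5 holdout repeats for the per-family checks, 2 holdout
repeats for the 17×6 ranking table, and 100 bootstrap repetitions
(the full default) for all cutoff analyses.  `ResamplingStrategy.with_pairs`
makes the reduction explicit and seeds are unchanged by it.

## Known limitations

* The cutpoint search scans observed values only; cutpoints between
  observed values (midpoints) are not considered.
* AUC for the SVM uses the margin, not calibrated probabilities; for
  hard-label situations the 0/1 fallback makes AUC coincide with
  balanced accuracy.
* The generator's independence and white-noise assumptions understate
  the temporal autocorrelation of real movement; descriptors on real
  data will be more variable across windows than the synthetic tiers
  suggest.
* Units follow the descriptor definition: pixels² for length variances,
  degrees² for angle variances.
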