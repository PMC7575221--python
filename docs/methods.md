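# Methods

`situp` re-implements, as a tested pipeline, the analysis of a passive
sit-up orthostatic test in people with spinal cord injury: continuous ECG
and finger arterial pressure are reduced to a per-beat series, calibrated to
brachial cuff pressure, summarised as a 5-min supine mean and seated 1-min
means, classified for (delayed) orthostatic hypotension, and phenotyped by
hierarchical clustering of the per-subject orthostatic response vector
(ΔSBP, ΔDBP, ΔHR).  Because the study's raw recordings are not public, a
synthetic-data module generates cohorts and waveforms with embedded ground
truth; everything below is therefore validated by recovery of known truth
and by brute-force oracles, not against the original recordings.

## Synthetic cohort generation

The public per-cluster summaries give, for eight clusters of 159 subjects
(sizes 24, 2, 20, 33, 23, 3, 28, 26), the median and range of ΔSBP, ΔDBP
(mmHg) and ΔHR (BPM).  `generate_cohort` draws each cluster's target deltas
from a normal centred on the printed median, truncated to the printed
range.  For clusters with n ≤ 3 the printed min/median/max *are* the sample
(order statistics determine it), so those values are used verbatim —
cluster 2's two members get exactly ΔSBP {−58, −51}, cluster 6's three get
{22, 23, 25}.

The dispersion is SD = range/`spread` with default `spread = 8`.  The
printed ranges of the central clusters (4, 5, 7, 8) overlap substantially,
so a sampler spread across the full printed range produces cohorts whose
generating labels are not recoverable by *any* method — the embedded
structure would be destroyed by construction, defeating the generator's
purpose of end-to-end validation.  `spread = 8` keeps ≈95% of each
truncated normal's mass inside the central half of the printed range while
leaving the endpoints attainable; with it, Ward + silhouette selection
recovers k = 8 on essentially every seed and the generating labels at
adjusted Rand index ≥ 0.9 on ≈90% of seeds.  `spread = 4` (mass spread over
the whole range) remains selectable for sensitivity analysis.  Sample
medians track the printed medians to within range/6 for the larger
clusters; truncation asymmetry contributes a small, documented shift.

Supine baselines are population-typical draws (SBP ~ N(120, 10) clipped to
100–145 mmHg, pulse pressure ~ N(45, 6), HR ~ N(68, 8)); injury level
(cervical/high-thoracic/low-cord) and AIS grade are drawn at the cohort
composition (85/21/53 and 60/35/41/23).  Protocol mix follows the study
sites: 240-s seated at 500 Hz vs 900-s seated at 1000 Hz, with the long
protocol at probability 76/159.  All draws come from one seeded generator;
identical seeds give byte-identical cohorts.

## Waveform synthesis

Each recording is 300 s supine, a 10-s passive transition, and the seated
period.  SBP, DBP and HR follow piecewise-constant per-window trajectories
joined by 5-s cosine ramps.  The seated "nadir" window (default window 2)
carries exactly supine + target for all three variables; every other seated
window sits `3 + 1.5·|w − nadir|` mmHg above the nadir SBP (half that for
DBP, and 70% of the HR response), which makes the nadir the unique
lowest-SBP window whatever the sign of the targets.  Ramps are placed so
the nadir window is never polluted: the ramp into it lies in the preceding
window, the ramp out of it in the following window.  A subject with targets
exactly (0, 0, 0) is rendered flat at supine levels throughout.  Programmed
window means are computed by numerically integrating the actual trajectory
and embedded in the record's metadata, alongside the true beat times and
per-beat pressures.

The ECG is a simplified complex — dominant R spike (Gaussian, σ = 8 ms)
with smaller P/Q/S/T deflections — because only R timing matters
downstream.  The pressure wave rises from the diastolic trough (at the
pulse foot, 150 ms after R) to the systolic peak with a half-cosine
upstroke, then decays to the next foot with an optional dicrotic bump.
Noise defaults: ECG SD = 5% of R amplitude, BP sample SD = 1 mmHg, per-beat
SBP/DBP variability SD = 0.5 mmHg, RR jitter CV = 1%.

What the generator does *not* emulate: arrhythmia/ectopy, respiratory
modulation, probe movement artifact, nonlinear or drifting finger-pressure
error (the miscalibration model is affine, matching what a two-point
calibration can undo), or symptom-triggered early test termination.
Passing recovery tests therefore demonstrate internal consistency of the
pipeline, not robustness to every property of real recordings.

## Beat detection

R peaks: band-pass (5–25 Hz, zero-phase Butterworth), derivative, square,
120-ms moving-window integration; candidate peaks ≥ 250 ms apart are
accepted against an adaptively updated signal/noise threshold
(running-estimate scheme) and refined to the local raw-ECG maximum.  All
thresholds are relative to the signal's own scale, so detection is
invariant to uniform amplitude scaling.  Flat or empty input yields an
empty beat list with a warning, not an exception.

BP extrema: for each R peak, the systolic peak is located on a 40-ms
moving-average of the pressure wave within (R, R + 0.6·RR]; the diastolic
trough is the minimum between the preceding systolic peak and the current
peak.  Values are read from a ±40-ms least-squares parabola on the *raw*
samples around the located extremum — this suppresses the upward bias that
picking the max of noisy samples would cause, without the peak flattening
of a heavy low-pass filter.  Beats with pulse pressure < 10 mmHg are
flagged unresolvable.

Artifact screening flags (never deletes) beats outside HR 20–220 BPM,
SBP 40–260 mmHg, DBP 20–160 mmHg, |beat-to-beat ΔSBP| > 25 mmHg, or RR
deviating > 40% from the centred 11-beat rolling median.  Window means use
valid beats only.  These limits are conventional defaults, configurable via
`PhysiologicLimits`.

## Calibration, windows, classification

Two-point calibration maps the supine-window mean finger SBP and DBP onto
the mean cuff SBP and DBP; two points determine the affine map exactly, and
gain > 0 preserves the DBP < SBP ordering.  The supine summary is the mean
over the 300 s before sit-onset; seated windows are half-open 60-s
intervals from the end of the transition, a partial final window is kept if
≥ 30 s.  Window HR is the arithmetic mean of instantaneous 60/RR over
valid beats (matching the notion of 1-min means of a continuous HR signal),
and windows with < 10 valid beats are marked missing.

Orthostatic hypotension: a fall of ≥ 20 mmHg SBP and/or ≥ 10 mmHg DBP
(thresholds inclusive, reading "at least" literally) between the supine
mean and the lowest seated 1-min mean within the first 3 min.  Delayed OH:
OH absent but the same criteria met over the windows after minute 3 —
assessable only on the long protocol.  The two flags are mutually
exclusive by construction.

The cluster feature vector uses the "coherent-window" convention by
default: the seated window with the lowest 1-min SBP mean over the whole
seated period supplies all three deltas.  This choice explains negative
ΔHR values in the printed per-cluster HR ranges, which a max-HR convention
would make rare; because the source description is ambiguous, a
"per-variable-extremum" convention (min-SBP, min-DBP, max-HR windows
separately) is selectable.  Whether the feature window search should be
restricted to the first 3–4 min on the short protocol is likewise
ambiguous; the default searches the full seated period.

## Clustering

Ward's-method linkage is computed in-package by the Lance–Williams
recurrence on squared Euclidean distances; each step merges the pair
minimising the increase in total within-cluster sum of squares (ΔESS),
ties broken by the smallest (left, right) cluster-id pair for cross-platform
determinism.  Recorded heights are √(2·ΔESS) — the convention under which
two singletons merge at their plain Euclidean distance, making toy examples
hand-checkable (and matching the common reference implementations).
Distances are Euclidean on raw units, without standardization: the three
features span comparable numeric ranges and the reference analysis
clusters raw changes; z-scoring is available behind a flag.  The linkage is
verified in the test suite against an exhaustive agglomeration oracle that
recomputes every candidate merge's ΔESS from raw points (n ≤ 10, 100
random instances) and against an independent hierarchical-clustering
implementation.

k is selected by mean silhouette over k = 2..15: among interior local
maxima of the profile the one with the largest silhouette wins (smallest k
on ties); with no interior local maximum the global maximum is used with a
logged note.  Per-item silhouette is (b − a)/max(a, b) with the singleton
convention s = 0.  The search range is a package choice — the reference
analysis reports its selected k as a local maximum without stating the
range searched, so the global-max rule is deliberately not forced.

## Group comparisons

Continuous variables: two-sample Wilcoxon rank-sum ("rank-sum" read as the
two-sample test, since the compared groups are independent subjects) or
Kruskal–Wallis, two-sided, with mid-rank ties; small untied rank-sum
samples get exact permutation p-values.  Categorical: Pearson chi-square
(no continuity correction) or, for sparse 2×2 tables, Fisher's exact test
summing hypergeometric outcomes no more probable than the observed table.
These standard tests are delegated to scipy.stats behind the module
surface; the test suite checks them against brute-force enumeration.
α = 0.05, two-tailed, no multiplicity correction by default.

## Numerical and degenerate-input conventions

All timestamps are seconds from recording start; windows are half-open
[start, end) so boundary beats are counted once.  RR intervals attach to
the later beat; the first beat has no RR/HR and is flagged.  Calibration
raises on degenerate input (finger SBP mean = DBP mean, no cuff readings,
or < 10 valid beats).  A supine span shorter than 300 s is summarised over
the available span with a warning.  Identical-valued groups return p = 1
with a warning rather than failing.  Cluster labels are 1..k in order of
first leaf appearance, making assignments deterministic and
permutation-equivariant.

## Problem sizes used in validation

The acceptance script and test suite run: the 159-subject cohort at
feature level over 10 seeds for cluster recovery; 20 subjects (at most 4 on
the long protocol) at waveform level for signal recovery; 100 random
instances (n ≤ 10) for the Ward oracle; 20–30 instances for the
silhouette/Fisher/rank-sum oracles.  These sizes make the full suite run in
well under a minute of compute per stage while keeping every check
statistically meaningful.

## Known limitations

- The within-cluster distribution beyond median/range is unknowable from
  the printed summaries; the truncated normal (and its tight default
  spread) is a modelling stand-in, and cohort-level prevalence numbers from
  synthetic cohorts are illustrative, not estimates of the study's.
- Beat-to-beat variability analyses, respiration, and arrhythmia handling
  are out of scope.
- The R-peak detector is designed for the synthetic morphology and clean
  clinical recordings; it is not tuned for pathological ECGs.
- The OH classifier needs a usable supine mean and at least one usable
  seated window in the first 3 min; otherwise it reports "unassessable"
  rather than guessing.
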