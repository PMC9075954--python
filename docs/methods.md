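# Methods

`wmdecode` simulates and analyzes a delayed spatial working-memory fMRI
experiment in which the required motor response is either knowable in
advance of the memory delay ("informative" trials) or not
("uninformative" trials). The scientific question the analysis graph is
built around is whether remembered information is carried by a
sensory-like spatial code (angular position decodable from visual-like
voxels) or re-coded into an action-oriented code (upcoming finger press
decodable from sensorimotor-like voxels), and how that balance shifts
with the response's pre-plannability. Every stage operates on synthetic
data with a known generative ground truth, so each analysis can be
validated against what was actually injected.

## Task designs

Four event-related designs are generated with full counterbalancing:

* **Main task** — 10 runs x 20 trials per session, two sessions. Within a
  session each condition uses 100 unique target angles on a 3.6 deg
  lattice and 100 unique response-disk rotations on the same lattice
  shifted by 1.8 deg (so a target never falls exactly on the disk
  boundary). The 10x10 matrix of (36 deg target bin) x (36 deg rotation
  bin) combinations is filled exactly once per condition, implemented as
  independent per-bin permutations assigned across the opposing factor's
  bins. Informative previews equal the response rotation; uninformative
  previews shuffle the same 100 rotations. Trials where target and
  boundary share a 36 deg bin are flagged `hard_trial` (the
  bonus-eligible fine discriminations). The correct finger follows the
  target's side of the boundary (side A iff `sin(target - rotation) > 0`)
  through a luminance-to-finger map that flips between sessions.
  Within-trial timeline (s from target onset): pre-cue -0.75, target
  0-0.5, color cue 1.5-3.5, preview disk 3.5-4.5, response disk
  16.5-18.5. Inter-trial intervals are drawn uniformly on a 0.1 s grid in
  [1, 5] s and a final fixation pads each run to exactly 466 s.
* **Mapping task** — 200 target angles exactly 1.8 deg apart over 10 runs
  of 20 trials; the 20 bins of 10 positions are each sampled once per
  run. Probe start angles use the identical scheme drawn independently.
  Runs are padded to 406 s.
* **Spatial localizer** — 24 wedge centers at 7.5 + k*15 deg (never on a
  cardinal meridian), four presentations each per 96-trial run of 3 s
  trials without ITI; consecutive wedges never share a quadrant. Runs
  last 313 s.
* **Button localizer** — 60 one-second press trials per 319 s run, 30 per
  index finger, ITI uniform on [2, 6] s, cue-color mapping inverted on
  alternating runs. The generator reserves at least 8 s of final
  fixation so post-onset epoch windows always fit inside the run.

Angle convention everywhere: degrees in [0, 360), 0 deg at the positive
x-axis, counter-clockwise. All generators require an explicit seed and
are bit-reproducible.

## Generative voxel model

Each voxel carries:

* a preferred angle (uniform on the circle) and von Mises concentration
  `kappa`, giving a spatial tuning profile
  `exp(kappa * (cos(angle - pref) - 1))`;
* condition gains `g_informative`, `g_uninformative` multiplying that
  tuning during the delay window (3.5-16.5 s after target onset), plus a
  shared encoding gain before the preview disk appears — conditions are
  indistinguishable until the preview reveals (or withholds) the
  response mapping;
* a signed action weight expressing preference for presses contralateral
  to the voxel's hemisphere, active during the delay only on informative
  trials (the plan is only knowable then) and during the response window
  on all trials (the press itself);
* an orientation gain driving a 180 deg-periodic response to the preview
  disk's boundary, identical across conditions (the disk is a physical
  stimulus either way).

Neural boxcars at these windows are convolved with a peak-normalized
double-gamma HRF (peak delay 6 s, undershoot delay 16 s, ratio 6;
sampled at TR = 0.8 s) and summed with voxelwise stationary AR(1)
Gaussian noise (marginal sd `noise_sd`, lag-one correlation `ar1_phi`).
Voxels are spatially independent; no physiological noise, motion, or
volumetric geometry is modeled, so passing tests demonstrate the
correctness and calibration of the analysis chain, not robustness to
real-data artifacts.

Default ROI profiles (chosen once so the decoders land in the
qualitative regime each profile emulates, with per-participant condition
effects that are reliable at the single-participant level):

| profile | kappa | g_uninf | g_inf | action weight | orientation gain |
|---|---|---|---|---|---|
| visual_like | 4.0 | 0.07 | 0.03 | 0 | 0.25 |
| parietal_like | 4.0 | 0.03 | 0.012 | 0 | 0.10 |
| sensorimotor_like | 0 | 0 | 0 | 0.04 (60% of voxels) | 0 |
| null | 0 | 0 | 0 | 0 | 0 |

with `baseline_amp = 1`, `noise_sd = 1`, `ar1_phi = 0.3` throughout.
At these values visual-like spatial decoding averages roughly 0.90
(uninformative) vs 0.77 (informative), sensorimotor action decoding
roughly 0.97 (informative) vs chance (uninformative), at 50 voxels per
ROI and six participants.

## Preprocessing

Per run: optional high-pass filtering (projection onto a DCT-II cosine
basis with frequencies below 1/40 Hz; an approximation to scanner
detrending, not a bit-exact replica of any specific tool), voxelwise
z-scoring (sample sd; zero-variance voxels are an error, never silent
NaNs). Trials are epoched by pure indexing at TR `round(onset / 0.8)`
(round-half-away-from-zero; the simulator's run padding guarantees no
truncation, and truncation is otherwise an error unless explicitly
zero-padded). Time-averaged patterns use inclusive TR windows — main
task 10-16 (8-12.8 s, mid/late delay), mapping 6-12 (4.8-9.6 s),
localizers 4-7 (3.2-5.6 s) — and are mean-centered across voxels per
trial so global activation differences cannot drive decoding.

## FIR deconvolution

Condition-wise HRFs are estimated by ordinary least squares on a
finite-impulse-response design: one 0/1 onset indicator per condition
plus 34 shifted copies (35 lags = 0-27.2 s, covering the 18.5 s trial
plus hemodynamic tail; configurable) and one constant per run. Events
shifted past a run's end truncate; simultaneous same-condition events
cannot occur in these designs but would collapse to an indicator.
Rank-deficient designs raise with the offending columns named. With
noiseless data and a FIR window covering the kernel, recovery is exact
(machine precision) for arbitrary, including overlapping, schedules. A
contralateral/ipsilateral split relabels trials per hemisphere by the
laterality of the correct finger for four-condition fits.

## Decoding

The classifier is a binary nearest-class-mean rule in per-voxel
variance-normalized space: class means and the equal-weight average of
the two classes' unbiased per-voxel variances are estimated from
training data, and a test pattern joins the class minimizing
`sum_v (x_v - mu_cv)^2 / var_v`. Training classes must be balanced;
zero pooled variances are floored at 1e-12 with a warning; distance ties
resolve to the lower class label.

Continuous angles are discretized into eight 45 deg bins (first bin
centered at 0 deg) and four binary classifiers discriminate bins 180 deg
apart; the headline accuracy is their unweighted mean, with chance at
50%. Localizer training data use eight slightly overlapping 60 deg bins
on the same centers (a wedge can train two neighboring bins, never two
opposite ones). Regimes:

* **train_mapping / train_sensory_localizer** — train on the independent
  task's window-averaged patterns, test on main-task trials.
* **within_condition** — leave-two-out cross-validation (one trial per
  class, random seeded matching; every trial tested exactly once;
  training rebalanced by seeded subsampling when bin counts differ).
* **cross_session_action** — finger decoding trained on one session and
  tested on the other, both directions averaged. Labels are the
  *correct* finger; since the luminance-to-finger map flips between
  sessions, a luminance-driven signal reverses under transfer and can
  never masquerade as action information.
* **disk_orientation** — preview boundary orientation mod 180 deg, four
  45 deg bins at 0/45/90/135, two classifiers (0 vs 90, 45 vs 135),
  cross-session, all averaged.
* **timecourse** — per-TR variants (spatial: train once on the mapping
  window, test each TR; action: train and test at the same TR across
  sessions), each TR's pattern re-centered.

## Group inference

The group statistic is a signed Wilcoxon-type rank sum of paired
differences (zeros dropped, average ranks on ties, `sum(sign * rank)`),
chosen because the inference procedures need a signed quantity with a
symmetric null; the classical one-sided rank sum W+ is not signed.
P-values follow exact counting without +1 smoothing, so p = 0 occurs at
finite iteration counts, and are bit-reproducible under seeds.

* **Above-chance**: each of (default) 1000 iterations re-runs the full
  decoding with training labels shuffled within classifier (class counts
  preserved), computes the signed-rank statistic of (real − shuffled)
  across participants, and p is the fraction of iterations with
  statistic ≤ 0 (one-tailed).
* **Condition difference**: each participant's condition pair is swapped
  with probability 0.5; p doubles the smaller tail count (two-tailed,
  capped at 1). Identical conditions yield a "no difference" sentinel
  rather than an undefined statistic.
* **Two-way repeated-measures ANOVA** (ROI x condition): classical
  within-subject sums of squares with subject-by-factor error terms,
  computed by a vectorized routine (cross-checked against an independent
  library implementation in the tests); the permutation null shuffles
  each participant's scores across all cells.
* **Timepoint tests**: the condition-difference test applied
  independently per TR, uncorrected (a Benjamini-Hochberg helper exists
  but is never applied implicitly).
* **Behavioral**: classical paired t-tests on accuracy and response
  time.

Because the expensive above-chance test retrains decoders every
iteration while sign-flip tests only re-rank six numbers, the pipeline
accepts separate iteration counts for the two families
(`n_iter` / `n_iter_signflip`).

## Pipeline, seeds, and the qualitative check

`run_experiment` derives every seed from a single master seed via
`SeedSequence([master, crc32(stage), indices...])`, so any stage is
re-runnable in isolation and identical configurations give hash-equal
tables. The qualitative pattern check asks, per simulated experiment:
(a) visual-profile ROIs decode position better in the uninformative
condition (sign-flip p ≤ 0.05, means ordered); (b) sensorimotor-profile
ROIs decode the upcoming action above chance in the informative
condition only; (c) spatial decoding in sensorimotor-profile ROIs is at
chance. "At chance" is operationalized as a one-sample t-test against
0.5 failing to reject at α = 0.01 — a deliberate asymmetry: accepting a
permutation null at α = 0.05 would make roughly one replicate in twenty
fail each negative subcheck by construction, which would measure the
test's level rather than the simulation's fidelity.

## Calibration studies and problem sizes

Three studies back the package's empirical claims (all in
`wmdecode.validation`, re-run by the test suite and
`scripts/acceptance.py`):

* **Chance calibration** — 200 replicates of the full spatial pipeline
  under a null ground truth (24 voxels, one mapping + one main session
  per replicate); mean accuracy is within two Monte-Carlo standard
  errors of 50%.
* **Type-I calibration** — 200 null experiments of six participants,
  each a four-pair signal-free decoding problem (mirroring the real
  pipeline's accuracy granularity; a single coarse classifier would
  produce tied scores and a spuriously conservative test), permutation
  tests at 200 iterations; rejection rates at α = 0.05 fall in the
  binomial band [0.02, 0.09]. The condition-difference test is
  inherently conservative at n = 6 (smallest attainable two-sided p is
  2/64 ≈ 0.031).
* **Effect recovery** — 50 replicate six-participant experiments with
  one visual-like and one sensorimotor-like ROI of 50 voxels at the
  default gains; the qualitative check passes in ≥ 90% of replicates.

These sizes (voxel counts, replicate counts, 200 permutation iterations
for retraining nulls vs 1000 for sign-flip nulls) are the package's
default desk-scale study conditions; all are parameters.

## Known limitations

Voxel noise is spatially independent AR(1) — no physiological
regressors, spatial autocorrelation, motion, or susceptibility effects;
behavioral summaries are drawn from a descriptive two-condition normal
model rather than simulated trial-by-trial; the high-pass filter is a
DCT projection, not a replica of any scanner pipeline; no volumetric or
surface geometry (an ROI is just a voxel set); decoders are strictly
binary pair schemes, no multiclass or continuous reconstruction.
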