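# Methods

This note documents the models, rules, and design choices behind
`gazesearch`: what each stage assumes, which parameters matter, what the
synthetic data do and do not emulate, and where the design was genuinely
open.

## 1. Event classification

**Fixation detection** (`events.detect_fixations`) is a threshold parser: a
gaze sample is saccadic when its speed reaches 30 deg/s or its speed
derivative reaches 8,000 deg/s² (the customary defaults for video-based
trackers; both are arguments).  Speed and acceleration use a two-sided,
3-sample attribution — the minimum of the backward and forward difference
at each sample — so a displacement interval is charged only to samples
strictly inside the movement.  On clean streams this keeps detected onsets
and durations within one sample period of the generating events (verified
by round-trip tests against rendered streams).  This parser is a simplified
stand-in for vendor software: it has no blink handling, drift correction,
or pupil-size logic, and it is bypassed entirely whenever fixation-level
input is supplied.

**AOI geometry.** Candidate stimulus locations form a 7 × 3 grid at a
200-px pitch centered on a 1920 × 1080 screen; the central cell holds the
fixation marker and never a stimulus.  Each AOI is a closed 101 × 130 px
rectangle centered on the (jittered) stimulus center.  Coordinates are
screen pixels, origin top-left, y downward.  Since centers are at least
180 px apart and rectangles are 101 px wide, rectangles cannot overlap and
containment is unambiguous; for fixations outside every rectangle the
nearest AOI center is used, ties broken by the lowest row-major grid index
(any deterministic rule would do; this one is reproducible).

**Visit runs.** After fixations on unoccupied AOIs are dropped (the
central marker cell counts as unoccupied), maximal blocks of consecutive
same-stimulus fixations become runs.  A run is a *revisit* iff its stimulus
owns an earlier run; maximality guarantees the interruption requirement
(at least one intervening fixation on a different stimulus).  Because
empty-AOI fixations are eliminated before scoring, "off-stimulus fixation"
is interpreted as "fixation on a different occupied stimulus"; the
alternative order (score revisits first, then drop empty-AOI fixations)
would count interruptions by empty-cell fixations too — with the standard
display geometry the two readings differ only in rare corner cases.
Fixations ongoing at the response keypress are truncated at RT: gaze after
the decision is not search.

## 2. Trial statistics and filtering

Per trial of set size *m*: skipping = (never-fixated stimuli)/*m*;
revisiting = (stimuli with ≥ 1 revisit run)/*m* (so both are multiples of
1/*m*, and revisiting ≤ 1 − skipping); dwelling = mean first-run dwell over
fixated stimuli, with the target excluded in target-present trials so the
statistic is a pure distractor measure; dwelling is missing when every
distractor was skipped.  RT is only meaningful for correct responses;
incorrect trials are excluded from RT-based analysis everywhere.

Outlier filtering operates per participant within each target-presence ×
similarity × set-size cell, on the log scale, *one-sided*: values at or
above cell mean + k·SD (default k = 2) are removed.  One-sided because the
scheme is paired with explicit bottom cutoffs on the raw scale — 300 ms for
RT, 40 ms for dwells — which govern the lower tail.  Cell statistics are
computed once on pre-filter data (no iterative re-filtering), which makes
the floor rule and the SD rule commute.  Dwell filtering removes individual
stimulus dwells (not whole trials) and trial dwelling is then recomputed
from the survivors; this matches removal counts that far exceed trial
counts.  Cells with fewer than two observations skip the SD rule (floors
still apply) and are tallied with a warning.  On clean log-normal data the
SD rule removes about the upper Φ(−2) ≈ 2.3% per cell, which the filter
calibration test confirms.

## 3. Inference

Analyses use correct target-absent trials.  RT, skipping, dwelling,
revisiting, **and age** are z-transformed pooled across trials; dummy codes
(dissimilar = 0 / similar = 1, set size 5 = 0 / 10 = 1) are never
standardized, and interactions are products of standardized age with the
dummies.  Standardizing age is a deliberate choice: it puts between- and
within-subject coefficients on one comparable scale.  Trials with missing
dwelling drop listwise from models that include dwelling (logged).

Models are linear mixed regressions with a random intercept per
participant, estimated by REML through `statsmodels` `MixedLM` (default
gradient optimizer, with a derivative-free Powell retry when the gradient
path stalls near the zero-variance boundary; an unconverged fit raises).
With thousands of trial-level observations, t statistics are referred to
the standard normal and |t| > 1.96 is flagged significant; no
multiple-testing correction is applied, and coefficients should be read by
size (|b| < 0.10 very small, 0.10–0.29 small, 0.30–0.49 medium, above 0.50
large; boundaries fall upward except 0.50, which is still medium).

Diagnostics: tolerance = 1 − R² of each fixed-effect predictor regressed on
the others (flagged at ≤ 0.70, critical at ≤ 0.10).  Note that
age × dummy interactions formed from uncentered dummies are intrinsically
correlated with their main effects, so those terms sit near tolerance 0.5
by construction and trigger the advisory warning.  Marginal R² =
var(Xβ̂) / (var(Xβ̂) + σ²_intercept + σ²_residual), which reduces to OLS R²
as the intercept variance vanishes.  Power for a bivariate correlation uses
the Fisher-z normal approximation, two-sided: power = P(|Z| > z₁₋α/₂) with
Z ~ N(atanh(r)·√(n−3), 1); it equals α at r = 0 and matches Monte-Carlo
rejection rates of the exact test within 0.02 on the tested (r, n) grid.

Pearson trial-level correlations are pairwise-complete; binary design
factors enter as dummies (point-biserial).  A constant column yields
missing entries rather than an error.

## 4. The synthetic study

The generator emulates the face-in-crowd search design: 45 subjects, ages
uniform over 19–85 (an optional gap toggle excludes 30–40, mirroring
samples thin in middle age), 8 blocks × 20 trials, similarity alternating
by block with the starting block counterbalanced across subjects, ten
target-present and ten target-absent trials per block, set sizes 5 and 10
balanced within block.  Displays sample distinct non-central grid cells
uniformly; each occupied center is jittered per axis by −10, −5, 0, 5, or
10 px, so any two stimulus centers are ≥ 180 px apart.

The observer model is deliberately phenomenological — enough structure to
endow the data with the correlational pattern the analysis assumes, no
claim to being a process model of guided search.  Per trial, given
covariates x = (age_z, sim, set, age_z·sim, age_z·set):

- inspection order: uniform random permutation;
- skip: each stimulus independently with p = invlogit(b₀ₛ + βₛ·x + uₛ);
- first-visit dwell: LogNormal(μ_d + β_d·x + u_d, σ_d), default
  μ_d = log 250 ms, σ_d = 0.45;
- revisit (target-absent only): each visited stimulus independently with
  p = invlogit(b₀ᵣ + βᵣ·x + uᵣ); revisit gaze = 0.7 × a fresh dwell draw
  (the 0.7 is an arbitrary documented default — revisit durations are
  measured but not modeled);
- u· are per-subject Gaussian intercepts (defaults: 0.40 logit for skip and
  revisit, 0.20 log for dwell, 60 ms for motor).

RT = Σ first dwells + Σ revisit gazes + Σ per-run transitions
(N(45, 15) ms, floored at 5) + motor residual (N(500 + 100·age_z + u_m,
100) ms, floored at 50) — exactly, for every trial, in integer
milliseconds.  The 100 ms/SD-age motor term is the model's *direct*
(non-oculomotor) age effect on RT; without it, age could influence RT only
through the eye metrics and the RT model's age coefficient would be null.
Error rates are per-condition constants (≈ 0.5–1% target-absent, 6–11%
target-present, worse in hard conditions); target-present trials end at
target fixation with detection probability 1, so they contain no revisits.
A lone planned revisit of the very last inspected stimulus could never be
interrupted; the generator demotes that stimulus one slot in the
(exchangeable) inspection order instead of cancelling, so no trial
statistic is perturbed — cancellation would otherwise leak a spurious
set-size effect into revisiting under null effects.  Only the degenerate
one-stimulus-visited case voids the revisit.

Ground truth (visit order, flags, dwells, RT components) is drawn before
and independently of event rendering, so a seed pins the identical study
whether or not events are rendered (`events=False` skips rendering for
simulation studies).  Rendering emits each run as one — occasionally two —
fixations at the stimulus center plus isotropic N(0, 10 px) noise, with
onsets accumulating the stored transition times; the classification
pipeline reproduces the truth *exactly* from these events, which is the
round-trip guarantee the tests enforce at full study scale.

**Calibration of the `paper_like` preset.**  The preset documents its
effect sizes as *standardized regression coefficients* (e.g. age → dwelling
0.36, similarity → dwelling 0.54, set size → skipping 0.37), but the
generator's βs live on logit/log link scales, where the same numbers would
realize very different standardized effects.  `simulate.calibrate_preset`
resolves this with a damped stochastic fixed point: simulate a pilot study,
run the exact analysis pipeline (filter + standardize + REML fits),
estimate each coefficient's link-to-standardized gain, rescale, repeat —
averaging several pilots in the late iterations so the frozen preset's
residual calibration error stays well under the recovery bias budget.  The
shipped file was produced by one documented run
(`calibrate_preset(seed=20260929)`, 250-subject pilots, 5 iterations) and
can be regenerated.  Verified recovery at study scale (45 subjects): every
injected coefficient's 200-replicate mean within ±0.05 of target, all signs
correct.  The RT-model coefficients are *emergent* from the mechanistic RT
composition, not injectable parameters: only their sign pattern (dwelling
and revisiting prolong RT, skipping shortens it, age slows the residual,
set size raises it) is a model guarantee, and only that is asserted.

**What the simulation does not emulate.**  No guidance or saliency
(inspection order is uniform, whereas real scanpaths are spatially
systematic), no saccade kinematics beyond what the threshold-parser
round-trip needs, no fatigue/practice, no within-trial dependence between
skip and dwell decisions, no face stimuli.  Passing tests therefore show
that the pipeline and models are *correct* — classification is lossless,
injected effects are recovered unbiasedly, nulls stay null — not that real
search data satisfy the model's independence assumptions.

## 5. Numerical and interface choices

- All millisecond fields are integers (pixels may be fractional); the RT
  decomposition is exact in integer arithmetic.
- z-transform uses the sample SD (ddof = 1) and propagates missing values;
  a constant series raises.
- One user seed drives everything; stages derive child seeds via
  `numpy.random.SeedSequence`.  Same seed ⇒ byte-identical outputs.
- Problem sizes in the test suite: the brute-force oracle covers 10,000
  random scanpaths; losslessness is checked on one full 45 × 160 study at
  event level; recovery and type-I calibration use 200 replicate studies
  each at trial level (the truth/rendering split above is what makes that
  cheap).
- File formats: tab-separated fixation/layout/trial tables mirroring a
  vendor fixation-report export (uppercase headers), comma-separated trial
  statistics and coefficient tables, key=value preset and filter-report
  files, JSON-lines path summaries.  Simulator outputs carry their seed in
  a `#` header line.  The trial-statistics table appends an `AGE` column to
  the canonical header, carrying the covariate the regression stage needs.

## 6. Known limitations

- The fixation parser is intentionally minimal (see §1); use vendor
  fixation reports when available.
- Tolerance warnings for age × dummy interaction terms reflect the coding,
  not a data problem (§3).
- Random slopes, Satterthwaite/Kenward-Roger degrees of freedom, Bayesian
  estimation, and structural-equation modeling of the two-stage system are
  out of scope; with ~3,500 observations the normal-reference t is mildly
  anti-conservative for between-subject terms (45 clusters), visible as a
  type-I rate nearer 6% than 5% in the null calibration.
- The generator's error-rate table is a per-condition constant; error
  *processes* (lapses, guesses) are not modeled, because incorrect trials
  are excluded from analysis anyway.
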