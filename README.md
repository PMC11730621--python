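# gazesearch

Eye-movement analysis of **distractor rejection in visual search**, as a
reusable, tested pipeline.

When people search a display for a target among distractors, overall search
time hides three distinct ways of dealing with each distractor: a distractor
can be **skipped** (never fixated, rejected peripherally), **dwelt on** (the
first continuous series of fixations on it — its *dwell time* — reflects how
hard it is to reject foveally), or **revisited** (fixated again after at
least one intervening fixation elsewhere, reflecting forgetting or
insufficient first-pass processing).  `gazesearch` classifies raw fixation
sequences over grid-based search displays into these three trial-level
measures and models how they relate to observer age, target-distractor
similarity, display set size, and search reaction time (RT) on
target-absent trials, where distractor rejection is observable
uncontaminated by target selection.

The package was built for behavioral/cognitive-aging researchers working
with fixation-report exports from video-based eye trackers, and for anyone
who needs a fully verifiable reference implementation: a synthetic
display-and-scanpath generator with complete ground truth makes every stage
testable end to end without any recorded data.

## What it computes

**Classification.** Fixations (parsed from gaze samples by a 30 deg/s speed
/ 8,000 deg/s² acceleration threshold rule, or supplied directly as a
fixation report) are assigned to 101 × 130 px rectangular areas of interest
(AOIs) on a 7 × 3 location grid (200-px pitch, center reserved for the
fixation marker) — by containment, else to the nearest AOI center.
Fixations on unoccupied AOIs are discarded; the rest are segmented into
maximal same-stimulus *visit runs*.  Per trial:

- *Skipping* = proportion of stimuli never fixated,
- *Revisiting* = proportion fixated again after an interruption,
- *Dwelling* = mean first-run dwell time over fixated distractors
  (revisit gaze never counts, keeping the measures unconfounded),
- *RT* = display onset to the correct-answer keypress.

**Filtering.** RTs and per-stimulus dwell times are log-transformed and
filtered per participant within each target-presence × similarity × set-size
cell: values ≥ cell mean + 2 SD are removed (one-sided, paired with raw
bottom cutoffs of 300 ms for RT and 40 ms for dwells).

**Inference.** With z-standardized metrical variables and dummy-coded
factors (dissimilar = 0/similar = 1; set size 5 = 0/10 = 1), the package fits
REML random-intercept models (per-participant intercept, t referred to the
standard normal, |t| > 1.96 significant):

```
skipping / dwelling / revisiting ~ age + sim + set + age:sim + age:set + (1 | participant)
rt ~ skipping + dwelling + revisiting + age + sim + set + (1 | participant)
```

plus trial-level Pearson correlations, per-predictor tolerance (1/VIF),
marginal R² (fixed-effect variance share), effect-size labels for
standardized coefficients, and two-sided power for a bivariate correlation
via the Fisher-z approximation.

**Simulation.** A phenomenological observer: stimuli inspected in random
order, each independently skipped (inverse-logit), log-normal first-visit
dwells, independent post-pass revisits; age, similarity, set size, and
age × difficulty products act linearly on the link scales with per-subject
intercepts.  RT is assembled mechanistically and exactly as
`RT = Σ dwells + Σ revisit gazes + Σ transitions + motor`.  The shipped
`paper_like` preset is calibrated so that the realized *standardized*
eye-metric coefficients match its documented targets; `null` has all
effects at zero for type-I calibration.

## Worked example

```sh
gazesearch simulate --preset paper_like --seed 7 --out demo --subjects 6 --blocks 2
gazesearch process  --out demo --compare-truth demo/truth_trials.csv
gazesearch analyze  --out demo --seed 7
```

`process` prints the ground-truth verification:

```
skipping: exact match
revisiting: exact match
dwelling_ms: exact match
rt_ms: exact match
```

meaning every trial's four statistics computed from the rendered fixation
events equal the generator's truth bit for bit.  `analyze` logs

```
analysis done: n_obs=120, marginal R2 (RT model)=0.803
```

and writes `table4_{skipping,dwelling,revisiting}.csv` and `table5_rt.csv`
(columns `term, b, sd_b, t, significant, effect_size`),
`table3_correlations.csv`, a `path_summary.jsonl` edge list of the fitted
two-stage coefficients, and `filter_report.txt` with the outlier tallies.
Here `n_obs=120` is the correct target-absent trial count of this toy run
(6 subjects × 40 trials × ½ absent, minus errors/outliers), and marginal
R² ≈ 0.80 says the fixed effects dominate RT variance — expected, since the
simulator composes RT from the eye metrics plus set-size-dependent
transition counts.

The same stages are available as library calls (`simulate_study`,
`process_dataset`, `analyze_dataset`); see `docs/methods.md` for the model,
parameter, and design documentation.

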