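# Methods

## The data and what the pipeline computes

`mtpipe` analyzes cursor trajectories from two-choice categorization
experiments run in a web browser.  On every trial the participant's cursor
starts on the **Next** button (the mandatory end point of the previous
trial), a stimulus appears, and the participant clicks one of two category
buttons placed 570 px apart, 472 px above the Next button.  While the page
is active, JavaScript samples the cursor position roughly every 16–18 ms.
The raw export is *wide*: one CSV row per subject, with the whole session's
(x, y, t) triplets stored as long character-separated strings (separator
`"a"`), and per-trial quantities (trial onset `onReadyTime`, category click
`buttonClickTime`, window size, alert codes, latency, presentation order)
stored as shorter streams with one token per trial.

The pipeline segments these streams into trials (a sample belongs to trial
*j* iff `onReady_j <= t <= buttonClick_j`, closed because the boundary
samples are the onset and the click), undoes the randomized presentation
order, applies quality control, and computes five trial-level measures of
category competition:

- **xflips** — sign reversals of the successive horizontal displacements;
- **xdev** — max over samples of |x̃ − L(ỹ)|, where (x̃, ỹ) is the
  trajectory min–max rescaled to the unit square and L is the straight
  "ideal" line from start to end, parametrized by the vertical coordinate
  (progress toward the buttons) and extended linearly beyond its endpoints;
- **area** — trapezoidal Riemann sum Σ ((dᵢ+dᵢ₊₁)/2)·|ỹᵢ₊₁−ỹᵢ| of the
  unsigned deviations dᵢ = |x̃ᵢ − L(ỹᵢ)|, so excursions on both sides of the
  ideal line accumulate rather than cancel;
- **maxspeed** — peak Euclidean displacement per ms on *raw* pixels
  (only the three spatial measures are unit-rescaled and unitless);
- **rt** — `buttonClick − onReady` in ms.

Design choices where the definitions were genuinely open: deviation and
area are parametrized by ỹ rather than by time or arc length, because
"horizontal deviation at matched vertical progress" matches the geometry of
the task (a time-parametrized variant is available through `rescale_time`);
the Riemann sum is trapezoidal with a left-endpoint option
(`riemann_method="left"`); zero-valued x-steps are skipped when counting
flips and a configurable jitter threshold (default 0) can discard sub-pixel
trembles; browser y grows downward but every measure is invariant to the
y direction, so no flip is applied (plots invert y for display only).
Trials with fewer than two samples, zero duration, or no vertical progress
(start ỹ = end ỹ) yield explicit missing values rather than contrived
numbers.

## Quality control

QC never raises on bad data; it records reasons.  Structural defects —
`missing_trajectory`, `stream_length_mismatch`, `nonmonotone_time`,
`wrong_trial_count` — mark a subject for exclusion under the default
**conservative** policy (any defect on any trial excludes the subject); the
**permissive** policy keeps any subject with at least one intact trial.
Non-monotone timestamps are flagged, never re-sorted: re-sorting would
fabricate dynamics.

Two display idiosyncrasies become model covariates, not exclusions:

- `weird_scaling` — non-standard pixel scaling (typically browser zoom),
  detected when any trial's |x_last − x_first| falls outside
  E·(1 ± τ), where E = 285 px is half the button separation (the cursor
  starts centred between the buttons and ends on one of them) and τ = 0.25
  by default.  The source experiment reports only "unexpectedly large or
  small" distances; ±25% is this package's default band and both E and τ
  are configurable.
- `wts` — "window too small": any trial ran in a window below the
  interface minimum (default 800×600 px, the smallest window that fits the
  570-px button row plus a stimulus; configurable) or carries alert code 4.

Alert codes recorded per trial: 1 = started too early, 2 = started too
late (first movement after 700 ms), 3 = exceeded the 5000 ms answer limit,
4 = window too small.  A trial can trigger several; tokens are the
concatenated sorted digits (`0` none, `23` codes 2 and 3), which keeps the
alert stream numeric.  Recomputed latency (first sample whose position
differs from the trial's initial position, minus onset) is cross-checked
against the recorded latency; disagreement beyond 50 ms is logged as a
warning, not a defect, since browser event timing jitters.

## Models

Each outcome is regressed on the 0/1 stimulus-ambiguity indicator with
trials as the unit of analysis, using GEE with an exchangeable working
correlation over subjects and robust (sandwich) inference, via
`statsmodels`.  Robust inference defaults to the Mancl–DeRouen
bias-reduced sandwich with a t reference (df = clusters − parameters):
the plain sandwich with a normal reference rejects at ~6–7% instead of
the nominal 5% with 50 clusters, while the corrected form stays at
~5% there and is indistinguishable from the plain sandwich at ≳150
clusters.  `cov_type="robust"` restores the plain sandwich.  Continuous outcomes are z-scored across all analyzed trials
(both ambiguity groups pooled), so coefficients read as standard-deviation
differences for ambiguous versus unambiguous trials; x-flips use a Poisson
log link (no dispersion parameter is needed under sandwich inference).  The
nuisance design is the full factorial expansion of {ambiguous,
weird_scaling, wts}: three main effects, three 2-way interactions, one
3-way interaction.  Terms that are inestimable in a given sample — constant
columns, exact duplicates, or terms whose sandwich variance is not finite
and positive (near-collinear indicators in sparse cells) — are dropped with
a warning and listed on the fit object.  Rows with missing outcomes or
covariates are dropped listwise per model, with counts recorded.
Moderation models add a two-level moderator (browser or operating system;
rows from rarer levels are excluded) and its interaction with ambiguity.

## The simulator

Real cohorts for this design are crowdsourced and not redistributable, so
the package ships a generator whose output is the test oracle for the whole
pipeline.  Cursor dynamics follow a two-attractor model: the cursor sits on
the Next button for a gamma-distributed latency (shape 1.2, scale 350 ms,
mean ≈ 420 ms), then moves toward the currently active category button at
0.8 px/ms with Gaussian positional noise (SD 3 px per step — enough hand
tremor that direction reversals occur at a small positive rate even on
unambiguous trials, as in human data, keeping the Poisson x-flips model
well-posed), sampled every
17 ± 1 ms.  On ambiguous trials the active attractor switches between the
buttons as a Poisson process (default hazard 0.002/ms) until a commit time
(normal, mean 600 ms, SD 250 ms, truncated at 0, measured from movement
onset), and each switch triggers a brief speed burst (×1.8 for 150 ms) —
the abrupt corrective lunge a category shift produces.  The trial ends when
the cursor is within 15 px of the chosen button.  This mechanism makes all
five measures larger on ambiguous trials, which is the qualitative
prediction of category competition, without targeting any particular effect
size.

Defaults for injected idiosyncrasies mirror an uncontrolled crowdsourced
collection: 40% of subjects zoomed (factors drawn from browser zoom stops
{0.5, 0.67, 1.5, 2}, all outside the ±25% scaling band), 10% with a
too-small window on ≥1 trial, 10% losing their coordinate streams entirely,
independent Bernoulli "started too early" alerts at 10%.  Alert codes 2–4
are derived by applying the collector's rules to the generated timings, not
injected.  Speed and latency defaults put the simulated median RT near
1.1 s and median sampling interval at 17 ms, in line with reported values
for this kind of collection.  Epoch timestamps start from an arbitrary
fixed origin, since only differences matter downstream.  Coordinates and
times are emitted as integers (pixels and ms), like the real collector.

What the simulator does **not** emulate: human kinematic regularities
(Fitts' law, minimum-jerk velocity profiles), practice-block behavior,
inter-trial cursor motion, partial within-trial data loss, or stimulus-level
heterogeneity in difficulty.  Passing tests therefore demonstrate that the
pipeline's bookkeeping, measures and inference behave correctly under a
controlled generative model — not that the dynamics model is an accurate
account of human reaching.

A second, outcome-level generator (`simulate_measures_table`) bypasses
trajectories and draws measures directly from an exchangeable Gaussian
model (subject intercept variance = ICC, residual variance = 1 − ICC, so a
planted coefficient *is* the standardized ambiguity effect) plus a Poisson
model with log-normal frailty for x-flips.  It is the harness for the
frequentist checks of the GEE machinery — type-I error at the nominal 5%,
bias and ~95% interval coverage for a planted effect — where the
trajectory model cannot fix the true standardized effect exactly.

## Problem sizes and numerical choices

The shipped validation studies use: 1000 random trajectories for
brute-force oracle equivalence (exact for flips, 1e−12 relative for the
rest); a 200-subject clean cohort for export round-trip exactness; 500
subjects for QC-rate calibration against exact binomial 95% bands; 10,000
trials for alert-rule agreement; 500 replicates of 50×10 for type-I error
and 200 replicates of 100×10 for effect recovery; and a 188-subject cohort
under default conditions for the end-to-end run (188×10 = 1880 trials when
clean).  Sub-seeds are derived deterministically from the single run seed.
Min–max rescaling of a degenerate axis maps to 0 and marks the trajectory;
samples landing exactly on a trial's time boundary belong to that trial;
when two trial windows could both claim a sample the earlier trial wins and
each sample is assigned at most once.

## Known limitations

Exclusion accounting follows the stated conservative rule only; the
simulator's data loss is all-or-none per subject, so the permissive policy's
"some intact trials" branch is exercised only by hand-built fixtures.
Even the bias-reduced sandwich is only approximately calibrated below
~30 clusters.  The moderation models assume the moderator is constant
within subject.
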