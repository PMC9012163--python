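# Methods

## From pen samples to strokes

A trial is a sequence of timestamped pen samples (t, x, y, p): position in
centimetres (y up, origin at the tablet's bottom-left), pressure normalised
to [0, 1], time in seconds from trial start.  Raw tablet dialects are
converted on read: counts / lpi x 2.54 cm, y flipped with the declared
active-area height, pressure divided by the declared maximum (8191 for a
8192-level stylus).

The extraction pipeline is: linear resampling onto a uniform 200 Hz grid;
zero-phase low-pass filtering (forward-backward 4th-order Butterworth);
differentiation; pen-down segmentation (pressure > 0.10); stroke boundaries
at reversals of vertical velocity.  A reversal is accepted only after |vy|
has exceeded 5% of the run's maximum on both sides (hysteresis), the
boundary sits at the sample nearest the vy sign change, and candidate
strokes shorter than 30 ms are merged into their predecessor.  Within a
pen-down run strokes therefore partition the samples and alternate
direction; direction is the sign of mean vy (US up, DS down).

### Three frequency bands

One cutoff cannot serve all three measures, so the pipeline deliberately
uses three bands on the same grid:

* **Segmentation band, 10 Hz.**  Stroke reversals are slow events; a low
  band keeps the vy sign structure clean.  Standard for handwriting
  kinematics.
* **Trajectory band, 20 Hz.**  The 10 Hz zero-phase filter's kernel has
  negative side lobes that overshoot at stroke reversals and inflate arc
  length by ~0.01 cm per stroke, while raw positions inflate it through
  jitter rectification (~0.02 cm); a mid band minimises both (residual bias
  ~+0.002 cm).  Path length is the polyline sum over the stroke span.
* **Dysfluency band, 45 Hz.**  Dysfluency transients in these strokes live
  near 25-40 Hz and are annihilated at 10 Hz, while digitiser jitter
  dominates above ~50 Hz.  Speed in this band is computed with a 4th-order
  difference stencil (a plain central difference loses 24% at 40 Hz on a
  200 Hz grid) followed by a 3-tap binomial smoothing of the scalar speed.

Interior stroke boundaries found in the segmentation band are refined to
the nearest vy sign change of the dysfluency band within a 30 ms window:
any velocity event close to a reversal is smeared across it by the 10 Hz
kernel and can drag the coarse crossing by several samples, which would
leak duration between neighbouring strokes.

### Counting velocity peaks

A dysfluency peak is a strictly interior local maximum of the stroke's
speed whose topographic prominence is at least 10% of the stroke's maximum
speed; among qualifying peaks, smaller ones within 30 ms of a larger one
are discarded; plateaus count once at their midpoint; endpoint maxima never
count (they indicate segmentation slippage, not dysfluency).  The
implementation is scipy's peak finder plus an explicit greedy separation
filter, and is held equal, in tests, to an exhaustive O(n^2) scan that
re-derives prominences from the definition.

## The analysis unit and the models

Both bigrams begin with a cursive *l*; the first letter's US and DS are
strokes 0 and 1 of the first pen-down run (positional identification — no
shape matching).  Trials whose first run has fewer than two strokes or
starts with a descending stroke are flagged and excluded from aggregation
(logged, never imputed).  Unflagged trials are averaged into subject x
direction x bigram cells; the mixed models consume cell means because the
published denominator df (138 with 48 subjects x 4 cells) is the cell-mean
residual df, not the trial-level one.

Per measure, a random-intercept LMM is estimated by REML, profiled to the
single variance ratio lambda = sigma2_subject / sigma2_resid: for fixed
lambda the GLS coefficients and the REML criterion are closed-form through
the per-subject block structure of V = I + lambda ZZ', and lambda is found
by bounded scalar search (the lambda = 0 boundary is checked explicitly).
The fit matches statsmodels' MixedLM to ~1e-7 and an exhaustive lambda grid
in tests.  Type-III Wald F tests use sum-to-zero coding, under which each
of the seven factorial terms is a single coefficient (df1 = 1).
Satterthwaite denominator df follow the standard delta-method construction
df2 = 2 (c'Vc)^2 / Var(c'Vc), with Var from numerical derivatives of c'Vc
over the two variance components and the inverse numerical REML observed
information; a subject variance estimated on its boundary is treated as
structurally zero, collapsing the df to the fixed-effects residual df.
In the balanced design the computed df land on the classical values (within
terms ~138, group ~46).  Estimated marginal `ll - ln` contrasts within each
group x direction are Holm-adjusted over the 4-contrast family (the
adjustment in the original analysis is unstated; Holm is conservative and
assumption-free, and unadjusted p values are reported alongside).  Partial
eta-squared is df1 F / (df1 F + df2).

Spearman correlations are pairwise-complete with average ranks; two-sided p
values use the t approximation on n - 2 df.  Zero-variance variables are
reported as missing rather than zero.

## The synthetic cohort

The generator defines the study conditions: 24 subjects per group, 2
bigrams, 10 trials per bigram, 200 Hz emission, Gaussian position jitter of
0.002 cm, subject intercept SDs of 0.015 s / 0.05 cm and trial SDs of
0.030 s / 0.08 cm for duration / trajectory.

A stroke's speed profile is a raised-cosine pulse whose integral equals the
nominal path; vy = +/-speed cos(8 deg), vx = speed sin(8 deg) (a fixed
writing slant), positions by cumulative integration.  A trial is the first
letter (US then DS, drawn from the per-cell means below), a pen-down
connection, and a second letter as nominal scenery strokes (two for *l*,
four for *n*) whose only purpose is to force the segmentation to isolate
the first letter; pen-up lead-in/out samples carry p = 0.

Per-cell first-letter means were solved from the published marginal means
under balanced pooling and two-decimal rounding (the paper prints margins,
never cells): durations US 0.195 everywhere except SCZ/ln 0.197; DS 0.190
except CTRL/ln 0.250 and SCZ/ln 0.192; trajectories 0.625 cm for controls
except CTRL/ln/DS 0.725, and 0.840 cm for patients (macrography).  The
anticipation effect is +0.060 s and +0.100 cm on the control downstroke
before *n* only; patients carry a +0.002 s non-directional *ln* elevation,
small enough that their contrasts are genuinely null at this sample size.
With anticipation disabled the CTRL/ln/DS cells reset to their *ll* values,
giving an exact null for type-I calibration.

**Dysfluency events.**  Extra velocity peaks are injected as zero-net-area
events: a sharp corrective bump (50% of the primary's height, width
max(0.15 D, 35 ms)) paired with a broad shallow trough displaced toward the
stroke's interior — the pen accelerates briefly and pays the speed back.
Zero net area keeps the speed integral equal to the nominal path and leaves
no low-frequency footprint that could drag stroke boundaries.  Only the two
shoulders of the primary pulse can host a bump that survives as a distinct
local maximum (centers at ~8-13% of the stroke from either end, at least
25% of the stroke away from the primary peak), so a stroke carries at most
two events; per-stroke counts are min(Poisson(lambda'), 2) with lambda'
solved so the capped mean equals the nominal rate, making cell means
exactly 1 + lambda (CTRL 0.0325 / 0.1425 and SCZ 0.4125 / 0.5225 for
US / DS).  Event-carrying strokes are drawn at >= 0.17 s (0.20 s for two
events) with a tighter trial SD (0.015 s): below these durations the
primary's shoulder slope provably swallows the bump's prominence.  This
moves pooled duration margins by under 2 ms and couples dysfluency weakly
to duration — as in real writing, where dysfluent strokes take longer.

Clinical covariates are truncated normals whose *post-truncation* means
equal the published means at the published SDs (naive truncation at the
scale minima would shift PANSS-P by +0.55 and SAS by +2.3).  The
dominant-hand Purdue score is coupled to each patient's mean nominal stroke
trajectory through a Gaussian copula at Spearman rho = -0.5; all other
covariates are independent.

Randomness uses per-subject and per-trial child generators keyed by
(seed, group, subject, bigram, trial), so any single trial is reproducible
in isolation and cohorts are byte-identical across runs of the same seed.

## What the synthetic data do and do not show

The generator reproduces the study's *effect structure* and *descriptive
levels*, not its full error structure: real handwriting has letter shapes,
curvature, baseline drift, variable slant, pressure dynamics and
heavy-tailed trial noise, none of which are modelled.  Effects are
correspondingly cleaner — the duration F statistics on synthetic cohorts
are an order of magnitude larger than the published ones (the published
cell-level variability cannot be reconstructed from the printed marginal
SDs, which mix dispersion units).  Passing tests therefore demonstrate that
the measurement chain is unbiased and the inference machinery correct under
the stated conditions, not that the pipeline's accuracy transfers to real
traces.  Stochastic calibration targets carry seed-level uncertainty of
roughly 0.005 cm / 0.01 peaks (SE over five cohorts), so quantities sitting
within ~0.005 of a two-decimal rounding edge can round either way; the
tests report this precisely rather than widening the check.

## Numerical choices and limitations

* Resampling is linear; boundary quantisation is to the nearest sample
  (about +-2.5 ms per boundary, mean-unbiased).
* filtfilt pad length is capped for short traces; traces must have >= 8
  samples to enter the pipeline.
* The REML criterion guards exact-fit degeneracy (residual variance floored
  at 1e-300) and returns +inf off-domain; a singular information matrix
  falls back to residual-df tests rather than failing the analysis.
* The LMM supports only the 2x2x2 factorial with a single random intercept
  — no random slopes, no Kenward-Roger df, no unbalanced multi-level
  factors beyond missing cells.
* Dysfluency counting assumes the 200 Hz default grid; at other rates the
  separation and window constants scale in seconds, not samples.
* Segmentation offers no curvature-based or velocity-minimum alternative,
  and no Sigma-Lognormal decomposition.
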