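# penkin — handwriting kinematics of motor anticipation

`penkin` is an analysis pipeline for studying **motor anticipation in cursive
handwriting**, built around the paradigm used to probe motor dysfunction in
schizophrenia: participants write the bigrams *ll* and *ln* on a digitising
tablet, and the kinematics of the **first letter** reveal whether the writer
is already programming the *next* letter while producing the current one.
In skilled writers the downstroke (DS) of the first *l* is longer — in time
and in path — when the following letter requires a change of size and
rotation (*ln*) than when the same motor program repeats (*ll*); an absent
modulation is read as a loss of anticipatory motor planning.

Three classic measures are computed per stroke:

* **Duration** (s) — time per stroke, bounded by reversals of vertical
  velocity;
* **Trajectory** (cm) — arc length of the pen path within the stroke;
* **Dysfluency** — the number of velocity peaks in the tangential speed
  profile (a smooth stroke has exactly one).

Inference follows the study design: for each measure a linear mixed model

```
y_ijk = (Group x Direction x Bigram)'beta + b_i + e_ijk,
b_i ~ N(0, sigma2_subject),  e_ijk ~ N(0, sigma2_resid)
```

is fitted by REML on subject x direction x bigram cell means with a random
intercept per subject, using sum-to-zero coding; Type-III Wald F tests get
**Satterthwaite** denominator degrees of freedom, effect sizes are partial
eta-squared `df1*F / (df1*F + df2)`, and the four `ll - ln` contrasts within
group x direction are Holm-adjusted.  Clinical covariates (PANSS, SAS,
chlorpromazine equivalents, illness duration, education, Purdue Pegboard)
are related to per-subject kinematics through a Spearman matrix.

Because the original recordings are not public, the package ships a
**synthetic cohort generator** that emulates the study conditions — 24
patients and 24 controls, repeated trials per bigram, pen traces with
velocity-pulse strokes, injected dysfluency events, digitiser jitter, and
clinical covariates at the published summary levels — calibrated so the full
pipeline reproduces the published descriptive means.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1     # 960 trials -> results/analysis/cohort
python analysis/02_extract_features.py             # strokes -> features.csv, cells.csv
python analysis/03_fit_anticipation_models.py      # mixed models + contrasts
python analysis/04_clinical_correlations.py        # Spearman matrix
```

On the seed-1 cohort the extraction step prints the pooled first-letter
means

```
DS duration (s)        0.210      SCZ trajectory (cm)    0.833
ll duration (s)        0.195      CTRL trajectory (cm)   0.661
SCZ dysfluency         1.457      CTRL dysfluency        1.087
```

and the duration model prints, among its seven effects and four contrasts,

```
group:direction:bigram  F(1, 138.0) = 143.19  p = 0.0000
CTRL-DS ll-ln: -0.0580 (t(138) = -24.23, Holm p = 0.0000) *
CTRL-US ll-ln: +0.0008 (t(138) = +0.34, Holm p = 1.0000)
SCZ-DS ll-ln:  -0.0010 (t(138) = -0.43, Holm p = 1.0000)
SCZ-US ll-ln:  +0.0005 (t(138) = +0.21, Holm p = 1.0000)
```

— the anticipation signature: the downstroke of the first letter lengthens
before an *n* only in controls (here by ~58 ms), while both patient
contrasts are null.  The Satterthwaite denominator df land on the classical
balanced-design values (138 within subjects, 46 for the group effect).  The
correlation step reports Spearman rho = -0.51 (p = 0.01) between
dominant-hand Purdue score and mean stroke trajectory — worse dexterity,
larger writing — with all other clinical-kinematic pairs null.

The same pipeline is available as a CLI (`penkin simulate / extract /
analyze / report / repro`) for running on recorded traces: a cohort is a
manifest CSV pointing at per-trial trace files (plain CSV with a `#` header
declaring dialect, resolution in lpi, and sampling rate; raw tablet counts
are converted at 2.54 cm per inch and flipped to y-up).

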