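"""Synthetic pen-trace cohorts with the study's motor-anticipation structure.

The generator emulates the experiment the pipeline analyses: two groups of
24 subjects (schizophrenia SCZ, control CTRL) writing the cursive bigrams
*ll* and *ln* repeatedly on a digitiser.  Each trial is a sequence of
direction-alternating strokes whose speed profile is a primary raised-cosine
pulse, optionally carrying secondary pulses (dysfluency events); positions
follow by integrating velocity along a fixed slant.  The effect structure:

* anticipation: in controls only, the first letter's downstroke is longer in
  *ln* than *ll* (+0.060 s, +0.100 cm) — writing an *l* while preparing the
  size/rotation change of an *n* slows and lengthens the descending stroke;
* patients write larger (macrography: all first-letter strokes 0.840 cm) and
  more dysfluently (higher secondary-pulse rates), with only a small
  non-directional *ln* elevation, so their ll-vs-ln contrasts are null-ish;
* clinical covariates are drawn at the cohort's published summary levels,
  with dominant-hand dexterity (Purdue) rank-coupled to stroke size.

Cell means were chosen so that balanced pooling reproduces the study's
printed marginal means after two-decimal rounding; dysfluency counts per
stroke are shoulder-capped Poisson draws whose rates are compensated so the
cell means are exactly 1 + lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .io import BIGRAMS, GROUPS, CohortManifest, PenTrace, write_manifest, write_trace

SLANT_DEG = 8.0  # fixed writing slant: vy = +/- speed*cos, vx = speed*sin

#: per-(group, direction, bigram) first-letter stroke duration means (s)
DEFAULT_DURATION_MEANS = {
    ("CTRL", "US", "ll"): 0.195, ("CTRL", "US", "ln"): 0.195,
    ("SCZ", "US", "ll"): 0.195, ("SCZ", "US", "ln"): 0.197,
    ("CTRL", "DS", "ll"): 0.190, ("CTRL", "DS", "ln"): 0.250,
    ("SCZ", "DS", "ll"): 0.190, ("SCZ", "DS", "ln"): 0.192,
}

#: per-(group, direction, bigram) first-letter stroke path means (cm)
DEFAULT_TRAJECTORY_MEANS = {
    ("CTRL", "US", "ll"): 0.625, ("CTRL", "US", "ln"): 0.625,
    ("CTRL", "DS", "ll"): 0.625, ("CTRL", "DS", "ln"): 0.725,
    ("SCZ", "US", "ll"): 0.840, ("SCZ", "US", "ln"): 0.840,
    ("SCZ", "DS", "ll"): 0.840, ("SCZ", "DS", "ln"): 0.840,
}

#: Poisson rates of secondary (dysfluency) pulses by (group, direction)
DEFAULT_PEAK_RATES = {
    ("CTRL", "US"): 0.0325, ("CTRL", "DS"): 0.1425,
    ("SCZ", "US"): 0.4125, ("SCZ", "DS"): 0.5225,
}

#: published clinical summaries: name -> (mean, sd, lower bound)
CLINICAL_MARGINS = {
    "panss_p": (16.04, 5.39, 7.0),
    "panss_n": (20.22, 6.96, 7.0),
    "panss_g": (33.86, 10.00, 16.0),
    "sas": (3.21, 5.09, 0.0),
    "cpze": (779.37, 419.28, 0.0),
    "illness_years": (15.36, 10.11, 0.0),
    "education_years": (10.79, 4.48, 0.0),
    "purdue_dom": (13.74, 8.65, 0.0),
    "purdue_nondom": (10.73, 2.95, 0.0),
    "purdue_both": (8.01, 2.25, 0.0),
    "purdue_asm": (28.59, 9.23, 0.0),
}

#: Spearman coupling between dominant-hand Purdue and mean stroke trajectory
PURDUE_TRAJECTORY_RHO = -0.5


class FeasibilityError(ValueError):
    """Requested secondary pulses cannot be separated under the margins."""


@dataclass(frozen=True)
class PulseMargins:
    """Detectability margins for secondary pulses, relative to the stroke."""

    rel_amplitude: float = 0.50     # secondary peak height / primary height
    rel_width: float = 0.15         # secondary pulse width / stroke duration
    rel_separation: float = 0.25    # min |center - primary peak| / duration


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_subjects_per_group: int = 24
    trials_per_bigram: int = 10
    seed: int = 0
    rate_hz: float = 200.0
    duration_means: dict = field(default_factory=lambda: dict(DEFAULT_DURATION_MEANS))
    trajectory_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAJECTORY_MEANS))
    peak_rates: dict = field(default_factory=lambda: dict(DEFAULT_PEAK_RATES))
    subject_sd_duration: float = 0.015
    subject_sd_trajectory: float = 0.05
    trial_sd_duration: float = 0.030
    trial_sd_trajectory: float = 0.08
    position_jitter_sd: float = 0.002
    margins: PulseMargins = field(default_factory=PulseMargins)
    anticipation_enabled: bool = True

    def __post_init__(self) -> None:
        if not self.anticipation_enabled:
            self.duration_means[("CTRL", "DS", "ln")] = self.duration_means[("CTRL", "DS", "ll")]
            self.trajectory_means[("CTRL", "DS", "ln")] = self.trajectory_means[("CTRL", "DS", "ll")]
        if any(v <= 0 for v in self.duration_means.values()):
            raise ValueError("duration means must be positive")
        if any(v <= 0 for v in self.trajectory_means.values()):
            raise ValueError("trajectory means must be positive")
        if any(v < 0 for v in self.peak_rates.values()):
            raise ValueError("peak rates must be non-negative")


@dataclass
class StrokeSpec:
    """Analytic description of one stroke's speed profile.

    speed(tau) = amp * rc(tau; 0, D) plus one dysfluency event per secondary
    pulse, where rc is a raised-cosine bump.  A dysfluency event is
    zero-net-area: a sharp corrective bump (relative amplitude
    ``rel_amplitude``, width W) paired with a broad shallow trough (width
    2W, half the height) displaced toward the stroke's interior — the pen
    briefly accelerates and pays the speed back.  Zero net area keeps the
    time integral of speed equal to the nominal path and leaves no
    low-frequency footprint that could drag the stroke boundaries in the
    segmentation band.
    """

    duration: float
    path: float
    direction: str              # "US" | "DS"
    pulse_centers: np.ndarray   # secondary pulse centers, in [0, duration]
    rel_amplitude: float
    pulse_width: float
    amp: float                  # primary pulse height (cm/s)

    @staticmethod
    def _rc(tau, center, width, height):
        local = (np.asarray(tau, dtype=float) - center) / width
        return np.where(np.abs(local) <= 0.5,
                        0.5 * height * (1 + np.cos(2 * np.pi * local)), 0.0)

    def speed_at(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        out = np.where(
            (tau >= 0) & (tau <= self.duration),
            0.5 * self.amp * (1 - np.cos(2 * np.pi * np.clip(tau, 0, self.duration) / self.duration)),
            0.0,
        )
        h = self.amp * self.rel_amplitude
        w = self.pulse_width
        for c in self.pulse_centers:
            inward = 1.0 if c < self.duration / 2 else -1.0
            out = out + self._rc(tau, c, w, h)
            out = out - self._rc(tau, c + inward * 1.5 * w, 2 * w, h / 2)
        return np.maximum(out, 0.0)

    def sample(self, rate: float) -> tuple[np.ndarray, np.ndarray]:
        """Speed samples on a grid of the given rate over [0, duration]."""
        n = int(round(self.duration * rate)) + 1
        t = np.arange(n) / rate
        return t, self.speed_at(t)


#: minimum stroke duration (s) able to carry a detectable secondary pulse.
#: A bump of the configured relative amplitude survives as a distinct local maximum
#: only while the primary pulse's shoulder slope is shallow relative to the
#: bump's own slope; on shorter strokes the margins fall under the default
#: detector's floor, so pulse-carrying strokes are drawn at least this long
#: (with tighter trial spread, so cell duration means move only ~2 ms).
MIN_PULSE_STROKE_DURATION = {1: 0.17, 2: 0.20}
TRIAL_SD_DURATION_PULSED = 0.015
#: absolute floor (s) on the secondary-pulse width: narrower bumps fall
#: outside the dysfluency band and would be smoothed away.
MIN_PULSE_WIDTH_S = 0.035
#: only the two primary-pulse shoulders can host a detectable bump, so a
#: stroke carries at most 2 secondary pulses.
MAX_PULSES_PER_STROKE = 2


def _place_pulse_centers(duration: float, n: int, margins: PulseMargins,
                         rng: np.random.Generator) -> np.ndarray:
    """Secondary-pulse centers: one per shoulder of the primary pulse,
    >= rel_separation*D away from the primary peak at D/2, mutually
    separated, and clear of the stroke edges (edge maxima are never
    counted).

    Only the low-slope outer shoulders can host a bump that survives as a
    distinct local maximum with the configured relative amplitude, so at
    most two pulses fit; more is a feasibility error.
    """
    if n == 0:
        return np.array([])
    if n > MAX_PULSES_PER_STROKE:
        raise FeasibilityError(
            f"cannot place {n} secondary pulses of relative amplitude "
            f"{margins.rel_amplitude} with separation {margins.rel_separation}*D "
            f"in one stroke: only the two shoulders are usable"
        )
    if duration < MIN_PULSE_STROKE_DURATION[min(n, 2)] - 1e-9:
        raise FeasibilityError(
            f"stroke of {duration:.3f} s is too short to carry {n} detectable "
            f"secondary pulses (needs >= {MIN_PULSE_STROKE_DURATION[min(n, 2)]} s)"
        )

    # the bump must lie fully inside the stroke (a truncated tail would put
    # a step discontinuity at the boundary and drag the segmentation), and
    # low on the shoulder (away from the primary's steep mid-rise)
    half_w = 0.5 * max(margins.rel_width * duration, MIN_PULSE_WIDTH_S)
    c_lo = max(0.078 * duration, half_w + 0.004)
    c_hi = max(0.115 * duration, c_lo + 0.008)
    sides = ["left", "right"] if n == 2 else [("left", "right")[rng.integers(2)]]
    centers = []
    for side in sides:
        c = float(rng.uniform(c_lo, c_hi))
        centers.append(duration - c if side == "right" else c)
    return np.sort(np.array(centers))


def generate_stroke(duration: float, path: float, n_extra_pulses: int,
                    direction: str, margins: PulseMargins,
                    rng: np.random.Generator) -> StrokeSpec:
    """Build one stroke's analytic speed profile.

    The primary raised-cosine pulse spans [0, duration]; each secondary pulse
    has relative amplitude ``margins.rel_amplitude`` and width
    ``margins.rel_width * duration``.  The profile is scaled so the time
    integral of speed equals ``path``, making the nominal trajectory exact by
    construction.
    """
    if duration <= 0 or path <= 0:
        raise ValueError("duration and path must be positive")
    width = max(margins.rel_width * duration, MIN_PULSE_WIDTH_S)
    centers = _place_pulse_centers(duration, n_extra_pulses, margins, rng)
    # dysfluency events are zero-net-area, so only the primary carries path
    amp = path / (duration / 2.0)
    return StrokeSpec(duration=duration, path=path, direction=direction,
                      pulse_centers=centers, rel_amplitude=margins.rel_amplitude,
                      pulse_width=width, amp=amp)


_RATE_CACHE: dict[float, float] = {}


def _compensated_rate(lam: float) -> float:
    """Poisson rate lambda' such that E[min(Pois(lambda'), 2)] = lam.

    Pulse counts are capped at the two usable shoulders of a stroke, which
    would otherwise pull the mean dysfluency below its nominal 1 + lam;
    the drawing rate is raised to keep the post-cap cell mean exact.
    E[min(X, 2)] = 2 - exp(-l) * (2 + l).
    """
    if lam <= 0:
        return 0.0
    if lam >= 2.0:
        raise ValueError("capped pulse count cannot reach a mean of 2")
    cached = _RATE_CACHE.get(lam)
    if cached is None:
        cached = float(optimize.brentq(
            lambda L: 2.0 - math.exp(-L) * (2.0 + L) - lam, lam, 4 * lam + 1.0))
        _RATE_CACHE[lam] = cached
    return cached


# letter templates: per-stroke (duration, path) of the *second* letter.
# These strokes are scenery — they exist so segmentation must isolate the
# first letter — and carry no group effects.
SECOND_LETTER_STROKES = {
    "ll": [(0.195, 0.62), (0.190, 0.60)],
    "ln": [(0.170, 0.25), (0.160, 0.23), (0.170, 0.24), (0.160, 0.22)],
}
PEN_LEAD_S = 0.06   # stationary pen-up lead-in/out
PEN_DOWN_PRESSURE = 0.60


def generate_trial(group: str, bigram: str,
                   subject_dur_offset: float, subject_traj_offset: float,
                   config: GeneratorConfig, rng: np.random.Generator,
                   subject_id: str = "", trial: int = 1,
                   ) -> tuple[PenTrace, pd.DataFrame]:
    """One trial: first letter *l* (US, DS with the cell's effect structure),
    then the second letter as nominal strokes joined pen-down, with pen-up
    lead-in/out and Gaussian position jitter.  Returns the trace and its
    ground-truth stroke table."""
    specs: list[StrokeSpec] = []
    truth_rows = []
    for direction in ("US", "DS"):
        mu_d = config.duration_means[(group, direction, bigram)]
        mu_p = config.trajectory_means[(group, direction, bigram)]
        lam = config.peak_rates[(group, direction)]
        n_extra = min(int(rng.poisson(_compensated_rate(lam))), MAX_PULSES_PER_STROKE)
        if n_extra > 0:
            # dysfluent strokes must be long enough for their pulses to be
            # physically distinguishable; tighter trial spread keeps the
            # cell duration means essentially unchanged
            dur = max(MIN_PULSE_STROKE_DURATION[n_extra],
                      mu_d + subject_dur_offset
                      + rng.normal(0, TRIAL_SD_DURATION_PULSED))
        else:
            dur = max(0.05, mu_d + subject_dur_offset
                      + rng.normal(0, config.trial_sd_duration))
        pth = max(0.10, mu_p + subject_traj_offset + rng.normal(0, config.trial_sd_trajectory))
        specs.append(generate_stroke(dur, pth, n_extra, direction, config.margins, rng))
        truth_rows.append({"subject_id": subject_id, "group": group,
                           "bigram": bigram, "trial": trial, "letter": 1,
                           "stroke": len(specs) - 1, "direction": direction,
                           "nominal_duration_s": dur, "nominal_path_cm": pth,
                           "n_extra_pulses": n_extra})
    for k, (dur, pth) in enumerate(SECOND_LETTER_STROKES[bigram]):
        direction = "US" if k % 2 == 0 else "DS"
        specs.append(generate_stroke(dur, pth, 0, direction, config.margins, rng))
        truth_rows.append({"subject_id": subject_id, "group": group,
                           "bigram": bigram, "trial": trial, "letter": 2,
                           "stroke": len(specs) - 1, "direction": direction,
                           "nominal_duration_s": dur, "nominal_path_cm": pth,
                           "n_extra_pulses": 0})

    rate = config.rate_hz
    dt = 1.0 / rate
    starts = np.concatenate([[0.0], np.cumsum([s.duration for s in specs])])
    total = float(starts[-1])
    n_lead = int(round(PEN_LEAD_S * rate))
    n_down = int(math.floor(total * rate)) + 1
    t = np.arange(n_lead + n_down + n_lead) * dt
    t_down0 = n_lead * dt

    vx = np.zeros_like(t)
    vy = np.zeros_like(t)
    p = np.zeros_like(t)
    theta = math.radians(SLANT_DEG)
    for k, spec in enumerate(specs):
        tau = t - t_down0 - starts[k]
        mask = (tau >= 0) & (tau < spec.duration)
        sp = spec.speed_at(tau[mask])
        sign = 1.0 if spec.direction == "US" else -1.0
        vx[mask] = sp * math.sin(theta)
        vy[mask] = sign * sp * math.cos(theta)
    down = (t >= t_down0) & (t <= t_down0 + total)
    p[down] = PEN_DOWN_PRESSURE

    x = 1.0 + np.cumsum(vx) * dt
    y = 4.0 + np.cumsum(vy) * dt
    if config.position_jitter_sd > 0:
        x = x + rng.normal(0, config.position_jitter_sd, x.size)
        y = y + rng.normal(0, config.position_jitter_sd, y.size)

    trace = PenTrace(t=t, x=x, y=y, p=p, subject_id=subject_id, group=group,
                     bigram=bigram, trial=trial, nominal_rate=rate)
    return trace, pd.DataFrame(truth_rows)


@dataclass
class CohortStudy:
    """In-memory synthetic cohort: manifest rows, traces, ground truth,
    clinical covariates."""

    manifest: CohortManifest
    traces: list[PenTrace]
    ground_truth: pd.DataFrame
    covariates: pd.DataFrame
    config: GeneratorConfig


def _matched_truncnorm(mean: float, sd: float, lower: float):
    """Frozen truncated normal whose *post-truncation* mean equals ``mean``
    (scale fixed at ``sd``, support [lower, inf))."""

    def trunc_mean(loc: float) -> float:
        a = (lower - loc) / sd
        return float(sps.truncnorm.mean(a, np.inf, loc=loc, scale=sd))

    if trunc_mean(mean) - mean < 1e-9:
        loc = mean
    else:
        loc = optimize.brentq(lambda L: trunc_mean(L) - mean,
                              mean - 12 * sd, mean + sd)
    a = (lower - loc) / sd
    return sps.truncnorm(a, np.inf, loc=loc, scale=sd)


def generate_clinical(config: GeneratorConfig, subject_ids: list[str],
                      trajectory_means: np.ndarray,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates for the patient group.

    Each variable is a truncated normal reproducing the published mean at
    the published SD above its scale minimum.  The dominant-hand Purdue
    score is coupled to each subject's mean stroke trajectory through a
    Gaussian copula at Spearman rho = -0.5 (worse dexterity <-> longer,
    larger strokes); the remaining variables are independent.
    """
    if len(subject_ids) == 0:
        raise ValueError("clinical covariates require patient subjects")
    n = len(subject_ids)
    out = {"subject_id": list(subject_ids)}
    for name, (mean, sd, lower) in CLINICAL_MARGINS.items():
        if name == "purdue_dom":
            continue
        dist = _matched_truncnorm(mean, sd, lower)
        out[name] = dist.ppf(rng.uniform(size=n))

    # Gaussian copula: Pearson correlation on the latent normals chosen so
    # the rank correlation is the target Spearman rho.
    rho_s = PURDUE_TRAJECTORY_RHO
    rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
    ranks = sps.rankdata(trajectory_means)
    z1 = sps.norm.ppf((ranks - 0.5) / n)
    z2 = rho_p * z1 + math.sqrt(1 - rho_p ** 2) * rng.normal(size=n)
    mean, sd, lower = CLINICAL_MARGINS["purdue_dom"]
    dist = _matched_truncnorm(mean, sd, lower)
    out["purdue_dom"] = dist.ppf(sps.norm.cdf(z2))
    cols = ["subject_id"] + list(CLINICAL_MARGINS)
    return pd.DataFrame(out)[cols]


def generate_cohort(config: GeneratorConfig, out_dir=None) -> CohortStudy:
    """Generate the full cohort; fully reproducible from ``config.seed``.

    If ``out_dir`` is given, trace CSVs, the manifest, the ground-truth table
    and the covariates table are also written there.
    """
    traces: list[PenTrace] = []
    manifest_rows = []
    truth_frames = []
    subj_traj_offsets: dict[str, float] = {}
    # Independent child streams per subject and per trial: every trial is
    # reproducible on its own, regardless of cohort composition or ordering.
    for gi, (group, prefix) in enumerate(zip(GROUPS, ("ctl", "scz"))):
        for s in range(config.n_subjects_per_group):
            sid = f"{prefix}{s + 1:02d}"
            srng = np.random.default_rng([config.seed, gi, s])
            off_dur = srng.normal(0, config.subject_sd_duration)
            off_traj = srng.normal(0, config.subject_sd_trajectory)
            subj_traj_offsets[sid] = off_traj
            for bi, bigram in enumerate(BIGRAMS):
                for tr in range(1, config.trials_per_bigram + 1):
                    trng = np.random.default_rng([config.seed, gi, s, bi, tr])
                    trace, truth = generate_trial(
                        group, bigram, off_dur, off_traj, config, trng,
                        subject_id=sid, trial=tr)
                    traces.append(trace)
                    truth_frames.append(truth)
                    manifest_rows.append({
                        "subject_id": sid, "group": group, "bigram": bigram,
                        "trial": tr, "path": f"traces/{sid}_{bigram}_{tr:02d}.csv",
                    })
    ground_truth = pd.concat(truth_frames, ignore_index=True)

    scz_ids = sorted({r["subject_id"] for r in manifest_rows if r["group"] == "SCZ"})
    first = ground_truth[ground_truth["letter"] == 1]
    traj_means = (first[first["subject_id"].isin(scz_ids)]
                  .groupby("subject_id")["nominal_path_cm"].mean()
                  .reindex(scz_ids).to_numpy())
    covariates = generate_clinical(config, scz_ids, traj_means,
                                   np.random.default_rng([config.seed, 10 ** 6]))

    manifest = CohortManifest(trials=pd.DataFrame(manifest_rows), covariates=covariates)
    study = CohortStudy(manifest=manifest, traces=traces,
                        ground_truth=ground_truth, covariates=covariates,
                        config=config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "traces").mkdir(parents=True, exist_ok=True)
        for trace, row in zip(traces, manifest_rows):
            write_trace(trace, out_dir / row["path"])
        write_manifest(manifest, out_dir / "manifest.csv")
        ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
        covariates.to_csv(out_dir / "covariates.csv", index=False)
    return study
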