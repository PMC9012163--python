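"""First-letter stroke features and the subject-level cell table.

Both bigrams (*ll*, *ln*) begin with a cursive *l*, and motor anticipation is
operationalised on that first letter only: its upstroke (US) and downstroke
(DS) are the first two strokes of the first pen-down run.  Each trial yields
duration, trajectory, and dysfluency for those two strokes; trials are then
averaged within subject x direction x bigram cells, which is the unit the
random-intercept mixed model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PenTrace
from .kinematics import (
    SegmentationParams,
    count_velocity_peaks,
    dysfluency_speed,
    resample_uniform,
    segment_strokes,
    smooth_trace,
    velocity_profile,
)

MEASURES = ("duration_s", "trajectory_cm", "n_peaks")


@dataclass
class StrokeFeatures:
    duration_s: float
    trajectory_cm: float
    n_peaks: int


@dataclass
class TrialFeatures:
    """Per-trial kinematics of the first letter's US and DS.

    When a qc flag is present the corresponding stroke features are absent
    (None) and the trial is excluded from aggregation rather than imputed.
    """

    subject_id: str
    group: str
    bigram: str
    trial: int
    us: StrokeFeatures | None = None
    ds: StrokeFeatures | None = None
    qc_flags: set = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return not self.qc_flags


def extract_first_letter_features(
    trace: PenTrace, params: SegmentationParams | None = None
) -> TrialFeatures:
    """Run resample -> smooth -> velocity -> segment on one trial and measure
    the first letter's strokes.

    The first letter's US is stroke 0 of the first pen-down run and its DS is
    stroke 1.  Dysfluency is counted on speed from the wider dysfluency band
    (see :mod:`penkin.kinematics`), over the spans found by the segmentation
    band.  QC flags: ``too_few_strokes`` (fewer than 2 strokes in the first
    run), ``first_stroke_not_US``.
    """
    params = params or SegmentationParams()
    uniform = resample_uniform(trace, params.resample_rate)
    smooth = smooth_trace(uniform, params.lowpass_cutoff)
    profile = velocity_profile(smooth)

    # Path length is read off a mid-band smoothing of the positions: the
    # segmentation band's zero-phase filter rings at stroke reversals and
    # inflates arc length, while raw positions inflate it with jitter.  The
    # same band also refines stroke boundaries, whose coarse-band location
    # can be dragged by velocity events near a reversal.
    traj = smooth_trace(uniform, params.trajectory_cutoff)
    wide = smooth_trace(uniform, params.dysfluency_cutoff)
    strokes = segment_strokes(profile, smooth, params,
                              refine_vy=velocity_profile(wide).vy)
    wide_speed = dysfluency_speed(uniform, params)

    out = TrialFeatures(
        subject_id=trace.subject_id, group=trace.group,
        bigram=trace.bigram, trial=trace.trial,
    )
    # Strokes of the first pen-down run only.
    run0 = []
    for s in strokes:
        if run0 and s.start != run0[-1].end:
            break
        run0.append(s)
    if len(run0) < 2:
        out.qc_flags.add("too_few_strokes")
    if run0 and run0[0].direction != "US":
        out.qc_flags.add("first_stroke_not_US")
    if out.qc_flags:
        return out

    def _measure(stroke) -> StrokeFeatures:
        xs = traj.x[stroke.start:stroke.end]
        ys = traj.y[stroke.start:stroke.end]
        return StrokeFeatures(
            duration_s=stroke.duration_s,
            trajectory_cm=float(np.sum(np.hypot(np.diff(xs), np.diff(ys)))),
            n_peaks=count_velocity_peaks(
                wide_speed[stroke.start:stroke.end], params, params.resample_rate
            ),
        )

    out.us = _measure(run0[0])
    out.ds = _measure(run0[1])
    return out


def trial_features_frame(trials: list[TrialFeatures]) -> pd.DataFrame:
    """Long-format frame: one row per trial x direction (flagged trials keep
    their flags and carry NaN measures)."""
    rows = []
    for tf in trials:
        for direction, sf in (("US", tf.us), ("DS", tf.ds)):
            rows.append({
                "subject_id": tf.subject_id, "group": tf.group,
                "bigram": tf.bigram, "trial": tf.trial, "direction": direction,
                "duration_s": sf.duration_s if sf else np.nan,
                "trajectory_cm": sf.trajectory_cm if sf else np.nan,
                "n_peaks": sf.n_peaks if sf else np.nan,
                "qc_flags": ";".join(sorted(tf.qc_flags)),
            })
    return pd.DataFrame(rows)


def aggregate_subject_cells(
    trials: list[TrialFeatures],
) -> tuple[pd.DataFrame, list[dict]]:
    """Average unflagged trials into subject x direction x bigram cells.

    Returns the cell table (one row per subject-direction-bigram, with
    ``n_trials`` recording how many trials contributed) and a dropped-cells
    log listing any (subject, bigram) cell whose trials were all flagged.
    """
    frame = trial_features_frame(trials)
    ok = frame[frame["qc_flags"] == ""]
    dropped: list[dict] = []
    all_cells = frame[["subject_id", "group", "bigram"]].drop_duplicates()
    ok_cells = set(map(tuple, ok[["subject_id", "bigram"]].drop_duplicates().to_numpy()))
    for _, row in all_cells.iterrows():
        if (row["subject_id"], row["bigram"]) not in ok_cells:
            n_flagged = int(((frame["subject_id"] == row["subject_id"])
                             & (frame["bigram"] == row["bigram"])).sum()) // 2
            dropped.append({"subject_id": row["subject_id"],
                            "bigram": row["bigram"],
                            "n_flagged_trials": n_flagged})
    cells = (
        ok.groupby(["subject_id", "group", "direction", "bigram"], as_index=False)
        .agg(duration_s=("duration_s", "mean"),
             trajectory_cm=("trajectory_cm", "mean"),
             n_peaks=("n_peaks", "mean"),
             n_trials=("trial", "size"))
    )
    return cells, dropped


def subject_kinematics(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean of each kinematic measure across the four cells —
    the handwriting side of the clinical correlation analysis."""
    return (
        cells.groupby(["subject_id", "group"], as_index=False)
        [["duration_s", "trajectory_cm", "n_peaks"]].mean()
        .rename(columns={"duration_s": "mean_duration_s",
                         "trajectory_cm": "mean_trajectory_cm",
                         "n_peaks": "mean_n_peaks"})
    )
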