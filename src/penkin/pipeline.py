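"""End-to-end orchestration: simulate -> extract -> analyze -> report.

Everything here is thin plumbing over the library modules; the numbered
scripts under ``analysis/`` and the ``penkin`` CLI both go through
:func:`run_pipeline`.  Outputs are plain CSV and text; every table carries a
header comment with the configuration hash and seed so a run can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from . import io as pio
from . import simulate as sim
from . import stats as st
from .kinematics import SegmentationParams

log = logging.getLogger("penkin")

MEASURES = ("duration_s", "trajectory_cm", "n_peaks")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (unknown keys are rejected)."""

    results_dir: str = "results/run"
    manifest: str | None = None          # analyse recorded data ...
    covariates: str | None = None
    simulate: bool = True                # ... or a synthetic cohort
    seed: int = 0
    generator: dict = field(default_factory=dict)      # GeneratorConfig overrides
    segmentation: dict = field(default_factory=dict)   # SegmentationParams overrides
    measures: tuple = MEASURES
    make_plots: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# penkin config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def segmentation_params(cfg: RunConfig) -> SegmentationParams:
    return SegmentationParams(**cfg.segmentation)


def generator_config(cfg: RunConfig) -> sim.GeneratorConfig:
    return sim.GeneratorConfig(seed=cfg.seed, **cfg.generator)


def load_trials(cfg: RunConfig) -> tuple[list[pio.PenTrace], pd.DataFrame | None]:
    """Trial traces plus covariates, from the generator or from a manifest."""
    if cfg.simulate:
        study = sim.generate_cohort(generator_config(cfg))
        return study.traces, study.covariates
    if cfg.manifest is None:
        raise FileNotFoundError("config names no manifest and simulate is off")
    manifest = pio.read_manifest(cfg.manifest, covariates_path=cfg.covariates)
    traces = []
    for _, row in manifest.trials.iterrows():
        tr = pio.read_trace(row["path"])
        tr.subject_id, tr.group = row["subject_id"], row["group"]
        tr.bigram, tr.trial = row["bigram"], int(row["trial"])
        traces.append(tr)
    return traces, manifest.covariates


def extract_cohort(traces: list[pio.PenTrace], params: SegmentationParams,
                   ) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Extract per-trial features and the subject cell table for a cohort."""
    trials = [ft.extract_first_letter_features(t, params) for t in traces]
    n_flagged = sum(1 for t in trials if not t.ok)
    if n_flagged:
        log.info("extract: %d/%d trials flagged", n_flagged, len(trials))
    frame = ft.trial_features_frame(trials)
    cells, dropped = ft.aggregate_subject_cells(trials)
    for d in dropped:
        log.warning("dropped cell: %s", d)
    return frame, cells, dropped


def analyze_cells(cells: pd.DataFrame, covariates: pd.DataFrame | None = None,
                  measures=MEASURES) -> dict:
    """Fit the mixed model per measure; Type-III tests, contrasts, and the
    clinical Spearman matrix (patient group) if covariates are present."""
    out: dict = {"anova": {}, "contrasts": {}, "fits": {}}
    for m in measures:
        fit = st.fit_random_intercept_lmm(cells, m)
        out["fits"][m] = fit
        out["anova"][m] = st.effect_tests_frame(st.type3_f_tests(fit))
        out["contrasts"][m] = st.contrasts_frame(st.pairwise_contrasts(fit))
    if covariates is not None and len(covariates) >= 4:
        subj = ft.subject_kinematics(cells)
        table = covariates.merge(subj, on="subject_id", how="inner")
        out["spearman"] = st.spearman_matrix(
            table, [c for c in table.columns
                    if c not in ("subject_id", "group")])
    return out


def _descriptives(cells: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for m in MEASURES:
        for factor in ("group", "direction", "bigram"):
            for level, sub in cells.groupby(factor):
                rows.append({"measure": m, "margin": f"{factor}={level}",
                             "mean": sub[m].mean(), "sd": sub[m].std()})
    return pd.DataFrame(rows)


def _plot_cell_means(cells: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = {"duration_s": "Duration (s)", "trajectory_cm": "Trajectory (cm)",
              "n_peaks": "Dysfluency (velocity peaks)"}
    for m in MEASURES:
        fig, axes = plt.subplots(1, 2, figsize=(7, 3), sharey=True)
        for ax, grp in zip(axes, ("CTRL", "SCZ")):
            sub = cells[cells["group"] == grp]
            agg = sub.groupby(["direction", "bigram"])[m].agg(["mean", "sem"]).reset_index()
            for b, off in (("ll", -0.05), ("ln", 0.05)):
                rows = agg[agg["bigram"] == b].set_index("direction").reindex(["US", "DS"])
                xpos = np.arange(2) + off
                ax.errorbar(xpos, rows["mean"], yerr=rows["sem"], marker="o",
                            capsize=3, label=b)
            ax.set_xticks([0, 1], ["US", "DS"])
            ax.set_title(grp)
        axes[0].set_ylabel(labels[m])
        axes[1].legend(title="bigram")
        fig.tight_layout()
        fig.savefig(out_dir / f"cellmeans_{m}.png", dpi=120)
        plt.close(fig)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full analysis and write all tables under ``cfg.results_dir``.

    Raises on any stage error; plot generation alone is best-effort and never
    gates success.
    """
    out_dir = Path(cfg.results_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = segmentation_params(cfg)
    log.info("run: config_hash=%s seed=%d params=%s", cfg.config_hash(), cfg.seed, params)

    traces, covariates = load_trials(cfg)
    frame, cells, dropped = extract_cohort(traces, params)
    _write_table(frame, out_dir / "features.csv", cfg)
    _write_table(cells, out_dir / "cells.csv", cfg)
    _write_table(pd.DataFrame(dropped, columns=["subject_id", "bigram", "n_flagged_trials"]),
                 out_dir / "dropped_cells.csv", cfg)
    _write_table(_descriptives(cells), out_dir / "descriptives.csv", cfg)

    res = analyze_cells(cells, covariates, cfg.measures)
    report = [f"penkin run  config_hash={cfg.config_hash()}  seed={cfg.seed}",
              f"trials={len(traces)}  subjects={cells['subject_id'].nunique()}", ""]
    for m in cfg.measures:
        _write_table(res["anova"][m], out_dir / f"anova_{m}.csv", cfg)
        _write_table(res["contrasts"][m], out_dir / f"contrasts_{m}.csv", cfg)
        report.append(f"== {m} ==")
        for _, r in res["anova"][m].iterrows():
            report.append(
                f"  {r['term']:>24s}  F(1, {r['df2']:.1f}) = {r['F']:6.2f}"
                f"  p = {r['p']:.4f}  eta_p2 = {r['eta_p2']:.3f}")
        for _, r in res["contrasts"][m].iterrows():
            report.append(
                f"  {r['group']}-{r['direction']} ll-ln: est = {r['estimate']:+.4f}"
                f"  t({r['df']:.1f}) = {r['t']:+.2f}  p = {r['p_unadjusted']:.4f}"
                f"  p_holm = {r['p_holm']:.4f}")
        report.append("")
    if "spearman" in res:
        res["spearman"].rho.to_csv(out_dir / "spearman_rho.csv")
        res["spearman"].p.to_csv(out_dir / "spearman_p.csv")
        rho_pt = res["spearman"].rho.loc["purdue_dom", "mean_trajectory_cm"]
        report.append(f"Spearman(purdue_dom, mean trajectory) = {rho_pt:.3f}")
    (out_dir / "report.txt").write_text("\n".join(report) + "\n")

    if cfg.make_plots:
        try:
            _plot_cell_means(cells, out_dir)
        except Exception as exc:  # noqa: BLE001 - plots never gate success
            log.warning("plotting failed (non-fatal): %s", exc)
    return out_dir
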