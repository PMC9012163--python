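#!/usr/bin/env python
"""Clinical correlations in the patient group.

Spearman matrix between the clinical covariates (PANSS subscales, SAS,
chlorpromazine-equivalent dose, illness duration, education, Purdue
Pegboard subscores) and the per-subject mean kinematic measures.  The one
association the study design plants is dexterity vs stroke size: worse
dominant-hand Purdue performance goes with longer stroke trajectories.
"""

import argparse
from pathlib import Path

import pandas as pd

from penkin.features import subject_kinematics
from penkin.stats import spearman_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cells", type=Path, default=Path("results/analysis/cells.csv"))
    ap.add_argument("--covariates", type=Path,
                    default=Path("results/analysis/cohort/covariates.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cells = pd.read_csv(args.cells, comment="#")
    cov = pd.read_csv(args.covariates, comment="#")
    subj = subject_kinematics(cells)
    table = cov.merge(subj, on="subject_id", how="inner")
    m = spearman_matrix(table, [c for c in table.columns
                                if c not in ("subject_id", "group")])
    args.out.mkdir(parents=True, exist_ok=True)
    m.rho.to_csv(args.out / "spearman_rho.csv")
    m.p.to_csv(args.out / "spearman_p.csv")

    print(f"Spearman matrix over {len(table)} patients "
          f"({len(m.variables)} variables) -> {args.out}")
    kin = ["mean_duration_s", "mean_trajectory_cm", "mean_n_peaks"]
    print("\nclinical vs kinematic correlations (rho, p):")
    for clin in [v for v in m.variables if v not in kin]:
        row = "  ".join(f"{m.rho.loc[clin, k]:+.2f} ({m.p.loc[clin, k]:.2f})"
                        for k in kin)
        print(f"  {clin:>16s}: {row}")


if __name__ == "__main__":
    main()
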