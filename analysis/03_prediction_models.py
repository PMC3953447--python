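#!/usr/bin/env python
"""Stage 3 — how well does anthropometry predict each MRI compartment?

Fits, per sex, each compartment volume on BMI + WC + HC (all residual-adjusted
for age and height): model R², per-predictor type-II partial correlations with
95% CIs, and VIFs.  Writes a figure-style model CSV and prints the R² ladder —
aggregate compartments (TBV, TAT, SAT) are well predicted, the internal
compartments (VAT, CAT) and muscle much less so.
"""

import argparse
from pathlib import Path

import pandas as pd

from bodycomp import adjust, regmodel, synth_cohort as sc, tables
from bodycomp.corrstats import round_half_up

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = sc.read_cohort_csv(args.out / "cohort.csv")
cols = [tables.COLUMN_FOR_LABEL[v] for v in tables.CORR_LABELS]
adjusted = adjust.residual_adjust(cohort, cols)

rows = []
for sex, am in adjusted.items():
    am.data.columns = tables.CORR_LABELS
    am.labels = list(tables.CORR_LABELS)
    print(f"\n{sex} (n={am.n}):  outcome  R2%  best predictor (partial r)")
    for outcome in tables.OUTCOMES:
        fit = regmodel.fit_model(am, outcome, tables.PREDICTORS)
        best = max(fit.partials, key=lambda p: abs(p.r))
        print(f"  {outcome:>4}: {round_half_up(100 * fit.r2):>3.0f}%   "
              f"{best.predictor} ({best.r:+.2f} [{best.ci_low:+.2f}, {best.ci_high:+.2f}])")
        row = {"sex": sex, "outcome": outcome, "n": fit.n, "r2": round(fit.r2, 4),
               "r2_pct": round_half_up(100 * fit.r2)}
        for p in fit.partials:
            row[f"partial_{p.predictor}"] = round_half_up(p.r, 2)
            row[f"partial_{p.predictor}_ci"] = (
                f"{round_half_up(p.ci_low, 2):.2f}-{round_half_up(p.ci_high, 2):.2f}")
            row[f"vif_{p.predictor}"] = round(p.vif, 2)
        rows.append(row)

pd.DataFrame(rows).to_csv(args.out / "models.csv", index=False)
print(f"\nwrote {args.out/'models.csv'}")
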