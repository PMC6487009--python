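#!/usr/bin/env python
"""Run the statistics layer over the simulated cohort.

Reads results/cohort.csv (run 02_simulate_cohort.py first) and writes
the univariate Mann-Whitney table, the multivariable logistic fits, the
ROC coordinates for the low-is-risk markers (MA, DPD) and the 3 mm duct
stratification into results/.
"""

from pathlib import Path

import pandas as pd

from ctbodycomp.config import default_config
from ctbodycomp.pipeline import cmd_report

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main():
    cohort = OUT / "cohort.csv"
    if not cohort.exists():
        raise SystemExit("run analysis/02_simulate_cohort.py first")
    paths = cmd_report(default_config(), cohort, OUT, make_plot=True)
    logi = pd.read_csv(paths["logistic"], comment="#")
    print("multivariable logistic fits (severe POPF / major complications):")
    print(logi[logi.predictor != "intercept"]
          [["endpoint", "predictor", "or", "ci_low", "ci_high", "p"]]
          .round(3).to_string(index=False))
    roc = pd.read_csv(paths["roc"], comment="#")
    print("\nAUCs:")
    print(roc.groupby(["endpoint", "marker"])["auc"].first().round(3).to_string())
    strat = pd.read_csv(paths["duct_2x2"], comment="#")
    print("\nduct stratification at 3 mm:")
    print(strat.to_string(index=False))


if __name__ == "__main__":
    main()
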