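#!/usr/bin/env python
"""Stage 3 — the statistical stage on the simulated results table.

Reads results/results_table.csv (from 02_simulate_study.py), computes the
descriptive table, the Pearson correlation screen (p < 0.05, uncorrected),
and the three backward-elimination regressions predicting CO, SEP, and SRM
from {Age, PTA, TGap, DioFM, DichFM, TM, SM, STM}; writes the three table
analogues plus a text report to results/.
"""

from pathlib import Path

import pandas as pd

from audbattery.analysis_stats import analysis_report

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    results_path = OUT / "results_table.csv"
    if not results_path.exists():
        raise SystemExit("run analysis/02_simulate_study.py first")
    frame = pd.read_csv(results_path)
    report = analysis_report(frame, p_remove=0.10)
    paths = report.to_csv(OUT)
    print("wrote", ", ".join(str(p) for p in paths.values()))

    print("\nFinal regression models:")
    print(report.model_table().to_string(index=False))
    sep = report.models["SEP"]
    if not sep.no_model:
        print(f"\nSEP model retains: {', '.join(sep.predictors)} "
              f"(adjusted R^2 = {sep.adjusted_r2:.3f}, error = {sep.error_db:.2f} dB)")
    n_screen = len(report.correlations)
    print(f"correlation screen: {n_screen} pairs with p < 0.05 out of 55 evaluated")


if __name__ == "__main__":
    main()
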