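#!/usr/bin/env python
"""Stage 4 — operating characteristics of the backward-elimination stage.

Replicates the planted-cohort experiment many times (default 200 cohorts of
n = 41) and measures, against ground truth:

* how often backward elimination (p_remove = 0.10) retains both true
  predictors {Age, DioFM} of the separated-speech threshold;
* how often the predictor-independent colocated threshold ends with
  "no model" (all predictors eliminated or adjusted R^2 <= 0);
* the distribution of the final adjusted R^2 for the separated model.

This quantifies the statistical power of a stepwise analysis at this sample
size: with effect sizes calibrated to an adjusted R^2 near 0.29, joint
retention of both true predictors is far from guaranteed, and spurious
predictors survive the null outcome in roughly half of replicates.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from audbattery import analysis_stats as an
from audbattery import virtual_listener as vl

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--reps", type=int, default=200)
    parser.add_argument("--seed", type=int, default=2022)
    args = parser.parse_args()

    config = vl.CohortConfig(n=41)
    rows = []
    for rep in range(args.reps):
        frame = vl.cohort_frame(vl.generate_cohort(config, seed=args.seed * 100_000 + rep))
        X = frame[["Age", "PTA"]].join(
            frame[[f"{t}_true" for t in vl.TASKS]].rename(
                columns=lambda c: c.removesuffix("_true")
            )
        )
        sep = an.backward_eliminate(frame["SEP_true"], X, outcome="SEP")
        co = an.backward_eliminate(frame["CO_true"], X, outcome="CO")
        rows.append({
            "rep": rep,
            "sep_predictors": " ".join(sep.predictors),
            "sep_keeps_age_and_diofm": int({"Age", "DioFM"} <= set(sep.predictors)),
            "sep_adj_r2": sep.adjusted_r2 if not sep.no_model else np.nan,
            "co_no_model": int(co.no_model),
        })

    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    path = OUT / "backward_recovery.csv"
    frame.to_csv(path, index=False)
    print(f"wrote {path} ({args.reps} replicate cohorts of n = 41)")

    keep = frame.sep_keeps_age_and_diofm.mean()
    no_model = frame.co_no_model.mean()
    med = frame.sep_adj_r2.median()
    print(f"\nSEP: Age and DioFM jointly retained in {keep:.1%} of replicates")
    print(f"SEP: median final adjusted R^2 = {med:.3f} "
          "(selection inflates the planted ~0.26)")
    print(f"CO:  'no model' in {no_model:.1%} of replicates "
          "(a spurious model survives otherwise)")


if __name__ == "__main__":
    main()
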