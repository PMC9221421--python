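# audbattery

Older adults often struggle to understand speech in competition even when
their audiograms are near normal, and "suprathreshold" auditory abilities —
detecting frequency modulation, brief temporal gaps, or spectrotemporal
ripples in noise — are candidate explanations. `audbattery` is a simulation
of a portable psychoacoustic battery built to study that question: it
synthesizes the battery's calibrated stimuli, runs adaptive and progressive
tracking procedures against simulated listeners, generates virtual cohorts
with planted statistical structure, and reproduces the correlation /
backward-regression analysis stage. It is intended for psychoacousticians
and methodologists who want to study the *measurement properties* of such a
battery — staircase precision, scoring bias, and above all the behavior of
stepwise regression at realistic sample sizes — without human participants.

## The battery

Six detection tasks, each a four-interval two-cue two-alternative forced
choice (intervals 1 and 4 hold the standard; the target hides in 2 or 3)
tracked 2-down-1-up on a log scale, converging on the 70.7%-correct point:

| Task | Target | Threshold units |
|------|--------|-----------------|
| DioFM / DichFM | 2-Hz phase modulation of a 460–550 Hz tone, same / antiphase across ears | log2(Hz) peak deviation |
| TGap | silent gap between two 4-ms 500-Hz bursts | log2(ms) |
| TM / SM / STM | 4-Hz envelope / 2-cyc-per-octave spectral ripple / drifting ripple on broadband noise | dB depth |

Speech-in-competition uses a closed-set coordinate-response task (target
callsign CHARLIE; 4 colors × 8 numbers, guess rate 1/32) with two masker
talkers either colocated (CO) or at ±45° (SEP), measured by progressive
tracking: TMR descends 10 → −10 dB in 2-dB steps, two trials per step, and
the threshold is `10 − #correct` dB, estimating the 50% point. Spatial
release from masking is `SRM = CO − SEP`. Virtual listeners respond through
logistic psychometric functions p(x) = γ + (1−γ−λ)F((x−α)/β + c) anchored
so the planted α is exactly what each procedure estimates; cohorts carry a
planted linear model `SEP = β₀ + β_age·Age + β_FM·DioFM + ε` whose effect
sizes are calibrated to an adjusted R² near 0.29 at n = 41, with CO
independent of all predictors. The analysis stage screens all pairwise
Pearson correlations and fits backward-elimination regressions (partial-t
removal at p > 0.10) for CO, SEP and SRM.

See `docs/methods.md` for models, defaults, and known estimator biases.

## Worked example

```python
from audbattery import virtual_listener as vl
from audbattery.analysis_stats import analysis_report

cohort = vl.generate_cohort(vl.CohortConfig(n=41), seed=16)
results = vl.run_study(cohort, seed=16)
report = analysis_report(results, p_remove=0.10)
print(report.model_table().to_string(index=False))
```

prints

```
Condition Predictors Adjusted R^2      p Error (dB)
       CO          -            -      -          -
      SEP Age, DioFM        0.321    0.0       2.83
      SRM      DioFM        0.202  0.002       3.28
```

— one replicate cohort: the colocated model is empty (every predictor was
eliminated), the separated model retains Age and diotic FM with adjusted
R² 0.32 and ~2.8 dB residual error, and the SRM model keeps diotic FM.
Other seeds give very different final models — stepwise selection at
n = 41 is noisy, and `analysis/04_recovery_experiment.py` quantifies
exactly how noisy.

The same pipeline is scripted as a four-stage analysis under `analysis/`
(each writes its tables to `results/`):

```
python analysis/01_verify_stimuli.py       # stimulus QC round-trips
python analysis/02_simulate_study.py       # 41-listener battery run
python analysis/03_statistical_analysis.py # descriptives, screen, models
python analysis/04_recovery_experiment.py  # stepwise-selection power
```

A `click` CLI wraps the same operations (`audbattery synth`,
`verify-stimuli`, `simulate-study`, `analyze`), writing WAV stimuli, QC
reports, CSV tables and a reproducibility manifest.

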