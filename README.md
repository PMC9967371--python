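# plvconnect

Phase-locking-value (PLV) EEG functional connectivity analysis for
two-group, two-condition study designs — built for the comparison of
Parkinson's disease (PD) patients against healthy controls (HC) at rest
and during a motor task, and usable for any cohort with the same
factorial structure.

The package covers the full chain:

1. **Synthetic cohort generation** — multichannel EEG with
   band-specific inter-channel phase coupling whose population PLV is
   known in closed form, so every estimator downstream has an exact
   oracle (no external data needed to validate the pipeline).
2. **Preprocessing** — DC removal, 60 Hz notch, 1–70 Hz zero-phase
   linear-phase FIR band-pass, average re-reference, artifact-screened
   epoch selection.
3. **Connectivity** — PLV for all channel pairs per frequency band
   (delta 2–4, theta 5–7, alpha 8–12, beta 13–29, gamma 30–60 Hz),
   reduced to a global (mean over pairs) connectivity per
   recording × band.
4. **Inference** — three-way aligned-rank-transform (ART) factorial
   ANOVA (Frequency × Group × Condition) with Bonferroni-corrected
   rank-sum post-hocs, plus Kolmogorov–Smirnov normality screening and
   Spearman correlation.
5. **Discrimination** — empirical ROC on a single connectivity feature,
   operating point maximizing PPV + NPV, confusion-matrix metrics, and
   95% CIs from stratified bootstrap resampling.

## The statistics in brief

For phases φ_a, φ_b of two band-filtered channels (Hilbert analytic
signal), the phase locking value is

    PLV = | (1/N) Σ_t exp(i(φ_a(t) − φ_b(t))) |  ∈ [0, 1].

Synthetic coupling uses phase offsets with mean resultant
I₁(κ)/I₀(κ) — the von Mises concentration-to-PLV map — making sample
PLV testable against a Bessel-function oracle. The ART ANOVA aligns the
data per effect (subtracting all other effects' least-squares
estimates), ranks, and runs a standard factorial ANOVA on the ranks;
on aligned data every non-target effect has F ≈ 0, which the package
reports as a diagnostic. The ROC's trapezoidal AUC equals the
Mann–Whitney probability P(score_pos > score_neg) + ½P(tie) exactly.

See `docs/methods.md` for models, parameter defaults and numerical
decisions, and `examples/` for runnable walk-throughs of each stage.

## Worked example

```python
from plvconnect import PipelineConfig, SimConfig, run_pipeline, summarize

config = PipelineConfig(
    sim=SimConfig.test_scale(master_seed=11),  # 26 PD + 13 HC, 8 ch, 60 s
    epoch_seconds=55.0,
    n_boot=1_000,
)
print(summarize(run_pipeline(config)))
```

prints (abridged):

```
cohort: 26 PD + 13 HC, 8 channels, 55 s epochs (390 connectivity rows)

ART ANOVA (F, df, p):
  band                      F(4,370) = 63.70, p = 6.164e-41 *
  ...
significant post-hoc contrasts (Bonferroni-adjusted):
  group: HC vs PD (band=delta, condition=motor): p_adj = 1.231e-09 (raw 2.462e-10, family 5)
  condition: motor vs rest (band=delta, group=HC): p_adj = 3.846e-07 (raw 1.923e-07, family 2)

ROC (delta band, motor task, positive=HC):
  AUC = 1.000 (95% CI 1.00-1.00), cutoff = 0.6353
  sensitivity   100.0% (95% CI 100-100%)
  ...
```

The generator plants exactly one elevated coupling cell —
(HC, motor task, delta band) — and the pipeline recovers it: the only
significant group contrast is delta-band during the motor task, the
only significant condition contrast is within HC, and that single
feature separates the groups. Every denominator df is 370
(390 observations − 20 cells), the identity that pins the factorial
design.

The same stages are available as a CLI for store-on-disk workflows:

```sh
plvconnect simulate --config config.yaml --out raw/
plvconnect preprocess --in raw/ --out clean/ --epoch-seconds 55
plvconnect connectivity --in clean/ --out table.csv
plvconnect stats --table table.csv --out stats.json
plvconnect roc --table table.csv --band delta --condition motor --out roc.json
plvconnect run --config config.yaml --out results/   # everything at once
```

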