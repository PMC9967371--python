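# Methods

`plvconnect` implements a complete EEG functional-connectivity analysis
— phase locking value (PLV) over all channel pairs in five frequency
bands, compared across two groups (Parkinson's disease, PD, vs healthy
controls, HC) and two conditions (rest vs motor task) with an
aligned-rank-transform (ART) factorial ANOVA and a ROC discrimination
analysis — together with a synthetic coupled-oscillator EEG generator
that gives every estimator in the chain a closed-form oracle. This note
records the model, the parameter choices, and the numerical decisions.

## Phase locking value

For two signals with instantaneous phases φ_a(t), φ_b(t) over N
samples,

    PLV = | (1/N) Σ_t exp(i (φ_a(t) − φ_b(t))) |,

the mean resultant length of the phase difference: 1 under perfect
phase locking, near 0 for independent phases. Phases are extracted as
the angle of the Hilbert analytic signal of the band-filtered channel —
the standard realization of PLV for narrowband EEG; wavelet phase is a
known alternative and was not used. PLV is computed over the single
continuous analysis epoch as one window (no sub-window averaging).
*Global connectivity* for one recording × band is the mean PLV over all
n(n−1)/2 unordered channel pairs (diagonal excluded).

Edge handling: band filtering and the Hilbert transform are both
non-local, so `max(filter length, 1 s × fs)` samples are trimmed from
each end of the phase series before PLV.

The PLV estimator is positively biased at finite N: for N independent
uniform phasors E[PLV] ≈ √π/(2√N) (≈ 0.003 at N = 90,000). For
band-filtered data the effective N is the number of filter-bandwidth
coherence times, not samples; the frozen null-level regression bounds
in the tests (0.16 for the 2-Hz-wide delta band down to 0.05 for gamma)
were measured once on independent white-noise channels at 180 s / 250 Hz
and reflect that inflation.

## Frequency bands and filtering

Bands: delta 2–4, theta 5–7, alpha 8–12, beta 13–29, gamma 30–60 Hz.
Preprocessing chain, in fixed order: per-channel DC removal; 60 Hz
notch (band-stop FIR, 4 Hz wide — the width is our choice, a Q is not
standard); 1–70 Hz band-pass; average re-reference; amplitude-screened
epoch selection.

All filters are windowed-sinc (Hamming) linear-phase FIR with an odd
tap count chosen as the smallest giving a ≤ 2 Hz transition width,
applied forward–backward so the net response is |H(f)|² with exactly
zero phase — phase distortion would bias PLV directly. Because the
kernels are symmetric, the double pass is implemented as two FFT
convolutions with the same kernel; edge samples within one kernel
length of each end carry the zero-padding transient and are always
inside the region trimmed before phase estimation. Attained stop-band
attenuation (double pass of a Hamming design) comfortably exceeds the
30 dB the tests assert.

Epoch selection operationalizes "artifact-free": the earliest window of
the requested length in which no sample on any channel exceeds an
amplitude threshold (default 100 µV-like units); when no clean window
exists, the window with the fewest threshold crossings is returned and
flagged. ICA-based pulse/eye-blink correction is deliberately not
implemented: the synthetic data carry no such artifacts, and a
reproducible amplitude screen is a testable stand-in.

## Synthetic cohort generator

No generative model exists for the real data, so the generator is
designed around one requirement: every downstream estimator must have
an analytically known target.

Per frequency band, a common carrier phase follows
φ(t) = 2π f_c t + random walk(σ_step = `phase_drift_sd`, default
0.05 rad/sample), with f_c the band midpoint (3, 6, 10, 21, 45 Hz) so
the oscillation stays inside its analysis band. Channel 1 carries φ;
channel j ≥ 2 carries φ + θ_j + δ_j(t); the signal is the sum over
bands of unit cosines plus white Gaussian noise scaled to the
configured oscillation-to-noise power ratio (`snr`, default 10).

* **Coupling.** δ_j is a zero-mean phase offset whose mean resultant
  E[e^{iδ}] equals the von Mises resultant I₁(κ)/I₀(κ) for the
  configured concentration κ ≥ 0. Pairwise population PLV is therefore
  I₁(κ)/I₀(κ) against channel 1 and its square between two jittered
  channels (star topology — chosen over all-to-all Kuramoto dynamics
  because every pairwise target stays closed-form).
* **Jitter time course.** The phase-level oracle
  (`generate_coupled_phase_pair`) draws δ i.i.d. von Mises per sample.
  For *signals* this would fail: per-sample jitter is spectrally white,
  a 2-Hz-wide band-pass removes nearly all of it, and the filtered PLV
  saturates at 1 regardless of κ (measured: κ = 2, target 0.698,
  filtered PLV 0.996). The synthesizer therefore uses band-limited
  Gaussian phase noise — white noise smoothed with a 0.8 s Gaussian
  kernel (circular FFT convolution) and rescaled to variance
  σ² = −2 ln(I₁(κ)/I₀(κ)), so E[e^{iδ}] = e^{−σ²/2} hits the same
  Bessel-ratio target exactly while surviving the filter. Sample-and-
  hold von Mises draws and Ornstein–Uhlenbeck noise were evaluated and
  rejected (residual bias +0.03…+0.10 after filtering; the smoothed-
  Gaussian bias is ≲ +0.01 beyond the intrinsic resultant bias).
* **Per-channel phase offsets.** θ_j are fixed and evenly spaced around
  the circle (with a random per-band rotation). They leave every
  pairwise PLV unchanged but cancel the coherent part of the
  across-channel mean; without them, average re-referencing subtracts
  the common oscillation and inverts the designed group contrast
  (measured AUC 0.17 instead of ≈ 1 for the planted effect).
* **Cohort structure.** Defaults emulate the study conditions: 26 PD +
  13 HC subjects, two conditions each, 64 channels, 180 s at 500 Hz.
  `SimConfig.test_scale()` (8 channels, 60 s, 250 Hz) is the scale used
  throughout the test suite and the acceptance script. Per-recording
  seeds are hashed from the master seed with subject and condition
  indices, so cohorts are exactly reproducible and subjects
  independent.
* **Effect size.** κ = 1.0 in every (group, condition, band) cell
  except (HC, motor, delta) = 2.5, plus a per-subject lognormal κ
  multiplier (sd 0.15 in log space) shared across conditions. These
  numbers are synthetic choices — the study reports no effect size —
  set once so that the planted effect is clearly detectable at
  n = 13 vs 26 without being degenerate (group means ≈ 0.67 vs 0.32 in
  delta-band motor-task global PLV at test scale).

What the generator does *not* emulate: 1/f background spectra,
physiological artifacts (blinks, cardiac), volume conduction / field
spread, or channel geometry. Passing tests therefore certify the
estimator chain and inference machinery, not performance on real EEG;
on real data volume conduction alone can produce spurious zero-lag
PLV that this generator never exhibits.

## Aligned-rank-transform factorial ANOVA

The three-way design is Frequency (5) × Group (2) × Condition (2), one
observation per subject × band × condition: 390 rows for the full
cohort, 20 cells, residual df 370. The model is a fixed-effects full
factorial; subject random effects are not fitted (the pooled residual
df is what the design above implies, and the group factor — 26 vs 13
subjects — makes the layout unbalanced).

For each of the seven effects, ART proceeds: (i) *align* — fit the full
factorial linear model with sum-to-zero contrasts and keep
residual + the target term's fitted component; (ii) rank the aligned
values (midranks for ties); (iii) run the factorial ANOVA on the ranks
and report the target effect's row. Alignment is regression-based
rather than cell-mean-based so the defining "stripped effects" property
— every non-target effect has F = 0 on aligned data — holds to machine
precision even in the unbalanced layout; the `ARTResult` carries the
max stripped F per effect as a diagnostic. Effect tests use Type-III
sums of squares via full/reduced model comparison (`numpy.linalg.lstsq`);
in the balanced case these coincide with the classical sequential
decomposition, and the test suite checks both the exact agreement with
an independent statsmodels OLS/anova_lm oracle and the SS partition.
Simulated type-I error at α = 0.05 is nominal within the tested ±3
percentage points.

Degenerate inputs: a constant response returns F = 0 for every effect
(degeneracy is decided against the data's magnitude, not the centred
sum of squares, which is itself rounding noise there); a design with no
residual df raises.

Post-hoc contrasts are two-sided Wilcoxon rank-sum tests on slices of
the connectivity table with Bonferroni adjustment
(p_adj = min(1, p × family)); family sizes are 5 (bands) for per-band
group contrasts and 2 (groups) for per-group condition contrasts, and
each result records the family used. P-values are exact (full
enumeration) whenever there are no ties and the pooled n ≤ 60 — which
covers the 13-vs-26 contrast, where complete separation gives
p = 2/C(39,13) — and otherwise use the normal approximation with
continuity correction. Normality screening is a one-sample
Kolmogorov–Smirnov test against a moment-matched normal; the Spearman
correlation is the Pearson correlation of midranks. Both auxiliary
tests delegate to scipy and are cross-checked against brute-force
oracles in the suite.

## ROC discrimination

Scores are a single connectivity feature per subject (default:
delta-band motor-task global PLV); the positive class is HC, because
the feature is elevated in controls and only that reading yields the
screening-type operating point the design targets. Classification is
inclusive: score ≥ threshold → positive.

The empirical ROC uses every distinct score as a threshold; the
trapezoidal AUC is then *exactly* the Mann–Whitney probability
P(score_pos > score_neg) + ½ P(tie), an identity the tests assert on
1,000 random tie-bearing instances. The operating point maximizes
PPV + NPV over all thresholds where both predictive values are defined,
breaking ties toward higher sensitivity and then the lower threshold
(if no threshold defines both — all scores identical — the fallback
maximizes sensitivity + specificity). Undefined ratios (0/0) are
reported as NaN with an explicit flag, never silently 0.

Confidence intervals are 95% percentile intervals from stratified
bootstrap resampling (positives and negatives resampled separately,
default 10,000 replicates, seeded): per replicate the curve is rebuilt,
the cutoff re-selected, and all metrics recomputed; replicates where a
metric is undefined are dropped for that metric and counted. A
`freeze_cutoff` option holds the original cutoff fixed instead, since
either reading of "bootstrap the operating point" is defensible;
re-selection is the default. The canonical 13-vs-26 screening
configuration (all positives at the cutoff, half the negatives tied
with them) reproduces AUC 0.75, sensitivity 100%, specificity 50%,
PPV 50%, NPV 100%, accuracy 66.7%, with degenerate [100, 100]%
intervals for sensitivity and NPV.

## Pipeline, determinism, problem sizes

`run_pipeline` executes simulate → preprocess → connectivity → ART +
post-hocs → ROC under one config; every stage failure is re-raised with
the stage name and input identifier. All randomness descends from the
single master seed (per-recording seeds and the bootstrap seed are
hashed from it), so a re-run is bit-identical; the run report embeds
the band edges, filter parameters, seeds and row counts needed to
reproduce it.

Default problem sizes in the test suite and acceptance script are the
reduced scale (8 channels, 60 s at 250 Hz, 55 s epochs; bootstrap 200
replicates inside repeated-pipeline checks, 10,000 where a single
analysis is reported). Full study scale (64 channels, 180 s at 500 Hz,
10,000 replicates) is a configuration choice away and changes no code
path. A full-cohort reduced-scale pipeline run takes a few seconds; the
whole acceptance script a few minutes.

## Known limitations

* Plain PLV is used, as specified; no volume-conduction-robust variant
  (PLI, wPLI) and no directional or source-space measures.
* The ART post-hoc machinery is slice-based rank-sum contrasts, not
  ART-C multifactor contrasts; interaction post-hocs on ART data have
  known subtleties that are out of scope here.
* The fixed-effects ANOVA treats the 390 rows as exchangeable given the
  cell; repeated-measures correlation within subject is not modelled
  (matching the printed residual df), which on real data would make the
  tests anti-conservative.
* The gamma band (30–60 Hz) overlaps the 58–62 Hz notch stop band at
  its upper edge; the band contract (symmetry, [0, 1] range) is
  unaffected, but usable gamma bandwidth is reduced accordingly.
* EDF/BrainVision readers are thin optional wrappers over `mne`; EDF
  export is not provided.
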