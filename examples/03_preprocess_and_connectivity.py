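"""Preprocess one recording and compute its band-wise connectivity.

The chain is the standard offline EEG sequence: DC removal, 60 Hz
notch, 1-70 Hz zero-phase FIR band-pass, average re-reference, then
selection of the longest-available artifact-free epoch. Connectivity is
the mean PLV over all unordered channel pairs, per frequency band.
"""
from plvconnect import (
    DEFAULT_BANDS,
    SimConfig,
    global_plv,
    plv_matrix,
    preprocess_recording,
    synthesize_recording,
)

config = SimConfig.test_scale(duration=60.0)
raw = synthesize_recording(config, "HC", "motor", subject_seed=7, subject_id="HC01")
clean, epoch = preprocess_recording(raw, epoch_seconds=55.0)

print(f"epoch: start sample {epoch.start}, {epoch.length} samples, "
      f"clean={epoch.clean}")
print()
print(f"{'band':>6} {'edges (Hz)':>12} {'global PLV':>11}")
for band in DEFAULT_BANDS:
    g = global_plv(plv_matrix(clean, band))
    print(f"{band.name:>6} {f'{band.low:g}-{band.high:g}':>12} {g:>11.3f}")
print()
print("Delta sits highest: this HC motor-task recording was synthesized")
print("with elevated delta-band coupling (kappa 2.5 vs baseline 1.0).")
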