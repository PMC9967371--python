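"""The full pipeline on a synthetic cohort, end to end.

simulate -> preprocess -> PLV connectivity -> ART ANOVA + Bonferroni
post-hocs -> ROC with stratified bootstrap. One master seed makes the
whole run bit-reproducible. Runs at reduced scale (8 channels, 60 s,
250 Hz) in under a minute.
"""
from plvconnect import PipelineConfig, SimConfig, run_pipeline, summarize

config = PipelineConfig(
    sim=SimConfig.test_scale(master_seed=11),
    epoch_seconds=55.0,
    n_boot=1_000,
)
report = run_pipeline(config)
print(summarize(report))
print("The delta-band motor-task contrast is the planted effect; every")
print("other band and the resting state should stay non-significant.")
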