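import numpy as np
import pandas as pd
import pytest

from plvconnect import PipelineConfig, Recording, SimConfig, run_pipeline


def make_recording(samples, fs=250.0, group="PD", condition="rest", subject="S1"):
    samples = np.atleast_2d(samples)
    labels = [f"ch{i + 1:02d}" for i in range(samples.shape[0])]
    return Recording(samples, fs, labels, subject, group, condition)


@pytest.fixture
def recording_factory():
    return make_recording


def random_design(rng, n_pd=8, n_hc=4, bands=("delta", "theta", "alpha")):
    """Complete (possibly unbalanced) factorial table with noise response."""
    rows = []
    for g, nsub in (("PD", n_pd), ("HC", n_hc)):
        for s in range(nsub):
            for c in ("rest", "motor"):
                for b in bands:
                    rows.append(
                        dict(
                            subject_id=f"{g}{s:02d}",
                            group=g,
                            condition=c,
                            band=b,
                            global_plv=rng.normal(),
                        )
                    )
    return pd.DataFrame(rows)


@pytest.fixture
def design_factory():
    return random_design


@pytest.fixture(scope="session")
def default_report():
    """One full-cohort pipeline run at test scale, shared across tests."""
    cfg = PipelineConfig(
        sim=SimConfig.test_scale(master_seed=11),
        epoch_seconds=55.0,
        n_boot=200,
    )
    return run_pipeline(cfg)
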