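import numpy as np
import pytest

from gwsig import ExpressionDataset, ProbeAnnotation, SynthConfig, generate


@pytest.fixture
def tiny_dataset():
    """3 probes x 4 samples, log2 scale, hand-set values."""
    return ExpressionDataset(
        study_id="tiny",
        probe_ids=["p1", "p2", "p3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        labels={"s1": "control", "s2": "control", "s3": "case", "s4": "case"},
        values=np.array(
            [
                [2.0, 4.0, 5.0, 7.0],  # mean diff 3.0
                [1.0, 1.0, 2.0, 2.0],  # mean diff 1.0
                [3.0, 3.0, 3.0, 3.0],  # mean diff 0.0
            ]
        ),
        scale_flag="log2",
    )


@pytest.fixture
def tiny_annotation():
    return ProbeAnnotation(entries={"p1": ["GENEA"], "p2": ["GENEB"], "p3": ["GENEC"]})


@pytest.fixture(scope="session")
def small_synth():
    """3-study, 120-gene compendium with 12 planted genes; session-shared."""
    cfg = SynthConfig(
        n_studies=3,
        genes_total=120,
        planted_de_count=12,
        effect_size=2.0,
        noise_sd=1.0,
        samples_per_class=8,
        seed=7,
    )
    return cfg, generate(cfg)
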