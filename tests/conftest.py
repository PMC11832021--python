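import numpy as np
import pytest

from poresip import pipeline, synthetic_data as sd


@pytest.fixture(scope="session")
def small_signal_dataset():
    """Tiny signal-level dataset: 30 reads/class, k=3, short reads."""
    cfg = sd.GeneratorConfig(
        n_reads_per_class=30,
        k=3,
        read_length_mean=800,
        read_length_cv=0.3,
        seed=42,
    )
    return cfg, *sd.generate(cfg)


@pytest.fixture(scope="session")
def small_stats(small_signal_dataset):
    cfg, raw, seg, labels, truth = small_signal_dataset
    return pipeline.extract_stats(raw, seg, k=cfg.k, labels=labels)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
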