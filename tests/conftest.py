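import numpy as np
import pytest

from gaitxai import grf_io
from gaitxai.graph import TrainedModel, TrainingConfig, build_architecture, train
from gaitxai.synthetic import ClassEffect, GeneratorConfig, generate_pd_dataset


@pytest.fixture(scope="session")
def tiny_pd_dataset():
    """16 short severity windows (250 x 18), standardized and split."""
    cfg = GeneratorConfig.pd(n_subjects=2, trials_per_subject_per_class=2, window_len=250)
    ds = generate_pd_dataset(cfg, seed=7)
    ds, _ = grf_io.standardize(ds)
    return grf_io.split(ds, (0.5, 0.25, 0.25), seed=7)


@pytest.fixture(scope="session")
def tiny_model(tiny_pd_dataset):
    """A briefly trained, very small single CNN (for interface tests)."""
    graph = build_architecture(
        "single",
        (tiny_pd_dataset.window_len, tiny_pd_dataset.n_channels),
        len(tiny_pd_dataset.classes),
        {"scale": 0.25, "dense_width": 8},
    )
    return train(graph, tiny_pd_dataset,
                 TrainingConfig(epochs=1, batch_size=8, seed=7, dtype="float32"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
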