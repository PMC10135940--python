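import numpy as np
import pytest

from ppgbp.synth import SimConfig, generate_record, generate_dataset
from ppgbp.preprocess import preprocess_records
from ppgbp.train import inputs_to_arrays


@pytest.fixture(scope="session")
def clean_record():
    """30-s noise-free 120/80 record at 125 Hz."""
    return generate_record(SimConfig(duration_s=30.0, seed=11).clean())


@pytest.fixture(scope="session")
def small_dataset():
    """~120 clean preprocessed segments with morphology-coupled BP labels."""
    base = SimConfig(duration_s=10.0).clean()
    records = generate_dataset(40, "uniform", base_cfg=base, seed=77)
    inputs, reports = preprocess_records(records)
    X, y, rid = inputs_to_arrays(inputs)
    return X, y, rid


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_estimator(**overrides):
    """Smallest trainable architecture for smoke tests."""
    from ppgbp.estimator import MSAResNetRegressor

    kw = dict(
        blocks_per_stage=(1, 1),
        stage_channels=(8, 16),
        branch_channels=2,
        se_reduction=4,
        epochs=2,
        batch_size=16,
        lr0=0.02,
        random_state=0,
    )
    kw.update(overrides)
    return MSAResNetRegressor(**kw)
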