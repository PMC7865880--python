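import numpy as np
import pytest

import oinose
from oinose import evaluate, network
from oinose.specs import oidscnn_spec


@pytest.fixture(scope="session")
def small_dataset():
    """A 7-class dataset small enough for fast unit tests (20 per class)."""
    cfg = oinose.SynthConfig(n_per_class=20, seed=11)
    return oinose.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    normalized, quantized, y = evaluate.preprocess_dataset(small_dataset)
    x = np.stack([ns.values for ns in normalized])
    return normalized, quantized, x, y


@pytest.fixture(scope="session")
def trained_nobias(small_preprocessed):
    """A no-bias float network trained on the small dataset (shared across tests)."""
    _, _, x, y = small_preprocessed
    net = network.FloatNetwork(oidscnn_spec(bias=False), seed=3)
    network.train(net, x, y, network.TrainConfig(max_epochs=60, seed=3))
    return net


@pytest.fixture(scope="session")
def quantized_nobias(trained_nobias, small_preprocessed):
    """(WeightQuantResult, CalibrationResult) for the shared no-bias model."""
    normalized, quantized, _, y = small_preprocessed
    wq = evaluate._quantize_model(trained_nobias, with_bias=False)
    rng = np.random.default_rng(5)
    idx = evaluate._pick_calibration(y, 3, rng)
    cal = oinose.calibrate(trained_nobias, wq,
                           [normalized[i] for i in idx],
                           [quantized[i] for i in idx])
    return wq, cal
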