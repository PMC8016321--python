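import numpy as np
import pytest

from gaitprint import (
    SyntheticSpec,
    TrainConfig,
    desk_scale_spec,
    generate_dataset,
    generate_templates,
)


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    """4 subjects, 6 trials/day: big enough for every pipeline stage."""
    return desk_scale_spec(seed=7, n_subjects=4, trials_per_day=6)


@pytest.fixture(scope="session")
def tiny_truth(tiny_spec):
    return generate_templates(tiny_spec)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def toy_model():
    """Overfit model on a linearly separable 3-class toy problem."""
    from gaitprint import train
    from gaitprint.channels import N_FEATURES

    rng = np.random.default_rng(11)
    X = rng.uniform(-0.1, 0.1, size=(30, N_FEATURES))
    y = np.repeat([0, 1, 2], 10)
    for c in range(3):
        X[y == c, c * 10] += 0.8  # large class-specific offset
    model = train(X, y, TrainConfig(hidden_size=16, max_epochs=200), seed=3)
    return model, X, y
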