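import numpy as np
import pytest

from cagevib import (
    SensorSpec,
    SimConfig,
    SplitSpec,
    TrainConfig,
    build_dataset,
    features_table,
    label_windows,
    sample_schedule,
    segment_windows,
    split,
    synth_pose,
    synth_vibration,
    train,
)


@pytest.fixture(scope="session")
def spec() -> SensorSpec:
    return SensorSpec()


@pytest.fixture(scope="session")
def slow_spec() -> SensorSpec:
    """A low-rate sensor for window-bookkeeping tests: the floor(n / (15·rate))
    windowing rule is rate-invariant, and hour-scale streams stay small."""
    return SensorSpec(accel_rate=20.0, accel_bandwidth=10.0)


def make_stream(duration_s: float, spec: SensorSpec, value: float = 0.0):
    from cagevib import ImuStream

    n = int(round(duration_s * spec.accel_rate))
    a = np.full(n, value)
    return ImuStream(spec, a.copy(), a.copy(), a.copy())


@pytest.fixture(scope="session")
def trained_bundle():
    """A model trained on 1.5 h of default synthetic data; shared by the
    monitoring tests. Small hyperparameter search to keep the suite fast."""
    config = SimConfig(duration=5400.0, gyro=False)
    schedule = sample_schedule(config, seed=100)
    stream = synth_vibration(schedule, config, seed=101)
    track = synth_pose(schedule, config, seed=102)
    dataset = build_dataset(features_table(segment_windows(stream)),
                            label_windows(track))
    train_set, test_set = split(dataset, SplitSpec(n_test=80, seed=0))
    bundle = train(train_set, TrainConfig(seed=0, n_candidates=3))
    return bundle, test_set
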