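import numpy as np
import pandas as pd
import pytest

from sportdwt import (ClassifierSpec, SportPreset, feature_table,
                      segment_dataset, simulate_dataset, split_feature_table)


@pytest.fixture(scope="session")
def soccer_high_logs():
    """Default-size high-separability soccer dataset (210 logs)."""
    return simulate_dataset(SportPreset("soccer", "high"), seed=42)


@pytest.fixture(scope="session")
def soccer_high_features(soccer_high_logs):
    """Feature table at the baseline configuration (db4, level 2, 5 s)."""
    windows = segment_dataset(soccer_high_logs, 5.0)
    return feature_table(windows, "db4", 2)


@pytest.fixture(scope="session")
def soccer_high_Xy(soccer_high_features):
    return split_feature_table(soccer_high_features)


@pytest.fixture(scope="session")
def blobs_7class():
    """Well-separated 7-class Gaussian blobs as a named feature table."""
    rng = np.random.default_rng(0)
    labels = [f"A{i}" for i in range(1, 8)]
    rows, y = [], []
    for i, lab in enumerate(labels):
        center = np.zeros(4)
        center[i % 4] = 10.0 * (1 + i // 4)
        for _ in range(24):
            rows.append(center + rng.normal(0, 0.5, size=4))
            y.append(lab)
    X = pd.DataFrame(rows, columns=["f1", "f2", "f3", "f4"])
    return X, pd.Series(y)


@pytest.fixture
def spec_nb():
    return ClassifierSpec("naive_bayes", seed=1)
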