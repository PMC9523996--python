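import numpy as np
import pytest

from pfbs import FeatureTable


@pytest.fixture
def tiny_table() -> FeatureTable:
    """4 samples x 3 features, two classes."""
    return FeatureTable(
        values=np.array([[1.0, 2.0, 3.0],
                         [4.0, 5.0, 6.0],
                         [7.0, 8.0, 9.0],
                         [10.0, 11.0, 12.0]]),
        feature_names=("x", "y", "z"),
        labels=("a", "a", "b", "b"),
        sample_ids=("s0", "s1", "s2", "s3"),
    )


def make_signal_table(n: int, n_noise: int, seed: int,
                      flip_fraction: float = 0.05) -> FeatureTable:
    """Binary table where feature 'sig' is a noisy copy of the label."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    sig = y.astype(float) + rng.normal(0, 0.1, size=n)
    flips = rng.random(n) < flip_fraction
    sig[flips] = 1.0 - sig[flips]
    noise = rng.normal(size=(n, n_noise))
    values = np.column_stack([sig, noise])
    return FeatureTable(
        values=values,
        feature_names=("sig",) + tuple(f"noise{i}" for i in range(n_noise)),
        labels=tuple("ab"[v] for v in y),
        sample_ids=tuple(f"s{i}" for i in range(n)),
    )
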