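import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from rankpanel.dataset import ExpressionDataset
from rankpanel.simulate import (
    SyntheticSpec,
    generate_dataset,
    hierarchical_planting,
    strong_signal_spec,
)


def make_dataset(values, labels, studies=None, classes=None):
    """Build an ExpressionDataset from a plain dict-of-columns or DataFrame."""
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(values)
    return ExpressionDataset(values, labels, studies, classes=classes)


@pytest.fixture
def two_class_dataset():
    """4 samples, 3 features; pair (gA, gB) perfectly separates tumor vs normal."""
    values = pd.DataFrame(
        {
            "s1": [5.0, 2.0, 3.0],
            "s2": [6.0, 1.5, 3.5],
            "s3": [2.0, 5.0, 3.0],
            "s4": [1.0, 6.0, 2.5],
        },
        index=["gA", "gB", "gC"],
    )
    labels = {"s1": "tumor", "s2": "tumor", "s3": "normal", "s4": "normal"}
    return ExpressionDataset(values, labels)


@pytest.fixture
def random_small_dataset():
    """5 features x 12 samples of seeded noise, 2 classes — for brute-force oracles."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(8, 1, size=(5, 12)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(12)],
    )
    labels = {f"s{i}": ("pos" if i < 6 else "neg") for i in range(12)}
    return ExpressionDataset(values, labels)


@pytest.fixture(scope="session")
def strong_signal_dataset():
    """Seven classes, two studies, planted perfect reversals at every tree node."""
    ds, truth = generate_dataset(strong_signal_spec(seed=202))
    return ds, truth


@pytest.fixture(scope="session")
def planted_three_class():
    """Three classes where A,B differ weakly and C carries a strong reversal vs both."""
    from rankpanel.dataset import GenePair
    from rankpanel.simulate import PlantedPair

    classes = ["A", "B", "C"]
    planted = [
        # C vs rest: near-perfect reversal; A vs B: weak signal only.
        PlantedPair(GenePair("g0001", "g0002"), frozenset({"C"}), 1.0),
        PlantedPair(GenePair("g0003", "g0004"), frozenset({"A"}), 0.3),
    ]
    spec = SyntheticSpec(
        classes=classes,
        n_per_class_per_study=10,
        studies=("lab1",),
        n_features=10,
        planted=planted,
        noise_sd=1.0,
        seed=7,
    )
    return generate_dataset(spec)[0]
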