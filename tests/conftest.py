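import numpy as np
import pytest

from crossmet import SimulationConfig, generate_dataset, split_variation
from crossmet.peaks import synthetic_peak_library


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_arm_dataset():
    """Small paired study: 14 subjects x 2 arms, two planted metabolites."""
    cfg = SimulationConfig(
        n_subjects=14,
        treatments=("A", "B"),
        planted_effects={("B", "A"): {"glutamine": -2.0, "acetone": 2.0}},
        render_spectra=False,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_noise_dataset():
    """33 subjects x 2 arms, 3 strongly planted features among 12 noise features."""
    names = [f"met{i}" for i in range(3)] + [f"noise{i:02d}" for i in range(12)]
    cfg = SimulationConfig(
        n_subjects=33,
        treatments=("A", "B"),
        planted_effects={("B", "A"): {"met0": 2.0, "met1": -2.0, "met2": 2.0}},
        peak_library=synthetic_peak_library(names, include_anchor=False),
        baselines={n: 1.0 for n in names},
        render_spectra=False,
        seed=7,
    )
    return generate_dataset(cfg)


def paired_within(ds, pair):
    """(Xw, y, subjects, feature names) for one treatment pair of a dataset."""
    sub = ds.subset_pair(pair)
    X = sub.features.to_numpy()
    subjects = sub.design["subject"].to_numpy()
    y = np.where(sub.design["treatment"].to_numpy() == pair[0], 1.0, -1.0)
    return split_variation(X, subjects).Xw, y, subjects, list(sub.features.columns)
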