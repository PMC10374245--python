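import dataclasses

import numpy as np
import pytest

import dbjnet as d


@pytest.fixture(scope="session")
def small_cohort_config():
    """Three-subject cohort at default conditions (fast to simulate)."""
    return dataclasses.replace(d.SimConfig(), n_subjects=3, seed=101)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return d.simulate_dataset(small_cohort_config)


@pytest.fixture(scope="session")
def small_epochs(small_cohort):
    return d.preprocess_pipeline(small_cohort)


def make_toy_epochs(n_subjects=3, trials_per_class=4, n_channels=40,
                    n_samples=160, effect=3.0, seed=0):
    """Directly built EpochSet with class-dependent channel offsets; much
    cheaper than the full simulator for split/training mechanics tests."""
    rng = np.random.default_rng(seed)
    protos = rng.standard_normal((3, n_channels))
    data, labels, subjects = [], [], []
    for s in range(n_subjects):
        for label in (1, 2, 3):
            for _ in range(trials_per_class):
                trial = rng.standard_normal((n_channels, n_samples))
                trial += effect * protos[label - 1][:, None]
                data.append(trial)
                labels.append(label)
                subjects.append(f"T{s + 1:02d}")
    return d.EpochSet(np.stack(data).astype(np.float32), np.array(labels),
                      np.array(subjects, dtype=object), fs=4.0)


@pytest.fixture()
def toy_epochs():
    return make_toy_epochs()
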