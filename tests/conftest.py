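import numpy as np
import pytest

import physioaffect as pa


@pytest.fixture(scope="session")
def default_study():
    """One full default synthetic study (20 participants x 12 excerpts)."""
    design = pa.StudyDesign(seed=1)
    trials, ratings = pa.generate_study(design)
    return design, trials, ratings


@pytest.fixture(scope="session")
def default_features(default_study):
    _, trials, ratings = default_study
    return pa.build_feature_matrix(trials, ratings)


@pytest.fixture(scope="session")
def trained_ensemble(default_features):
    """The full 20-trial, 80k-epoch ensemble on the default feature matrix."""
    return pa.run_trials(default_features, pa.MLPConfig(seed=1))


@pytest.fixture(scope="session")
def small_study():
    """A cheap 2-participant, 4-excerpt study for structural tests."""
    excerpts = [
        pa.ExcerptSpec("E1", "Happy", 7.0, 7.0),
        pa.ExcerptSpec("E2", "Agitated", 3.0, 7.0),
        pa.ExcerptSpec("E3", "Sad", 3.0, 3.0),
        pa.ExcerptSpec("E4", "Peaceful", 7.0, 3.0),
    ]
    design = pa.StudyDesign(n_participants=2, excerpts=excerpts, seed=7)
    trials, ratings = pa.generate_study(design)
    return design, trials, ratings


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
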