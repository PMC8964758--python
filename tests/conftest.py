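import numpy as np
import pandas as pd
import pytest

from breathvoc import cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample cohort with two strongly informative VOCs among eight."""
    cfg = cohort.default_config(
        n_healthy=10, n_cirrhosis=20, n_hcc=30, n_voc=8,
        informative_voc=[(0, +1, 2.0), (3, -1, 2.0)],
        stage_gradient=(1.0, 1.0, 1.0, 1.0, 1.0),
        prevalence=1.0, noise_sd=0.5, day_sd=0.0, ambient_level=0.0,
        n_days=5, n_treated=10, modality_split=(6, 4),
        responders_by_modality=None, responder_fraction=0.6, seed=11,
    )
    return cohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def separable_xy():
    """Two well-separated 2-D classes (labels 'hcc' vs 'control')."""
    rng = np.random.default_rng(5)
    x_pos = rng.normal([4.0, 4.0], 0.3, size=(20, 2))
    x_neg = rng.normal([0.0, 0.0], 0.3, size=(20, 2))
    X = np.vstack([x_pos, x_neg])
    y = np.array(["hcc"] * 20 + ["control"] * 20)
    return X, y


@pytest.fixture()
def blank_fixture():
    raw = pd.DataFrame(
        {"Acetone": [10e6, 1e6], "Benzene": [5e6, 4e6]},
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    blanks = pd.DataFrame(
        {"Acetone": [2e6, 3e6], "Benzene": [0.0, 0.0]},
        index=pd.Index([0, 1], name="day"),
    )
    days = pd.Series([0, 1], index=raw.index)
    return raw, blanks, days
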