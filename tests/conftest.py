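import numpy as np
import pytest

from triadvote.synthetic import (StudyDesign, generate_study, make_condition_effect,
                                 sample_weight_table)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def null_study():
    """Three-triad synthetic study with identical weights in both conditions."""
    rng = np.random.default_rng(11)
    design = StudyDesign(n_groups=3)
    base = (sample_weight_table(design, rng).query("condition == 'quiet'")
            .drop(columns="condition").reset_index(drop=True))
    weights = make_condition_effect(base, effect="none")
    trials, truth = generate_study(design, weights=weights, sigma=1.0, rng=rng)
    return trials, truth


@pytest.fixture(scope="session")
def full_study():
    """Default-design study (10 triads) with independent per-condition weights."""
    trials, truth = generate_study(seed=7, sigma=1.0)
    return trials, truth
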