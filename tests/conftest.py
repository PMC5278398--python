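import numpy as np
import pytest

import hingeforce as hf
from hingeforce.pipeline import featurize_cohort
from hingeforce.preprocess import LabeledWindow


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects, 4 windows per class: enough for LOSO and feature tests."""
    return hf.generate_cohort(3, 4, seed=11)


@pytest.fixture(scope="session")
def small_vectors(small_cohort):
    return featurize_cohort(small_cohort)


def make_window(
    left, right, sample_rate=100.0, label=hf.Behavior.NHM, subject_id="S01"
):
    return LabeledWindow(
        subject_id=subject_id,
        label=label,
        sample_rate=sample_rate,
        left=np.asarray(left, dtype=float),
        right=np.asarray(right, dtype=float),
    )


def random_window(rng, n=300, sample_rate=100.0, **kwargs):
    return make_window(
        rng.normal(size=n), rng.normal(size=n), sample_rate=sample_rate, **kwargs
    )
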