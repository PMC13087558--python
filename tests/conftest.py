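"""Shared fixtures: small synthetic datasets generated once per session."""

import numpy as np
import pytest

from cstt import GeneratorSpec, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Small dataset with the default (imbalanced, care-modulated) world."""
    return generate_dataset(GeneratorSpec(n_subjects=10, seed=11,
                                          frames_per_sample=20))


@pytest.fixture(scope="session")
def mixed_group_dataset():
    """Dataset deterministically covering all three care groups."""
    from cstt import ActivityLabel
    from cstt.data_core import Dataset
    from cstt.synthetic import generate_sample, generate_subject

    samples = []
    for i, cl in enumerate((1, 2, 3, 3, 4, 5)):
        subject = generate_subject(cl, seed=100 + i, subject_id=f"m{i}",
                                   confusability=0.6)
        acts = ([ActivityLabel.SITTING, ActivityLabel.EATING]
                if cl >= 4 else list(ActivityLabel))
        for a in acts:
            for rep in range(2):
                samples.append(generate_sample(
                    subject, a, t_f=16, seed=1000 + 10 * i + int(a) + rep,
                    sample_id=f"m{i}_{a.name.lower()}_{rep}",
                    session_id=f"day{rep}",
                ))
    return Dataset(samples)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
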