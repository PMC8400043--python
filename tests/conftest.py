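import numpy as np
import pytest

import sonouroflow as sf
from sonouroflow.dataset import Example


@pytest.fixture(scope="session")
def small_cohort():
    """3 patients per class, deterministic."""
    return sf.gen_cohort(3, seed=42)


@pytest.fixture(scope="session")
def bell_curve():
    return sf.gen_flow_curve(sf.ArchetypeSpec("bell", q_max=20.0, voiding_time=30.0, seed=7))


@pytest.fixture(scope="session")
def staccato_curve():
    return sf.gen_flow_curve(
        sf.ArchetypeSpec("staccato", q_max=8.0, voiding_time=40.0, n_dips=4, dip_depth=0.5, seed=7)
    )


@pytest.fixture(scope="session")
def interrupted_curve():
    return sf.gen_flow_curve(
        sf.ArchetypeSpec("interrupted", q_max=4.0, voiding_time=60.0, n_bursts=3, seed=7)
    )


@pytest.fixture(scope="session")
def tiny_classification_set():
    """Small, fast classification training set (still all 3 classes)."""
    events = sf.gen_cohort(3, seed=5)
    examples = []
    for i, e in enumerate(events):
        for c in sf.augment(e.flow, sf.AugmentConfig(n_copies=10, seed=100 + i)):
            examples.append(Example(e.patient_id, sf.normalize_resample(c).values, label=e.label))
    return sf.build_training_set(examples, task="classification", split_fraction=0.7, seed=1)


@pytest.fixture(scope="session")
def tiny_regression_set():
    events = sf.gen_cohort(4, seed=6)
    examples = [
        Example(
            e.patient_id,
            np.column_stack([e.features.loudness, e.features.roughness]),
            target=e.flow.flowrate,
        )
        for e in events
    ]
    return sf.build_training_set(examples, task="regression", split_fraction=0.75, seed=1)
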