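import numpy as np
import pytest

from lthrm import (
    RollingWindowDetector,
    SimSpec,
    generate_cohort,
    preprocess_recording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_cohort():
    """Six short annotated recordings shared across detector tests."""
    spec = SimSpec(n_patients=6, recording_minutes=3.0, seed=42)
    recs, anns, labels = generate_cohort(spec)
    preps = [preprocess_recording(r) for r in recs]
    return {"recs": recs, "anns": anns, "labels": labels, "preps": preps}


@pytest.fixture(scope="session")
def trained_detector(small_cohort):
    """Detector trained on the first four patients of the small cohort."""
    det = RollingWindowDetector(stride=10, random_state=0)
    det.fit(small_cohort["preps"][:4], small_cohort["anns"][:4])
    return det
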