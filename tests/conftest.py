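import numpy as np
import pytest

from sleepmci.features import extract_cohort_features
from sleepmci.synth import SimulationConfig, generate_cohort

FS = 100.0


@pytest.fixture(scope="session")
def strong_effect_cohort():
    """Seeded cohort with strong group effects, shared across the
    classifier and statistics tests (feature extraction is the expensive
    step, so it runs once per session)."""
    config = SimulationConfig(seed=7, mci_spindle_factor=0.3,
                              mci_theta_boost=2.0)
    recordings, hypnograms, truths, labels = generate_cohort(config, 8, 8)
    annotations = [t.artifact_annotations() for t in truths]
    tables = extract_cohort_features(recordings, hypnograms,
                                     annotations=annotations)
    return {"config": config, "recordings": recordings,
            "hypnograms": hypnograms, "truths": truths,
            "labels": np.array(labels), "tables": tables}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
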