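import numpy as np
import pytest

from sparseseg.io import CHANNEL_NAMES, Subject
from sparseseg.normalize import fit_histogram_model, normalize_cohort
from sparseseg.synth import PhantomConfig, generate_cohort_subjects


@pytest.fixture(scope="session")
def small_phantom_config():
    return PhantomConfig(shape=(32, 32, 32), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_phantom_config):
    """Four complete-imaging phantoms at 32^3, shared across tests."""
    return generate_cohort_subjects(small_phantom_config, 4, force_complete=True)


@pytest.fixture(scope="session")
def normalized_cohort(small_cohort):
    model = fit_histogram_model(small_cohort)
    return normalize_cohort(small_cohort, model), model


def make_subject(channels, mask=None, available=None, spacing=(1.0, 1.0, 1.0),
                 subject_id="sub"):
    """Hand-built subject; brain mask = support of the first channel."""
    channels = np.asarray(channels, dtype=np.float32)
    if available is None:
        available = [np.abs(c).max() > 0 for c in channels]
        available[0] = True
    brain = (np.abs(channels[0]) > 0).astype(np.uint8)
    if mask is not None:
        brain = np.maximum(brain, np.asarray(mask, dtype=np.uint8))
    return Subject(subject_id=subject_id, channels=channels,
                   available=np.asarray(available, dtype=bool),
                   spacing=spacing, brain_mask=brain, mask=mask)
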