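import numpy as np
import pytest
from hypothesis import settings

from cytoconn import synth

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_config():
    """Scaled-down study: 4 systems x 3 ROIs, short scans, one age."""
    return synth.SynthConfig(
        n_subjects_per_group=8, n_rois=12, n_systems=4,
        affected_systems=(1, 2), n_timepoints_per_scan=120,
        scans_per_subject=2, ages=(6.0,), seed=11)


@pytest.fixture
def cytokine_config():
    """Full four-age design for cytokine generation (planted analytes)."""
    return synth.SynthConfig(
        n_subjects_per_group=7, n_rois=12, n_systems=4,
        affected_systems=(1, 2), seed=5)
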