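import numpy as np
import pytest

from protniche.synthetic_data import StudySpec, simulate_study


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """A small synthetic study bundle shared across tests (8 organisms,
    alternating acidic-planted methanogen-like and basic-planted
    sulphur-metaboliser-like groups, GC 0.30-0.70)."""
    root = tmp_path_factory.mktemp("bundle")
    return simulate_study(StudySpec(seed=11), root)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
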