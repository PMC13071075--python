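import numpy as np
import pytest

from nodulenet.phantom import generate_cohort, load_manifest


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 6-case phantom cohort shared by pipeline-level tests."""
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(6, 0.5, seed=123, out_dir=out)
    return out


@pytest.fixture(scope="session")
def small_manifest(small_cohort):
    return load_manifest(small_cohort / "manifest.csv")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
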