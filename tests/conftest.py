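import pytest

from embody import crossval_pipeline, make_task_design


@pytest.fixture(scope="session")
def design6():
    """A default six-block IA task design."""
    return make_task_design(seed=11)


@pytest.fixture(scope="session")
def cv_mid():
    """A cross-validated synthetic subject at moderate signal strength.

    Small voxel count keeps the six-fold fit fast while the signal is strong
    enough for clearly above-chance decoding.
    """
    return crossval_pipeline(seed=11, n_voxels=30, snr=1.5)
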