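import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from deftrus import phantom as ph

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort64(tmp_path_factory):
    """Small unpaired 64-px phantom cohort with a paired evaluation split."""
    out = tmp_path_factory.mktemp("cohort64")
    return ph.make_cohort(out, n_train_mr=4, n_train_trus=4, n_paired_eval=2,
                          seed=0, base_spec=ph.PhantomSpec.for_size(64, n_slices=2))


@pytest.fixture(scope="session")
def smoke_params():
    """Training configuration of the desk-scale smoke model."""
    return dict(iterations=200, batch_size=2, n_res=4, base_channels=8,
                disc_channels=8, n_patches=64, n_negatives=128)


@pytest.fixture(scope="session")
def quick_translator(cohort64):
    """A briefly trained translator for cheap structural tests."""
    from deftrus.training import MRToTRUSTranslator

    return MRToTRUSTranslator(iterations=6, n_res=2, base_channels=8,
                              seed=3).fit(cohort64)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
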