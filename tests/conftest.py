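import numpy as np
import pytest

from ventseg.phantom import PhantomSpec, make_cohort


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """A fast phantom for unit tests: 32x32 in-plane, 12 thin slices."""
    return PhantomSpec(n_slices=12, thick_factor=4, thin_spacing=0.8,
                       in_plane_size=(32, 32), head_radii=(60.0, 40.0, 40.0),
                       seed=0)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory, tiny_spec):
    """A 3 labeled / 3 unlabeled / 2 test-pair cohort of tiny phantoms."""
    out = tmp_path_factory.mktemp("tiny_cohort")
    manifest = make_cohort(3, 3, 2, out, seed=3, spec_template=tiny_spec)
    return manifest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
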