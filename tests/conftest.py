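import numpy as np
import pytest

from fcdmvpa.bold import BoldSeries, default_affine
from fcdmvpa.cohort import CohortSpec, generate_cohort


def tiny_spec(**kw) -> CohortSpec:
    """A very small cohort spec for fast unit tests: 4^3 GM region of 8
    parcels inside a 6^3 grid, 40 timepoints."""
    defaults = dict(
        n_group_a=4,
        n_group_b=4,
        grid_shape=(6, 6, 6),
        n_timepoints=40,
        n_parcels=8,
        hub_parcels=frozenset({1, 8}),
        coupling_a=2.0,
        coupling_b=0.5,
        seed=7,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_spec())


def make_series(data: np.ndarray, tr: float = 2.4) -> BoldSeries:
    return BoldSeries(data=np.asarray(data, float), tr=tr, affine=default_affine(3.0))


def random_series(rng, grid=(5, 5, 5), t=60, tr=2.4) -> BoldSeries:
    return make_series(rng.normal(size=grid + (t,)), tr=tr)
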