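import numpy as np
import pytest

from survrp.survival_core import SurvivalDataset
from survrp.synthetic_data import OutlierSpec, SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Modest cohort with signal: n=120, p=60, 3 informative genes."""
    spec = SyntheticSpec(n=120, p=60, n_informative=3, beta_scale=1.0, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def planted_cohort():
    """Study-shaped cohort with two planted long-term survivors."""
    spec = SyntheticSpec(
        n=517, p=2000, seed=0,
        outliers=(OutlierSpec("long_survivor", 2, 10.0),),
    )
    return generate_cohort(spec)


@pytest.fixture()
def two_subject_constant():
    """n=2, constant covariate (beta = 0): hand-computable Breslow example."""
    def make(times, status):
        return SurvivalDataset(
            sample_ids=["A", "B"],
            time=np.asarray(times, float),
            status=np.asarray(status, int),
            X=np.ones((2, 1)),
            gene_names=["g1"],
        )

    return make
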