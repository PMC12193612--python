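import warnings

import numpy as np
import pytest

import healthineq as hq
from healthineq.cardinalization import CONTROL_COLUMNS, fit_ordered_probit, predict_latent

# ordered-probit refits on resampled / null data can emit harmless
# statsmodels convergence chatter; tests assert on the converged flag instead
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def default_cohort_truth():
    """Default-configuration cohort at n=20,000 with its ground truth."""
    return hq.generate_cohort(hq.CohortConfig(n_individuals=20_000, seed=7))


@pytest.fixture(scope="session")
def default_cohort(default_cohort_truth):
    return default_cohort_truth[0]


@pytest.fixture(scope="session")
def default_probit(default_cohort):
    """Ordered-probit fit on the default cohort's initial income."""
    cohort = default_cohort
    return fit_ordered_probit(
        cohort["srh"].to_numpy(),
        cohort["income_initial"].to_numpy(),
        cohort.loc[:, list(CONTROL_COLUMNS)],
    )


@pytest.fixture(scope="session")
def default_sah(default_cohort, default_probit):
    """[0, 1] cardinal health on the default cohort (initial income)."""
    latent = predict_latent(
        default_probit,
        default_cohort["income_initial"].to_numpy(),
        default_cohort.loc[:, list(CONTROL_COLUMNS)],
    )
    return hq.rescale_unit(latent).sah


@pytest.fixture(scope="session")
def small_cohort():
    cohort, _ = hq.generate_cohort(hq.CohortConfig(n_individuals=2_000, seed=3))
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
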