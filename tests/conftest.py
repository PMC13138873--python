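import numpy as np
import pytest

from isapk.datatypes import (
    DoseEvent,
    IndividualParameters,
    Observation,
    PopulationModel,
    SubjectRecord,
)
from isapk.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def final_model() -> PopulationModel:
    """The fitted population model used throughout the analyses."""
    return PopulationModel()


@pytest.fixture(scope="session")
def typical_individual(final_model) -> IndividualParameters:
    return IndividualParameters(cl=final_model.tvcl, v=final_model.tvv,
                                ka=final_model.ka)


@pytest.fixture(scope="session")
def small_cohort():
    """25 sparse-sampled subjects with the default study structure."""
    spec = CohortSpec(n_subjects=25, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def rich_cohort():
    """60 subjects with richer sampling, for estimation tests."""
    spec = CohortSpec(n_subjects=60, seed=13, samples_per_subject=6,
                      trough_fraction=0.3)
    return generate_cohort(spec)


def make_qd_subject(subject_id="S1", dose=200.0, n_days=15, obs_spec=(),
                    centre=1, bmi=None):
    """A once-daily oral regimen with observations at (time, value) pairs."""
    doses = [DoseEvent(time=24.0 * k, amount=dose) for k in range(n_days)]
    obs = [Observation(time=t, value=v) for t, v in obs_spec]
    covariates = []
    if bmi is not None:
        from isapk.datatypes import CovariateRecord
        covariates = [CovariateRecord(time=0.0, bmi=bmi)]
    return SubjectRecord(subject_id=subject_id, centre=centre, doses=doses,
                         observations=obs, covariates=covariates)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
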