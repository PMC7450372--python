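import numpy as np
import pytest

from glysense.features import (aggregate_bins, build_dataset, impute_missing,
                               smooth_series)
from glysense.synthetic_data import (InfectionEpisode, PatientProfile,
                                     generate_patient_year)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def patient_year_log():
    """One patient-year with a single strong 7-day episode."""
    return generate_patient_year(
        PatientProfile(),
        [InfectionEpisode(150, 7, bg_elevation=60.0,
                          insulin_demand_multiplier=1.6,
                          carb_reduction_factor=0.7)],
        seed=1,
    )


@pytest.fixture(scope="session")
def daily_dataset(patient_year_log):
    """Smoothed daily labelled dataset from the patient-year fixture."""
    series = smooth_series(
        impute_missing(aggregate_bins(patient_year_log, "daily"))
    )
    return build_dataset(series, patient_year_log)


@pytest.fixture(scope="session")
def daily_dataset_raw(patient_year_log):
    series = impute_missing(aggregate_bins(patient_year_log, "daily"))
    return build_dataset(series, patient_year_log)
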