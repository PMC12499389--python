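import numpy as np
import pandas as pd
import pytest

from boldslope import cohort
from boldslope.spectral import estimate_ss_matrix


@pytest.fixture(scope="session")
def default_spec():
    return cohort.CohortSpec(seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    """Subjects, geometry and trajectory assignment of the default cohort."""
    subjects = cohort.generate_subject_table(default_spec)
    geometry = cohort.generate_parcel_geometry(default_spec)
    trajectories = cohort.assign_trajectories(default_spec, geometry)
    return default_spec, subjects, geometry, trajectories


@pytest.fixture(scope="session")
def default_ss_maps(default_cohort):
    """Estimated subject x parcel SS maps for the full default cohort."""
    spec, subjects, geometry, trajectories = default_cohort
    series = cohort.generate_cohort_timeseries(spec, subjects, trajectories, geometry)
    nonmed = ~geometry["medial_wall"].to_numpy()
    pids = geometry["parcel_id"].to_numpy()[nonmed]
    rows = {
        sid: estimate_ss_matrix(vals[:, nonmed], spec.tr, valid)[0]
        for sid, (vals, valid) in series.items()
    }
    maps = pd.DataFrame(rows).T
    maps.columns = pids
    maps.index.name = "subject_id"
    return maps


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
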