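import numpy as np
import pytest

from mmforecast.cohort import PatientTrajectory
from mmforecast.pipeline import preprocess_cohort
from mmforecast.simulate import (
    SimulationConfig,
    inject_missingness,
    label_cohort,
    simulate_cohort,
)


def make_trajectory(values, patient_id="P0", mask=None, labels=None):
    """Build a trajectory from a (visits x 10) array with sensible defaults."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return PatientTrajectory(
        patient_id=patient_id,
        visit_months=3.0 * np.arange(n),
        values=values,
        observed_mask=np.ones_like(values, dtype=bool) if mask is None else mask,
        pd_labels=np.full(n, -1, dtype=int) if labels is None else labels,
    )


def marker_trajectory(mpr=None, sfl_kappa=None, sfl_lambda=None, n=None, base=None):
    """Trajectory with specified marker columns and flat physiology elsewhere."""
    cols = [c for c in (mpr, sfl_kappa, sfl_lambda) if c is not None]
    n = n or len(cols[0])
    base = base if base is not None else [11, 9.5, 1.1, 180, 3.8, 3.5, 1.0, 20.0, 30.0, 6.0]
    values = np.tile(np.asarray(base, dtype=float), (n, 1))
    if mpr is not None:
        values[:, 6] = mpr
    if sfl_lambda is not None:
        values[:, 7] = sfl_lambda
    if sfl_kappa is not None:
        values[:, 8] = sfl_kappa
    return make_trajectory(values)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_patients=30, n_visits=12)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Labeled 30-patient cohort with missingness, shared across tests."""
    cohort = label_cohort(simulate_cohort(small_config))
    return inject_missingness(cohort, small_config)


@pytest.fixture(scope="session")
def prepared_small(small_cohort):
    prepared, _ = preprocess_cohort(small_cohort)
    return prepared
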