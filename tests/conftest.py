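import numpy as np
import pytest

from lmdpnet import data_model as dm
from lmdpnet import synthetic_cohort as sc


@pytest.fixture(scope="session")
def small_cohort():
    """12 patients with small imaging volumes and default missingness."""
    cfg = sc.CohortConfig(n_patients=12, volume_shape=(8, 10, 8), seed=11)
    cohort = sc.generate_cohort(cfg)
    return sc.apply_missingness(cohort, cfg)


@pytest.fixture(scope="session")
def tabular_cohort():
    """60 tabular-only patients with default missingness."""
    cfg = sc.CohortConfig(n_patients=60, render_images=False, seed=5)
    cohort = sc.generate_cohort(cfg)
    return sc.apply_missingness(cohort, cfg)


@pytest.fixture(scope="session")
def tabular_stats(tabular_cohort):
    return dm.compute_global_stats(tabular_cohort)


def make_visit(month, diagnosis="CN", bio=None, age=72.0, gender="F",
               education=16.0, apoe4=0, volumes=None):
    return dm.VisitRecord(
        timestamp_months=month,
        diagnosis=diagnosis,
        biomarkers=np.full(6, 10.0) if bio is None else np.asarray(bio, dtype=float),
        age=age, gender=gender, education=education, apoe4=apoe4,
        volumes=volumes or {},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
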