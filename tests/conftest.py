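import numpy as np
import pytest

from ntcpkit import cohort as syn
from ntcpkit.config import RunConfig
from ntcpkit.dvh import DVHCurve
from ntcpkit.io import build_feature_table
from ntcpkit.pipeline import run_pipeline


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dvh(rng, patient_id="p0", structure="s", max_dose=None):
    """Random piecewise-linear cumulative DVH, independent of the sigmoid
    generator (used as neutral input for metric property tests)."""
    if max_dose is None:
        max_dose = float(rng.uniform(20.0, 70.0))
    n = int(rng.integers(8, 40))
    dose = np.sort(rng.uniform(0.0, max_dose, size=n))
    dose = np.concatenate([[0.0], dose, [max_dose]])
    dose = np.unique(dose)
    vol = np.sort(rng.uniform(0.0, 1.0, size=dose.size - 2))[::-1]
    vol = np.concatenate([[1.0], vol, [0.0]])
    return DVHCurve(patient_id=patient_id, structure=structure, dose_gy=dose, volume_fraction=vol)


@pytest.fixture(scope="session")
def default_cohort():
    """Default 258-patient cohort with both endpoints (session-cached)."""
    return syn.generate_cohort(syn.default_spec(n_patients=258, seed=1))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    c = default_cohort
    return build_feature_table(list(c.dvhs), list(c.clinical), grades=c.grades)


@pytest.fixture(scope="session")
def small_pipeline_result(tmp_path_factory):
    """One small but complete pipeline run shared by report/CLI tests."""
    out = tmp_path_factory.mktemp("pipe")
    cfg = RunConfig(endpoint="esophagitis", seed=5, n_boot=8, synthetic_n_patients=90)
    return run_pipeline(cfg, out), out
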