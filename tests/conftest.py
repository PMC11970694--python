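import numpy as np
import pandas as pd
import pytest

from growthcanal.reference_model import default_toy_references, make_toy_reference
from growthcanal.synthetic_data import SimulationConfig, simulate_cohort
from growthcanal.target_height import add_target_height
from growthcanal.trajectory_analysis import add_discrepancy
from growthcanal.zscore_engine import add_zscores


@pytest.fixture(scope="session")
def toy_refs():
    return default_toy_references()


@pytest.fixture(scope="session")
def linear_child_std():
    # M(age) = 50 + age, L = 1, S = 0.04: closed-form z-scores in tests
    return make_toy_reference("linear_child", M0=50.0, slope=1.0, L=1.0, S=0.04)


@pytest.fixture(scope="session")
def adult_170_158():
    return make_toy_reference("adult_point", M_male=170.0, M_female=158.0, L=1.0, S=0.04)


def run_pipeline(cohort, refs):
    """z-score -> outlier filter -> target height -> discrepancy."""
    out = add_zscores(cohort, refs["child_std"], refs["bmi_std"])
    out = out[out["age_in_range"] & ~out["haz_excluded"]]
    out = add_target_height(out, refs["adult_ref"])
    out = out[out["thz"].notna()]
    return add_discrepancy(out)


@pytest.fixture(scope="session")
def small_cohort(toy_refs):
    cfg = SimulationConfig(n_per_wave=300, seed=7)
    return simulate_cohort(cfg, toy_refs)


@pytest.fixture(scope="session")
def analyzed_cohort(toy_refs):
    """A mid-size cohort run through the full pipeline (shared, read-only)."""
    cfg = SimulationConfig(n_per_wave=1250, seed=0)
    return run_pipeline(simulate_cohort(cfg, toy_refs), toy_refs)
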