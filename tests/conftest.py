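import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ptsd_phenotyper as pp
from ptsd_phenotyper.catalog import CriterionCatalog, ParameterSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """A study-scale cohort (38 controls / 84 exposed) with planted truth."""
    cfg = pp.default_simulation_config(seed=11)
    return pp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted(default_cohort):
    cohort, _truth = default_cohort
    return pp.SusceptibilityModel(cohort).fit()


def toy_catalog(n_continuous=3, n_criteria=1, binary=False):
    """A small catalog: n_continuous identity-transform parameters spread
    round-robin over criteria A-slots B, C, D..., plus an optional binary."""
    crits = list("BCDEG")[:n_criteria]
    params = [
        ParameterSpec(
            name=f"p{i}",
            assay="toy",
            kind="continuous",
            transform="identity",
            criteria=frozenset({crits[i % n_criteria]}),
        )
        for i in range(n_continuous)
    ]
    if binary:
        params.append(
            ParameterSpec(
                name="probe",
                assay="toy",
                kind="binary",
                criteria=frozenset({crits[0]}),
            )
        )
    return CriterionCatalog(parameters=tuple(params), measurable_criteria=tuple(crits))


def build_cohort(catalog, rows):
    """Cohort from a list of dicts (mouse_id, sex, group, parameter values)."""
    return pp.CohortTable(frame=pd.DataFrame(rows), catalog=catalog)
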