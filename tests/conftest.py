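import numpy as np
import pandas as pd
import pytest

from scovnet.regions import CohortTable, canonical_registry
from scovnet.simulate import generate_cohort, scenario_library


@pytest.fixture(scope="session")
def registry():
    return canonical_registry()


@pytest.fixture(scope="session")
def scenarios(registry):
    return scenario_library(registry)


@pytest.fixture(scope="session")
def null_cohort(scenarios):
    """One draw of the null scenario (71 controls / 67 cases)."""
    return generate_cohort(scenarios["A-null"], seed=20240901)


def make_cohort(registry, volumes_by_subject, groups, age=None, sex=None, tbv=None):
    """Assemble a small CohortTable directly from dicts/arrays."""
    n = len(volumes_by_subject)
    index = [f"s{i:03d}" for i in range(n)]
    volumes = pd.DataFrame(list(volumes_by_subject), index=index)
    rng = np.random.default_rng(7)
    covariates = pd.DataFrame(
        {
            "group": list(groups),
            "age": age if age is not None else rng.uniform(20, 60, n),
            "sex": sex if sex is not None else rng.integers(0, 2, n),
            "tbv": tbv if tbv is not None else rng.normal(1.5e6, 1e5, n),
        },
        index=index,
    )
    return CohortTable(volumes=volumes, covariates=covariates, registry=registry)


@pytest.fixture
def tiny_cohort_factory(registry):
    """Factory for hand-built cohorts over arbitrary region columns."""

    def _make(volumes_by_subject, groups, **kw):
        return make_cohort(registry, volumes_by_subject, groups, **kw)

    return _make
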