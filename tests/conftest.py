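import numpy as np
import pytest

from burdenmap.glmm import ModelSpec, build_design, fit
from burdenmap.synthetic import Scenario, generate_covariates, region_partition, simulate_survey


@pytest.fixture(scope="session")
def small_scenario():
    """A down-scaled study (150 clusters, coarse grid) for fast end-to-end tests."""
    return Scenario(seed=11, n_clusters=150, n_regions=5,
                    extent=(36.0, 6.0, 38.0, 8.0), cell_size=0.1)


@pytest.fixture(scope="session")
def small_study(small_scenario):
    covs = generate_covariates(small_scenario)
    records, truth = simulate_survey(small_scenario, covs)
    return small_scenario, covs, records, truth


@pytest.fixture(scope="session")
def cluster_covariates(small_study):
    scenario, covs, records, _ = small_study
    lons = np.array([r.lon for r in records])
    lats = np.array([r.lat for r in records])
    return {n: covs[n].sample_nearest(lons, lats) for n in scenario.covariate_names}


@pytest.fixture(scope="session")
def small_fit(small_study, cluster_covariates):
    scenario, covs, records, _ = small_study
    spec = ModelSpec(covariates=scenario.covariate_names, mode="embedded")
    result = fit(records, spec, cluster_covariates)
    data = build_design(records, cluster_covariates, spec)
    return result, data


@pytest.fixture(scope="session")
def small_zones(small_scenario):
    ids, _, polys = region_partition(small_scenario)
    return list(zip(ids, polys))
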