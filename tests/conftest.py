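"""Shared fixtures: a small study region and one desk-scale synthetic survey
with a fitted geostatistical model, reused across test modules."""

import numpy as np
import pytest

from geostunt import model, spde
from geostunt import synthetic as syn

DESK_TERMS = [
    model.CategoricalTerm(
        "maternal_education", ("none", "primary", "secondary+")
    ),
    model.CategoricalTerm("household_wealth", ("poor", "middle", "rich")),
    model.CategoricalTerm("aridity", ("Wet", "Semi-arid", "Arid")),
]


@pytest.fixture(scope="session")
def region():
    return syn.make_study_region(n_zones=6, extent_km=300.0, seed=1000)


@pytest.fixture(scope="session")
def desk_survey(region):
    """150-cluster survey with a range-80 km, variance-0.5 field."""
    cfg = syn.SimulationConfig(
        n_clusters=150,
        seed=11,
        matern=spde.MaternParams(kappa=spde.kappa_for_range(80.0), sigma2=0.5),
    )
    records, truth = syn.simulate_survey(region, cfg)
    return records, truth, cfg


@pytest.fixture(scope="session")
def desk_mesh(region, desk_survey):
    records, _, _ = desk_survey
    locs = np.array([[r.x, r.y] for r in records])
    return spde.build_mesh(
        locs, region.boundary, max_edge_km=45.0, cutoff_km=3.0,
        extension_km=90.0,
    )


@pytest.fixture(scope="session")
def desk_spec():
    return model.ModelSpec(covariates=list(DESK_TERMS), spatial=True)


@pytest.fixture(scope="session")
def desk_fit(desk_survey, desk_mesh, desk_spec):
    records, _, _ = desk_survey
    return model.fit_geostatistical(
        desk_spec, records, desk_mesh, method="laplace", seed=5
    )
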