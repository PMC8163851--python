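import numpy as np
import pandas as pd
import pytest

import firegest as fg
from firegest import cohort as cohort_mod
from firegest import exposure as exp_mod


@pytest.fixture(scope="session")
def small_world():
    """A compact seeded world shared by integration-style tests."""
    cfg = fg.WorldConfig(rng_seed=42, n_mothers=4000, n_clusters=80)
    return fg.simulate_world(cfg)


@pytest.fixture(scope="session")
def small_series(small_world):
    ev = small_world.cohort.events
    cl = ev[["cluster_id", "lat", "lon"]].drop_duplicates("cluster_id").sort_values("cluster_id")
    series = exp_mod.extract_at_points(
        small_world.calibrated, cl["lat"].to_numpy(), cl["lon"].to_numpy()
    )
    mapping = {c: i for i, c in enumerate(cl["cluster_id"])}
    return series, mapping


@pytest.fixture(scope="session")
def small_matched(small_world, small_series):
    series, mapping = small_series
    ev = small_world.cohort.events.assign(_point=lambda d: d["cluster_id"].map(mapping))
    return cohort_mod.build_matched_cohort(ev, series, (2000, 2014), point_col="_point")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def make_sets(records):
    """Long matched-set frame from [(set_id, is_case, {covariates}), ...]."""
    rows = []
    for set_id, is_case, cov in records:
        rows.append({"set_id": set_id, "is_case": is_case, **cov})
    return pd.DataFrame(rows)
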