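import warnings

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon

import surveygam as sg

# basis auto-reduction on sparse systematic designs is expected and noisy
warnings.filterwarnings("ignore", message=".*basis dimension.*")


@pytest.fixture(scope="session")
def triangle_run():
    """One dense-survey replicate pushed through segmentation (shared)."""
    cfg = sg.preset("triangle_like", seed=1)
    obs, transects, area, truth = sg.simulate(cfg)
    obs = sg.indicated_units(sg.apply_inclusion_rules(obs))
    segs = sg.assign_counts(sg.segment_transects(transects, 1.0, 0.4), obs)
    return {"cfg": cfg, "obs": obs, "transects": transects, "area": area,
            "truth": truth, "segments": segs}


@pytest.fixture(scope="session")
def triangle_m1_fit(triangle_run):
    models = sg.standard_models(which=["M1"], k_year=12)
    return sg.fit_gam(models["M1"], triangle_run["segments"])


@pytest.fixture(scope="session")
def small_nb_data():
    """Small NB data set with a year effect for engine unit tests."""
    rng = np.random.default_rng(5)
    n = 60
    data = pd.DataFrame(
        {
            "x_c": rng.uniform(0, 10, n),
            "y_c": rng.uniform(0, 10, n),
            "year": rng.integers(2000, 2010, n).astype(int),
            "area": rng.uniform(0.5, 2.0, n),
        }
    )
    mu = 0.8 * data["area"]
    data["count"] = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
    assert data["count"].sum() > 0
    return data


@pytest.fixture()
def straight_transect():
    return pd.DataFrame(
        [
            {
                "transect_id": "t1",
                "survey_id": "s",
                "year": 2000,
                "stratum": "a",
                "geometry": LineString([(0.0, 0.0), (10.0, 0.0)]),
                "design_width": 0.4,
            }
        ]
    )


@pytest.fixture()
def unit_square_area():
    return sg.StudyArea(
        polygons={"a": Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])}
    )
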