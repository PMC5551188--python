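"""Synthetic city generator: determinism, invariants, kernel closed
forms, additivity and seasonal calibration."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

import lurfkit as lk
from lurfkit.categories import AREAL_CATEGORIES, TREE_SUBLAYERS
from lurfkit.city import CityDataset, ConfigurationError
from lurfkit.grids import Raster


def make_line_city(aadt=100000.0, extent=10000.0, cell=100.0):
    """Minimal city: one straight freeway, flat terrain, no land cover."""
    n = int(extent / cell)
    zeros = lambda: Raster(np.zeros((n, n)), 0.0, 0.0, cell)
    areal = {c: zeros() for c in AREAL_CATEGORIES if c != "trees"}
    for s in TREE_SUBLAYERS:
        areal[s] = zeros()
    return CityDataset(
        areal_layers=areal,
        roads=pd.DataFrame(
            {
                "geometry": [LineString([(5000.0, 0.0), (5000.0, extent)])],
                "road_class": ["freeway"],
                "aadt": [aadt],
            }
        ),
        rail=pd.DataFrame({"geometry": []}),
        emitters=pd.DataFrame({"x": [], "y": [], "nox_tons_per_year": []}),
        housing=zeros(),
        elevation=zeros(),
        population={"all": zeros()},
        population_blocks=pd.DataFrame({"geometry": [], "population": []}),
        extent=(0.0, 0.0, extent, extent),
    )


def test_generation_is_deterministic():
    a = lk.generate_city(lk.SyntheticTruthParams(seed=1))
    b = lk.generate_city(lk.SyntheticTruthParams(seed=1))
    for name in a.areal_layers:
        np.testing.assert_array_equal(a.areal_layers[name].values, b.areal_layers[name].values)
    np.testing.assert_array_equal(a.housing.values, b.housing.values)
    pd.testing.assert_frame_equal(a.roads.drop(columns="geometry"), b.roads.drop(columns="geometry"))
    np.testing.assert_array_equal(a.population["all"].values, b.population["all"].values)


def test_areal_fraction_invariants(default_city):
    """Every fraction in [0, 1]; per-cell sums <= 1, by exhaustive scan."""
    city = default_city["city"]
    total = np.zeros_like(city.elevation.values)
    for name, r in city.areal_layers.items():
        assert (r.values >= 0).all() and (r.values <= 1).all(), name
        total += r.values
    assert (total <= 1.0 + 1e-9).all()


def test_layout_has_all_categories(default_city):
    city = default_city["city"]
    assert set(city.roads["road_class"]) == {"freeway", "primary", "secondary", "local"}
    for name, r in city.areal_layers.items():
        assert r.values.max() > 0, f"layer {name} empty"
    assert len(city.emitters) == 3


def test_zero_source_truth_is_constant_background():
    params = lk.SyntheticTruthParams(seed=0, source_strength={}, background=8.0)
    city = lk.generate_city(params)
    for season, mult in (("summer", 1.0), ("winter", 1.2)):
        surf = lk.simulate_no2_truth(city, params, season, cell_m=1000.0)
        np.testing.assert_allclose(surf.values, 8.0 * mult, rtol=1e-12)


def test_unknown_season_and_bad_config_errors(default_city):
    with pytest.raises(ValueError, match="season"):
        lk.simulate_no2_truth(default_city["city"], default_city["params"], "spring")
    with pytest.raises(ConfigurationError):
        lk.generate_city(lk.SyntheticTruthParams(seed=0), extent_m=-5.0)
    with pytest.raises(ConfigurationError):
        lk.SyntheticTruthParams(noise_sd=-1.0).validate()


def test_line_kernel_closed_form():
    """Truth at distance d from a single freeway is background +
    strength * (AADT/ref) * exp(-d/L), checked at three distances."""
    city = make_line_city(aadt=100000.0)
    params = lk.SyntheticTruthParams(
        seed=0, background=5.0, source_strength={"freeway": 6.0}
    )
    L = params.decay_length["freeway"]
    for d in (0.0, 150.0, 600.0):
        got = lk.truth_at_points(city, params, "summer", 5000.0 + d, 5000.0)
        expected = 5.0 + 6.0 * np.exp(-d / L)
        np.testing.assert_allclose(got, [expected], rtol=1e-12)


def test_truth_conservation_per_category(default_city):
    """Changing one category's strength changes truth only through that
    category's kernel term (surface subtraction)."""
    city = default_city["city"]
    p0 = default_city["params"]
    strengths = dict(p0.source_strength)
    strengths["trees"] = strengths["trees"] - 1.5
    p1 = lk.SyntheticTruthParams(seed=p0.seed, source_strength=strengths)
    a = lk.simulate_no2_truth(city, p0, "summer", cell_m=1000.0)
    b = lk.simulate_no2_truth(city, p1, "summer", cell_m=1000.0)
    xs = a.x_centers()
    ys = a.y_centers()
    xx, yy = np.meshgrid(xs, ys)
    term = lk.truth_category_term(city, p0, "trees", xx.ravel(), yy.ravel())
    # a - b = (s0 - s1) * K = 1.5 * (term / s0) = -0.5 * term for s0 = -3
    np.testing.assert_allclose((a.values - b.values).ravel(), -0.5 * term, atol=1e-9)


def test_seasonal_calibration(default_city):
    """Default config: summer truth within 4-23 ppb; seasonal site means
    within +-2 ppb of 11 (summer) and 13 (winter)."""
    ts = default_city["truth_summer"]
    tw = default_city["truth_winter"]
    assert ts.valid_values().min() >= 4.0 and ts.valid_values().max() <= 23.0
    assert tw.valid_values().min() >= 3.0 and tw.valid_values().max() <= 29.0
    sites = lk.sample_sites(default_city["city"], ts, tw, seed=3)
    means = sites.groupby("season")["no2_ppb"].mean()
    assert abs(means["summer"] - 11.0) <= 2.0
    assert abs(means["winter"] - 13.0) <= 2.0


class TestSampleSites:
    def test_counts_and_subset(self, default_city):
        sites = lk.sample_sites(
            default_city["city"],
            default_city["truth_summer"],
            default_city["truth_winter"],
            seed=5,
        )
        assert len(sites) == 174 + 82
        summer = set(sites.loc[sites.season == "summer", "site_id"])
        winter = set(sites.loc[sites.season == "winter", "site_id"])
        assert len(summer) == 174 and len(winter) == 82
        assert winter <= summer

    def test_zero_noise_matches_truth(self, default_city):
        sites = lk.sample_sites(
            default_city["city"],
            default_city["truth_summer"],
            default_city["truth_winter"],
            noise_sd=0.0,
            seed=5,
        )
        s = sites[sites.season == "summer"]
        np.testing.assert_allclose(
            s["no2_ppb"].to_numpy(),
            default_city["truth_summer"].sample(s["x"].to_numpy(), s["y"].to_numpy()),
        )

    def test_deterministic(self, default_city):
        args = (
            default_city["city"],
            default_city["truth_summer"],
            default_city["truth_winter"],
        )
        pd.testing.assert_frame_equal(
            lk.sample_sites(*args, seed=9), lk.sample_sites(*args, seed=9)
        )

    def test_winter_exceeding_summer_rejected(self, default_city):
        with pytest.raises(ValueError, match="n_winter"):
            lk.sample_sites(
                default_city["city"],
                default_city["truth_summer"],
                default_city["truth_winter"],
                n_summer=30,
                n_winter=31,
                seed=0,
            )
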