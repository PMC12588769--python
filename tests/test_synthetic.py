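import numpy as np
import pytest
from scipy import stats

from scalesdm.focal import focal_fraction
from scalesdm.grids import Grid2D
from scalesdm.synthetic import (
    FOREST,
    CROPLAND,
    ScenarioSpec,
    SyntheticTruth,
    derive_topography,
    generate_autocorrelated_field,
    generate_future_stack,
    generate_landscape,
    sample_occurrences,
    true_suitability,
)


class TestAutocorrelatedField:
    def test_white_noise_statistics(self):
        g = generate_autocorrelated_field(64, 64, 0.0, seed=0)
        v = g.values
        assert abs(v.mean()) < 3 / np.sqrt(v.size)  # exact 0 after standardising
        lag1 = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
        assert abs(lag1) < 0.05

    def test_deterministic_given_seed(self):
        a = generate_autocorrelated_field(32, 32, 3.0, seed=42)
        b = generate_autocorrelated_field(32, 32, 3.0, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_longer_length_means_larger_lag5_autocorrelation(self):
        def lag5(values):
            # direct autocovariance at horizontal lag 5
            a, b = values[:, :-5].ravel(), values[:, 5:].ravel()
            return np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())

        short = generate_autocorrelated_field(128, 128, 2.0, seed=7)
        long = generate_autocorrelated_field(128, 128, 10.0, seed=7)
        assert lag5(long.values) > lag5(short.values)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            generate_autocorrelated_field(8, 8, -1.0, seed=0)


class TestDeriveTopography:
    def test_flat_surface(self):
        topo = derive_topography(Grid2D(np.full((5, 5), 100.0), cell_size=1.0))
        for name in ("slope", "tri", "northness"):
            assert np.allclose(topo[name].valid_values(), 0.0)

    def test_north_and_south_ramps_hand_computed(self):
        # plane z = 10*y on unit cells: Horn's differences give dz/dy = 10,
        # slope = atan(10); downslope faces south so northness = -sin(slope)
        rows = np.arange(5)[:, None] * np.ones((1, 5))
        y = (5 - rows - 0.5) * 1.0
        south_facing = Grid2D(10.0 * y, cell_size=1.0, origin=(0.0, 5.0))
        topo = derive_topography(south_facing)
        expected_slope = np.degrees(np.arctan(10.0))
        assert np.allclose(topo["slope"].valid_values(), expected_slope, atol=1e-6)
        assert np.allclose(topo["aspect"].valid_values(), 180.0, atol=1e-6)
        assert np.allclose(
            topo["northness"].valid_values(), -np.sin(np.arctan(10.0)), atol=1e-6
        )
        north_facing = Grid2D(-10.0 * y, cell_size=1.0, origin=(0.0, 5.0))
        topo2 = derive_topography(north_facing)
        assert np.allclose(topo2["aspect"].valid_values(), 0.0, atol=1e-6)
        assert np.allclose(
            topo2["northness"].valid_values(), np.sin(np.arctan(10.0)), atol=1e-6
        )

    def test_tri_matches_hand_computed_neighbourhood(self):
        z = np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]])
        topo = derive_topography(Grid2D(z, cell_size=1.0))
        # |diffs| from 5: {4,3,2,1,1,2,3,4} -> mean 2.5
        assert topo["tri"].values[1, 1] == pytest.approx(2.5)

    def test_edges_masked(self):
        topo = derive_topography(Grid2D(np.random.default_rng(0).normal(size=(6, 6))))
        assert topo["slope"].nodata_mask[0].all()
        assert topo["slope"].nodata_mask[:, -1].all()
        assert not topo["slope"].nodata_mask[1:-1, 1:-1].any()

    def test_fully_masked_input_rejected(self):
        g = Grid2D(np.full((4, 4), np.nan), nodata_mask=np.ones((4, 4), bool))
        with pytest.raises(ValueError):
            derive_topography(g)


class TestGenerateLandscape:
    def test_contains_required_layer_families(self, landscape):
        names = set(landscape.names)
        assert {"elevation", "landcover", "footprint"} <= names
        assert {"annualtem", "tem_warmmon", "tem_coldmon"} <= names
        assert {"annualprec", "prec_wetmon", "prec_drymon"} <= names
        assert landscape.kinds["landcover"] == "categorical"
        codes = set(np.unique(landscape["landcover"].values))
        assert codes <= {1, 2, 3}

    def test_temperature_decreases_with_elevation(self, landscape):
        r = np.corrcoef(
            landscape["elevation"].values.ravel(), landscape["tem_warmmon"].values.ravel()
        )[0, 1]
        assert r < -0.5

    def test_contains_a_collinear_pair(self, landscape):
        r = np.corrcoef(
            landscape["annualtem"].values.ravel(), landscape["tem_warmmon"].values.ravel()
        )[0, 1]
        assert abs(r) > 0.7

    def test_deterministic_given_truth_seed(self, default_truth, landscape):
        again = generate_landscape(64, 64, 1000.0, default_truth)
        for name in landscape.names:
            assert np.array_equal(
                landscape[name].values, again[name].values
            ), f"layer {name} differs"

    def test_grid_too_small_for_largest_radius_rejected(self, default_truth):
        with pytest.raises(ValueError):
            generate_landscape(10, 10, 1000.0, default_truth)


class TestTrueSuitability:
    def test_no_responses_gives_uniform_half(self, landscape):
        truth = SyntheticTruth(true_radii={}, response_params={}, intercept=0.0)
        suit = true_suitability(landscape, truth)
        assert np.allclose(suit.valid_values(), 0.5)

    def test_unimodal_maximum_at_optimum(self, landscape):
        opt = float(np.median(landscape["tem_warmmon"].values))
        truth = SyntheticTruth(
            true_radii={"tem_warmmon": 0.0},
            response_params={"tem_warmmon": {"unimodal": (opt, 2.0)}},
            intercept=0.0,
        )
        suit = true_suitability(landscape, truth)
        best = np.unravel_index(np.argmax(suit.values), suit.shape)
        x_at_best = landscape["tem_warmmon"].values[best]
        # the argmax cell's variable value is the closest available to the optimum
        closest = np.min(np.abs(landscape["tem_warmmon"].values - opt))
        assert abs(x_at_best - opt) == pytest.approx(closest)

    def test_monotone_forest_term_ranks_with_forest_fraction(self, landscape):
        truth = SyntheticTruth(
            true_radii={"forest": 7.0},
            response_params={"forest": {"monotone": (30.0, 0.45)}},
        )
        suit = true_suitability(landscape, truth)
        frac = focal_fraction(landscape["landcover"], FOREST, 7.0)
        rho = stats.spearmanr(frac.values.ravel(), suit.values.ravel()).statistic
        assert rho > 0.9

    def test_missing_variable_raises(self, landscape):
        truth = SyntheticTruth(
            true_radii={"nope": 1.0}, response_params={"nope": {"monotone": 1.0}}
        )
        with pytest.raises(KeyError):
            true_suitability(landscape, truth)


class TestSampleOccurrences:
    def test_degenerate_mass_puts_all_points_in_one_cell(self):
        suit = np.zeros((5, 5))
        suit[2, 3] = 1.0
        g = Grid2D(suit, cell_size=1000.0, origin=(0.0, 5000.0))
        occ = sample_occurrences(g, 5, seed=1)
        assert len(occ) == 5
        assert all(g.cell_of(r.x, r.y) == (2, 3) for r in occ)

    def test_sampled_cells_are_suitability_enriched(self, suitability):
        occ = sample_occurrences(suitability, 200, seed=3)
        at_points = [suitability.value_at(r.x, r.y) for r in occ]
        assert np.mean(at_points) > suitability.valid_values().mean()

    def test_deterministic_given_seed(self, suitability):
        a = sample_occurrences(suitability, 50, seed=9)
        b = sample_occurrences(suitability, 50, seed=9)
        assert a.coordinates().tolist() == b.coordinates().tolist()

    def test_all_zero_suitability_rejected(self):
        g = Grid2D(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            sample_occurrences(g, 3, seed=0)


class TestGenerateFutureStack:
    def test_identity_scenario_is_bit_identical(self, landscape):
        spec = ScenarioSpec(label="base", period="now")
        out = generate_future_stack(landscape, spec)
        for name in landscape.names:
            assert np.array_equal(out[name].values, landscape[name].values)

    def test_warming_offset_is_exactly_additive(self, landscape):
        spec = ScenarioSpec(label="w", period="x", warming_offset=2.0)
        out = generate_future_stack(landscape, spec)
        assert np.array_equal(
            out["tem_warmmon"].values, landscape["tem_warmmon"].values + 2.0
        )
        assert np.array_equal(out["annualprec"].values, landscape["annualprec"].values)

    def test_forest_conversion_count_and_reproducibility(self, landscape):
        n_forest = int((landscape["landcover"].values == FOREST).sum())
        spec = ScenarioSpec(label="c", period="x", forest_to_crop_rate=0.5, seed=4)
        out = generate_future_stack(landscape, spec)
        converted = int(
            ((landscape["landcover"].values == FOREST) & (out["landcover"].values == CROPLAND)).sum()
        )
        assert converted == round(0.5 * n_forest)
        again = generate_future_stack(landscape, spec)
        assert np.array_equal(out["landcover"].values, again["landcover"].values)

    def test_conversion_prefers_low_elevation(self, landscape):
        spec = ScenarioSpec(label="c", period="x", forest_to_crop_rate=0.3, seed=4)
        out = generate_future_stack(landscape, spec)
        forest_mask = landscape["landcover"].values == FOREST
        converted = forest_mask & (out["landcover"].values == CROPLAND)
        kept = forest_mask & (out["landcover"].values == FOREST)
        elev = landscape["elevation"].values
        assert elev[converted].mean() < elev[kept].mean()

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(label="x", period="y", forest_to_crop_rate=1.5)
        with pytest.raises(ValueError):
            ScenarioSpec(label="x", period="y", precip_factor=0.0)
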