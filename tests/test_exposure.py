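import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import secr1d as s

from .conftest import make_samples
from .oracles import normal_mass

GRID = s.LatitudeGrid(44.0, 0.01, 20)


class TestRelativeOccurrence:
    def test_point_mass_limit(self):
        occ = s.relative_occurrence(GRID.centroids[9], 1e-12, GRID)
        assert occ[9] == pytest.approx(1.0)
        assert occ.sum() == pytest.approx(1.0)

    def test_symmetry_on_shared_edge(self):
        occ = s.relative_occurrence(GRID.edges[10], 0.0004, GRID)
        assert occ[9] == pytest.approx(occ[10], rel=1e-12)

    def test_one_bin_width_sigma(self):
        c = GRID.centroids[9]
        occ = s.relative_occurrence(c, GRID.bin_width_deg ** 2, GRID)
        assert occ[9] == pytest.approx(norm.cdf(0.5) - norm.cdf(-0.5), rel=1e-10)

    def test_matches_scipy_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            C = rng.uniform(*GRID.extent)
            s2 = np.exp(rng.normal(-6, 1))
            np.testing.assert_allclose(s.relative_occurrence(C, s2, GRID),
                                       normal_mass(GRID.edges, C, np.sqrt(s2)),
                                       atol=1e-12)

    def test_mass_truncated_not_renormalised(self):
        occ = s.relative_occurrence(GRID.extent[0], 0.01, GRID)
        assert occ.sum() < 0.6  # half the kernel lies south of the grid

    def test_invalid_sigma2(self):
        with pytest.raises(ValueError):
            s.relative_occurrence(44.05, 0.0, GRID)


class TestRescaleResidency:
    def test_min_max(self):
        out = s.rescale_residency(np.array([0.0, 1.0, 2.0]), np.ones(3, int))
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_all_equal_maps_to_one(self):
        out = s.rescale_residency(np.full(3, 0.7), np.ones(3, int))
        np.testing.assert_allclose(out, 1.0)

    def test_absent_maps_to_zero(self):
        out = s.rescale_residency(np.array([5.0, -1.0, 3.0]),
                                  np.array([0, 1, 1]))
        assert out[0] == 0.0
        np.testing.assert_allclose(out[1:], [0.0, 1.0])

    def test_no_present_returns_zeros(self):
        out = s.rescale_residency(np.array([1.0, 2.0]), np.zeros(2, int))
        np.testing.assert_array_equal(out, 0.0)


class TestSpaceUse:
    def test_degenerate_posterior_equals_occurrence(self):
        C = np.full((4, 1, 1), GRID.centroids[5])
        samples = make_samples(C, np.full_like(C, 0.0004),
                               np.zeros_like(C), np.ones_like(C, int))
        field = s.space_use_distribution(samples, GRID)
        occ = s.relative_occurrence(GRID.centroids[5], 0.0004, GRID)
        np.testing.assert_allclose(
            field.sort_values("bin_index")["mean_weighted_occurrence"], occ,
            atol=1e-12)

    def test_two_iteration_hand_average(self):
        # R draws {0, 1} for two individuals => R' = {0.5-ish}; simpler: one
        # individual with known occ vectors and R' = {1, 0.5} via two
        # individuals anchoring the rescale
        C = np.array([[[GRID.centroids[3]], [GRID.centroids[12]]],
                      [[GRID.centroids[4]], [GRID.centroids[12]]]])
        s2 = np.full_like(C, 0.0009)
        R = np.array([[[1.0], [2.0]], [[0.0], [2.0]]])  # ind0 R'={0.5? no}
        samples = make_samples(C, s2, R, np.ones_like(C, int))
        field = s.space_use_distribution(samples, GRID)
        # iteration 1: R' ind0 = (1-1)/(2-1)... min-max over {1,2} -> 0, 1
        # iteration 2: over {0,2} -> 0, 1
        occ1 = s.relative_occurrence(C[0, 0, 0], 0.0009, GRID) * 0.0
        occ2 = s.relative_occurrence(C[1, 0, 0], 0.0009, GRID) * 0.0
        ind0 = field[field["individual_id"] == "ind0"].sort_values("bin_index")
        np.testing.assert_allclose(ind0["mean_weighted_occurrence"],
                                   (occ1 + occ2) / 2, atol=1e-12)
        occ_a = s.relative_occurrence(C[0, 1, 0], 0.0009, GRID)
        occ_b = s.relative_occurrence(C[1, 1, 0], 0.0009, GRID)
        ind1 = field[field["individual_id"] == "ind1"].sort_values("bin_index")
        np.testing.assert_allclose(ind1["mean_weighted_occurrence"],
                                   (occ_a + occ_b) / 2, atol=1e-12)

    def test_zero_residency_gives_zero_field(self):
        C = np.full((3, 1, 1), GRID.centroids[5])
        samples = make_samples(C, np.full_like(C, 0.001), np.zeros_like(C),
                               np.zeros_like(C, int))  # absent in every draw
        field = s.space_use_distribution(samples, GRID)
        assert (field["mean_weighted_occurrence"] == 0).all()


class TestLayers:
    def test_scale_layer(self):
        layer = s.StressorLayer("x", "static", values=np.array([2.0, 4.0]))
        scaled = s.scale_layer(layer)
        np.testing.assert_allclose(scaled.values, [0.5, 1.0])
        assert scaled.scaled

    def test_scaled_max_is_one_and_constant_case(self):
        rng = np.random.default_rng(0)
        layer = s.StressorLayer("x", "static", values=rng.uniform(0, 9, 20))
        assert s.scale_layer(layer).values.max() == pytest.approx(1.0)
        const = s.StressorLayer("c", "static", values=np.full(5, 3.3))
        np.testing.assert_allclose(s.scale_layer(const).values, 1.0)

    def test_all_zero_layer_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            s.scale_layer(s.StressorLayer("z", "static", values=np.zeros(4)))

    def test_dynamic_scaled_by_global_max(self):
        tab = pd.DataFrame({"bin_index": [1, 1, 2, 2], "year": [2016, 2017] * 2,
                            "month": [6, 6, 7, 7], "value": [1.0, 2.0, 3.0, 4.0]})
        scaled = s.scale_layer(s.StressorLayer("d", "dynamic", table=tab))
        np.testing.assert_allclose(scaled.table["value"], [0.25, 0.5, 0.75, 1.0])

    def test_proximity_proxy_geometry(self):
        src = GRID.centroids[4]
        layer = s.proximity_proxy(src, GRID)
        assert layer.values.argmax() == 4
        # symmetric bins around the source get equal values
        assert layer.values[2] == pytest.approx(layer.values[6])
        assert layer.values.min() == pytest.approx(0.0)
        assert layer.values[-1] == 0.0  # farthest bin

    def test_annualize_dynamic_mean_and_identity(self):
        tab = pd.DataFrame({"bin_index": [1, 1, 1, 2], "year": [2016] * 4,
                            "month": [6, 7, 8, 6], "value": [2.0, 4.0, 6.0, 5.0]})
        annual = s.annualize_dynamic(s.StressorLayer("d", "dynamic", table=tab))
        lookup = annual.set_index(["bin_index", "year"])["value"]
        assert lookup.loc[(1, 2016)] == pytest.approx(4.0)
        assert lookup.loc[(2, 2016)] == pytest.approx(5.0)  # single month

    def test_zones_to_bins_length_weighting(self):
        grid = s.LatitudeGrid(0.0, 0.01, 4)
        # two zones split at the middle of bin 2; densities 10 and 30 per km2
        edges = np.array([0.0, 0.015, 0.04])
        vals = np.array([10.0, 60.0])
        areas = np.array([1.0, 2.0])
        out = s.zones_to_bins(edges, vals, areas, grid)
        np.testing.assert_allclose(out, [10.0, 20.0, 30.0, 30.0])


class TestExposure:
    def test_hand_arithmetic_case(self):
        # occ = {0.5, 0.5}, s = {0.2, 0.4}, R' = 0.5 -> E = 0.15
        occ = np.array([0.5, 0.5])
        layer = np.array([0.2, 0.4])
        assert (occ * layer).sum() * 0.5 == pytest.approx(0.15)
        # same through the package path: C on the shared edge of a 2-bin
        # grid with huge mass inside, R' anchored to 0.5 by companions
        grid2 = s.LatitudeGrid(0.0, 0.5, 2)
        C = np.full((1, 3, 1), grid2.edges[1])
        s2 = np.full_like(C, 1e-4)  # essentially all mass inside, split 50/50
        R = np.array([[[1.0], [0.0], [2.0]]])
        samples = make_samples(C, s2, R, np.ones_like(C, int))
        layer_obj = s.StressorLayer("h", "static", values=np.array([0.2, 0.4]),
                                    scaled=True)
        draws = s.exposure_distribution(samples, layer_obj, grid2)
        assert draws[0, 0, 0] == pytest.approx(0.15, abs=1e-9)

    def test_bounds_upper_attained(self):
        grid2 = s.LatitudeGrid(0.0, 1.0, 2)
        C = np.full((1, 1, 1), 1.0)
        samples = make_samples(C, np.full_like(C, 1e-4),
                               np.zeros_like(C), np.ones_like(C, int))
        ones = s.StressorLayer("u", "static", values=np.ones(2), scaled=True)
        draws = s.exposure_distribution(samples, ones, grid2)
        assert draws[0, 0, 0] == pytest.approx(1.0)
        zeros = s.StressorLayer("z", "static", values=np.zeros(2), scaled=True)
        assert s.exposure_distribution(samples, zeros, grid2)[0, 0, 0] == 0.0

    def test_bounds_on_fitted_posterior(self, small_fit, small_data):
        layers = s.simulate_stressors(small_data["scenario"])
        grid = small_data["grid"]
        for layer in layers:
            draws = s.exposure_distribution(small_fit, s.scale_layer(layer), grid)
            assert np.all(draws >= 0.0) and np.all(draws <= 1.0 + 1e-12)

    def test_monotone_overlap_with_unimodal_layer(self):
        peak_bin = 10
        layer = s.StressorLayer(
            "bump", "static",
            values=np.exp(-0.5 * ((np.arange(20) - peak_bin) / 3.0) ** 2),
            scaled=True)
        exposures = []
        for shift in range(8):
            C = np.full((1, 1, 1), GRID.centroids[peak_bin + shift])
            samples = make_samples(C, np.full_like(C, 0.0016),
                                   np.zeros_like(C), np.ones_like(C, int))
            exposures.append(s.exposure_distribution(samples, layer, GRID)[0, 0, 0])
        assert np.all(np.diff(exposures) < 0)

    def test_point_mass_recovers_layer_value(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.1, 1.0, GRID.n_bins)
        vals[vals.argmax()] = 1.0
        layer = s.StressorLayer("r", "static", values=vals, scaled=True)
        k = 7
        n = 500
        C = GRID.centroids[k] + rng.normal(0, 1e-7, size=(n, 1, 1))
        samples = make_samples(C, np.full_like(C, 1e-12),
                               rng.normal(size=(n, 1, 1)), np.ones_like(C, int))
        draws = s.exposure_distribution(samples, layer, GRID)
        # R' = 1 for a lone individual, sigma ~ 0 -> exposure = layer at bin k
        assert np.median(draws) == pytest.approx(vals[k], abs=1e-6)

    def test_summaries_and_reference_lines(self, small_fit, small_data):
        layer = s.scale_layer(s.simulate_stressors(small_data["scenario"])[0])
        draws = s.exposure_distribution(small_fit, layer, small_data["grid"])
        summ = s.exposure_summaries(draws, small_fit, layer.name)
        assert (summ["lo90"] <= summ["median"]).all()
        assert (summ["median"] <= summ["hi90"]).all()
        from secr1d.exposure import exposure_reference_lines
        annual, overall = exposure_reference_lines(summ)
        assert overall == pytest.approx(summ["median"].mean())
        assert len(annual) == len(small_fit.years)
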