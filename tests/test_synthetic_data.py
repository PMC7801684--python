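import numpy as np
import pytest

from dipsdm.preprocess import correlation_filter
from dipsdm.synthetic_data import (
    ScenarioOffsets,
    TEMPERATURE_LAYER,
    generate_env_stack,
    generate_future,
    generate_landcover_and_pa,
    generate_species,
    sample_occurrences,
)
from dipsdm.core_rasters import RasterGrid


def corr(a, b):
    return np.corrcoef(a.ravel(), b.ravel())[0, 1]


class TestEnvStack:
    def test_same_seed_is_bit_identical(self):
        s1, d1 = generate_env_stack(32, 32, seed=5)
        s2, d2 = generate_env_stack(32, 32, seed=5)
        for name in s1.names:
            np.testing.assert_array_equal(s1.layers[name].values, s2.layers[name].values)
        np.testing.assert_array_equal(d1.values, d2.values)

    def test_different_seed_differs(self):
        s1, _ = generate_env_stack(32, 32, seed=5)
        s2, _ = generate_env_stack(32, 32, seed=6)
        assert not np.array_equal(s1.layers["bio01"].values, s2.layers["bio01"].values)

    def test_uncorrelated_bioclim_layers_have_low_sample_r(self, small_stack):
        bio = [n for n in small_stack.names if n.startswith("bio")]
        for i, a in enumerate(bio):
            for b in bio[i + 1 :]:
                r = corr(small_stack.layers[a].values, small_stack.layers[b].values)
                assert abs(r) < 0.3, (a, b, r)

    def test_high_cross_correlation_triggers_pruning(self):
        stack, _ = generate_env_stack(64, 64, cross_correlation=0.95, seed=3)
        bio = stack.subset([n for n in stack.names if n.startswith("bio")])
        r = corr(bio.layers["bio01"].values, bio.layers["bio02"].values)
        assert abs(r) > 0.7
        retained = correlation_filter(bio, r_threshold=0.7)
        assert len(retained) == len(bio.names) - 1
        assert ("bio01" in retained) ^ ("bio02" in retained)

    def test_dem_anticorrelated_with_temperature(self, small_stack_and_dem):
        stack, dem = small_stack_and_dem
        assert corr(dem.values, stack.layers[TEMPERATURE_LAYER].values) < -0.3

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_env_stack(8, 8)
        with pytest.raises(ValueError):
            generate_env_stack(32, 32, cross_correlation=1.0)


class TestSpecies:
    def test_zero_coefficients_give_flat_probability(self, small_stack):
        _, prob = generate_species(small_stack, {"bio01": 0.0}, prevalence_target=0.2)
        vals = prob.values[prob.valid_mask]
        assert np.allclose(vals, 0.2, atol=1e-6)

    @pytest.mark.parametrize("target", [0.05, 0.1, 0.3])
    def test_prevalence_calibration_tolerance(self, small_stack, target):
        _, prob = generate_species(small_stack, {"bio01": -2.0}, {"bio01": -1.0}, target)
        assert np.nanmean(prob.values) == pytest.approx(target, abs=1e-6)

    def test_doubling_coefficient_preserves_cell_ordering(self, small_stack):
        _, p1 = generate_species(small_stack, {"bio02": 1.0}, prevalence_target=0.15)
        _, p2 = generate_species(small_stack, {"bio02": 2.0}, prevalence_target=0.15)
        order1 = np.argsort(p1.values.ravel())
        order2 = np.argsort(p2.values.ravel())
        np.testing.assert_array_equal(order1, order2)


class TestOccurrenceSampling:
    def test_exhaustive_draw_hits_every_cell_once(self):
        prob = RasterGrid(np.full((10, 10), 0.5), x0=0, y0=10, dx=1, dy=1)
        occ = sample_occurrences(prob, 100, seed=1)
        rows, cols = prob.point_to_index(occ.points)
        assert len(set(zip(rows.tolist(), cols.tolist()))) == 100

    def test_bias_mask_restricts_support(self):
        prob = RasterGrid(np.full((10, 10), 0.5), x0=0, y0=10, dx=1, dy=1)
        bias = np.zeros((10, 10))
        bias[:5, :5] = 1.0  # north-west quadrant
        occ = sample_occurrences(prob, 20, sampling_bias=prob.like(bias), seed=2)
        assert (occ.points[:, 0] < 5).all() and (occ.points[:, 1] > 5).all()

    def test_with_replacement_frequencies_match_probabilities(self):
        prob = RasterGrid(np.array([[0.8, 0.2]]), x0=0, y0=1, dx=1, dy=1)
        occ = sample_occurrences(prob, 10_000, seed=3, replace=True)
        frac_first = np.mean(occ.points[:, 0] < 1.0)
        se = np.sqrt(0.8 * 0.2 / 10_000)
        assert abs(frac_first - 0.8) < 3 * se

    def test_oversampling_without_replacement_raises(self):
        prob = RasterGrid(np.array([[0.5, 0.0]]), x0=0, y0=1, dx=1, dy=1)
        with pytest.raises(ValueError, match="exceeds"):
            sample_occurrences(prob, 2, seed=0)


class TestLandCoverAndPA:
    def test_reclass_table_has_requested_unsuitable_count(self, small_stack):
        _, _, reclass = generate_landcover_and_pa(
            small_stack, n_classes=22, n_unsuitable=17, seed=0
        )
        assert len(reclass) == 22
        assert (reclass["suitable"] == 0).sum() == 17

    def test_zero_anthropogenic_fraction_marks_nothing_unsuitable(self, small_stack):
        _, _, reclass = generate_landcover_and_pa(
            small_stack, anthropogenic_fraction=0.0, n_unsuitable=0, seed=0
        )
        assert (reclass["suitable"] == 1).all()

    def test_pa_fraction_tolerance(self):
        stack, _ = generate_env_stack(128, 128, seed=11)
        _, pa, _ = generate_landcover_and_pa(stack, pa_fraction=0.15, seed=1)
        assert np.mean(pa.values == 1) == pytest.approx(0.15, abs=0.03)

    def test_every_class_in_raster_appears_in_table(self, small_stack):
        lc, _, reclass = generate_landcover_and_pa(small_stack, seed=4)
        present = set(np.unique(lc.values).astype(int))
        assert present <= set(reclass["class_id"].astype(int))


class TestFutureScenarios:
    def test_zero_noise_reproduces_offset_stack(self, small_stack):
        off = ScenarioOffsets("rcp85", shifts={"bio01": 2.0}, scales={"bio02": 1.1})
        futures = generate_future(small_stack, off, n_gcms=3, gcm_noise_sd=0.0, seed=0)
        for f in futures:
            np.testing.assert_allclose(
                f.layers["bio01"].values, small_stack.layers["bio01"].values + 2.0
            )
            np.testing.assert_allclose(
                f.layers["bio02"].values, small_stack.layers["bio02"].values * 1.1
            )

    def test_gcm_average_clt_scaling(self, small_stack):
        off = ScenarioOffsets("rcp45", shifts={"bio01": 1.0})
        sd = 0.2
        futures = generate_future(small_stack, off, n_gcms=5, gcm_noise_sd=sd, seed=2)
        mean = np.mean([f.layers["bio01"].values for f in futures], axis=0)
        target = small_stack.layers["bio01"].values + 1.0
        rms = np.sqrt(np.mean((mean - target) ** 2))
        assert rms < 3 * sd / np.sqrt(5)

    def test_additive_shift_moves_the_mean(self, small_stack):
        off = ScenarioOffsets("rcp85", shifts={"bio01": 2.0})
        futures = generate_future(small_stack, off, n_gcms=5, gcm_noise_sd=0.05, seed=3)
        delta = np.mean(
            [f.layers["bio01"].values.mean() for f in futures]
        ) - small_stack.layers["bio01"].values.mean()
        assert delta == pytest.approx(2.0, abs=0.1)

    def test_invalid_inputs_rejected(self, small_stack):
        with pytest.raises(ValueError):
            ScenarioOffsets("x", scales={"bio01": -1.0})
        with pytest.raises(ValueError):
            generate_future(small_stack, ScenarioOffsets("x"), n_gcms=0)
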