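import itertools

import numpy as np
import pytest

from dipsdm.core_rasters import EnvStack, OccurrenceSet, RasterGrid, pairwise_distance_km
from dipsdm.preprocess import (
    PreprocessConfig,
    average_gcms,
    correlation_filter,
    soil_pca,
    thin_occurrences,
)
from dipsdm.synthetic_data import ScenarioOffsets, generate_future

from conftest import make_stack


def brute_force_max_thinned(points: np.ndarray, thin_km: float) -> int:
    """Oracle: size of the maximum subset with all pairwise distances >=
    thin_km, by exhaustive subset enumeration."""
    n = len(points)
    d = pairwise_distance_km(points, points, "planar-km")
    best = 0
    for r in range(n, 0, -1):
        if r <= best:
            break
        for sub in itertools.combinations(range(n), r):
            ok = all(d[i, j] >= thin_km for i, j in itertools.combinations(sub, 2))
            if ok:
                best = r
                break
    return best


class TestThinning:
    def test_single_point_unchanged(self):
        occ = OccurrenceSet("sp", [[0.0, 0.0]])
        assert thin_occurrences(occ).n == 1

    def test_collinear_chain_keeps_endpoints(self):
        occ = OccurrenceSet("sp", [[0.0, 0.0], [5.0, 0.0], [12.0, 0.0]])
        out = thin_occurrences(occ, thin_km=10, seed=1)
        assert out.n == 2
        assert {0.0, 12.0} == set(out.points[:, 0])

    def test_postcondition_and_idempotence(self):
        rng = np.random.default_rng(7)
        occ = OccurrenceSet("sp", rng.uniform(0, 60, size=(40, 2)))
        out = thin_occurrences(occ, thin_km=10, seed=2)
        d = pairwise_distance_km(out.points, out.points, "planar-km")
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10
        again = thin_occurrences(out, thin_km=10, seed=3)
        np.testing.assert_array_equal(again.points, out.points)

    def test_output_is_subset_of_input(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 40, size=(25, 2))
        out = thin_occurrences(OccurrenceSet("sp", pts), thin_km=10, seed=0)
        in_set = {tuple(p) for p in pts}
        assert all(tuple(p) in in_set for p in out.points)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_maximum_independent_set_on_small_inputs(self, seed):
        rng = np.random.default_rng(100 + seed)
        pts = rng.uniform(0, 30, size=(10, 2))
        out = thin_occurrences(OccurrenceSet("sp", pts), thin_km=10, n_restarts=50, seed=seed)
        assert out.n == brute_force_max_thinned(pts, 10.0)


class TestCorrelationFilter:
    def test_independent_layers_all_retained(self):
        rng = np.random.default_rng(0)
        stack = make_stack({f"v{i}": rng.normal(size=(20, 20)) for i in range(4)})
        assert correlation_filter(stack) == [f"v{i}" for i in range(4)]

    def test_duplicate_layer_forces_single_drop(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 20))
        stack = make_stack({"a": a, "b": a.copy(), "c": rng.normal(size=(20, 20))})
        retained = correlation_filter(stack)
        assert "c" in retained and len(retained) == 2
        assert ("a" in retained) ^ ("b" in retained)

    def test_keep_list_conflict_raises_with_pair(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(20, 20))
        stack = make_stack({"a": a, "b": a + 1e-9 * rng.normal(size=(20, 20))})
        with pytest.raises(ValueError, match="keep_list pair"):
            correlation_filter(stack, keep_list=("a", "b"))

    def test_result_is_a_fixed_point(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(20, 20))
        stack = make_stack(
            {
                "a": base,
                "b": 0.95 * base + 0.1 * rng.normal(size=(20, 20)),
                "c": rng.normal(size=(20, 20)),
                "d": 0.9 * base + 0.2 * rng.normal(size=(20, 20)),
            }
        )
        retained = correlation_filter(stack)
        again = correlation_filter(stack.subset(retained))
        assert again == retained


class TestSoilPCA:
    def test_two_latent_fields_give_two_components(self):
        rng = np.random.default_rng(4)
        f1, f2 = rng.normal(size=(2, 30, 30))
        layers = {}
        for i in range(8):
            w = f1 if i % 2 == 0 else f2
            layers[f"s{i}"] = w + 0.05 * rng.normal(size=(30, 30))
        pca, pcs = soil_pca(make_stack(layers), pca_var_target=0.90)
        assert pca.n_components_kept == 2
        assert len(pcs.names) == 2

    def test_duplicated_pair_is_rank_one(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(15, 15))
        pca, _ = soil_pca(make_stack({"a": a, "b": a.copy()}))
        assert pca.n_components_kept == 1
        assert pca.explained_fraction[0] == pytest.approx(1.0)

    def test_pc_rasters_mutually_uncorrelated(self, small_stack):
        soil = small_stack.subset([n for n in small_stack.names if n.startswith("soil")])
        _, pcs = soil_pca(soil)
        table, _ = pcs.table()
        corr = np.corrcoef(table, rowvar=False)
        off = corr[~np.eye(len(pcs.names), dtype=bool)]
        assert np.abs(off).max() < 1e-6

    def test_constant_layer_rejected(self):
        rng = np.random.default_rng(6)
        stack = make_stack({"a": rng.normal(size=(10, 10)), "b": np.full((10, 10), 3.0)})
        with pytest.raises(ValueError, match="zero variance"):
            soil_pca(stack)

    def test_explained_fractions_nonincreasing(self, small_stack):
        soil = small_stack.subset([n for n in small_stack.names if n.startswith("soil")])
        pca, _ = soil_pca(soil)
        assert (np.diff(pca.explained_fraction) <= 1e-12).all()
        assert pca.explained_fraction.sum() <= 1 + 1e-9


class TestAverageGcms:
    def test_single_stack_is_identity(self, small_stack):
        avg = average_gcms([small_stack])
        for n in small_stack.names:
            np.testing.assert_array_equal(avg.layers[n].values, small_stack.layers[n].values)

    def test_constant_stacks_average(self):
        s1 = make_stack({"a": np.full((5, 5), 1.0)})
        s3 = make_stack({"a": np.full((5, 5), 3.0)})
        avg = average_gcms([s1, s3])
        np.testing.assert_allclose(avg.layers["a"].values, 2.0)

    def test_mean_of_noisy_gcms_near_offset_stack(self, small_stack):
        off = ScenarioOffsets("rcp45", shifts={"bio01": 1.5})
        futures = generate_future(small_stack, off, n_gcms=5, gcm_noise_sd=0.1, seed=9)
        avg = average_gcms(futures)
        target = small_stack.layers["bio01"].values + 1.5
        rms = np.sqrt(np.mean((avg.layers["bio01"].values - target) ** 2))
        assert rms < 3 * 0.1 / np.sqrt(5)

    def test_empty_and_mismatched_rejected(self, small_stack):
        with pytest.raises(ValueError):
            average_gcms([])
        other = make_stack({"zzz": np.zeros((64, 64))}, cell_km=4.0)
        with pytest.raises(ValueError):
            average_gcms([small_stack, other])

    def test_nodata_propagates(self):
        a = np.ones((4, 4))
        b = np.ones((4, 4))
        b[1, 1] = np.nan
        avg = average_gcms([make_stack({"x": a}), make_stack({"x": b})])
        assert np.isnan(avg.layers["x"].values[1, 1])
        assert avg.layers["x"].values[0, 0] == 1.0


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(thin_km=0)
    with pytest.raises(ValueError):
        PreprocessConfig(r_threshold=1.2)
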