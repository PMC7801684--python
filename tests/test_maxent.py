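import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from dipsdm.maxent import (
    ModelConfig,
    build_features,
    default_reg_scalar,
    feature_penalties,
    fit_from_covariates,
    fit_maxent,
    penalized_objective,
)


def toy_problem(n_bg=6, n_pres=3, n_cov=1, seed=0):
    rng = np.random.default_rng(seed)
    bg = rng.uniform(0, 1, size=(n_bg, n_cov))
    pres = rng.uniform(0.4, 1, size=(n_pres, n_cov))
    return pres, bg


class TestFeatureExpansion:
    def test_linear_quadratic_count(self):
        _, bg = toy_problem(n_cov=2, n_bg=20)
        exp = build_features(bg, ["a", "b"], "LQ")
        assert exp.n_features == 4

    def test_lqph_combinatorics(self):
        _, bg = toy_problem(n_cov=3, n_bg=30)
        exp = build_features(bg, ["a", "b", "c"], "LQPH", n_hinge_knots=10)
        # 3 linear + 3 quadratic + 3 products + 3 covariates * 2 * 10 hinges
        assert exp.n_features == 69

    def test_hinge_endpoint_values(self):
        bg = np.linspace(0, 1, 50)[:, None]
        exp = build_features(bg, ["x"], "H", n_hinge_knots=3)
        fwd = [(k, i, a) for (k, i, a) in exp.features if k == "hinge_fwd"]
        knot = fwd[0][2]
        design = exp.raw_design(np.array([[knot], [1.0]]))
        col = exp.features.index(fwd[0])
        assert design[0, col] == pytest.approx(0.0)
        assert design[1, col] == pytest.approx(1.0)

    def test_features_rescaled_to_unit_interval_over_background(self):
        _, bg = toy_problem(n_cov=2, n_bg=40, seed=3)
        exp = build_features(bg, ["a", "b"], "LQPH", n_hinge_knots=4)
        F = exp.transform(bg)
        assert F.min() >= 0 and F.max() <= 1 + 1e-12

    def test_constant_covariate_dropped_with_warning(self):
        bg = np.column_stack([np.linspace(0, 1, 20), np.full(20, 2.0)])
        with pytest.warns(UserWarning, match="constant"):
            exp = build_features(bg, ["a", "const"], "L")
        assert exp.covariate_names == ["a"]


class TestRegularization:
    def test_scalar_interpolation_by_sample_size(self):
        assert default_reg_scalar("linear", 10) == pytest.approx(1.0)
        assert default_reg_scalar("linear", 100) == pytest.approx(0.05)
        assert default_reg_scalar("linear", 65) == pytest.approx((0.2 + 0.05) / 2)
        assert default_reg_scalar("hinge", 50) == pytest.approx(0.5)

    def test_huge_multiplier_shrinks_everything_to_uniform(self):
        pres, bg = toy_problem(n_bg=50, n_pres=10)
        model = fit_from_covariates(pres, bg, ["x"], ModelConfig("L", reg_multiplier=1e6))
        assert np.all(model.beta == 0)
        raw = model.predict_cov(bg, output="raw")
        np.testing.assert_allclose(raw, 1.0 / len(bg))


class TestFitting:
    def test_one_feature_matches_golden_section_oracle(self):
        pres, bg = toy_problem(n_bg=6, n_pres=3, seed=1)
        config = ModelConfig("L", reg_multiplier=0.01, convergence_tol=1e-10)
        exp = build_features(bg, ["x"], "L")
        F_p, F_b = exp.transform(pres), exp.transform(bg)
        lam = feature_penalties(exp, F_b, len(pres), 0.01)
        model = fit_maxent(F_p, F_b, config, exp)
        oracle = minimize_scalar(
            lambda b: penalized_objective(np.array([b]), F_p, F_b, lam),
            bounds=(-50, 50), method="bounded",
            options={"xatol": 1e-12},
        )
        assert model.beta[0] == pytest.approx(oracle.x, abs=1e-4)

    def test_positive_score_gives_positive_coefficient(self):
        # feature 1 at all presences, background mean 0.5
        F_p = np.ones((5, 1))
        F_b = np.concatenate([np.ones(25), np.zeros(25)])[:, None]
        exp = build_features(F_b, ["x"], "L")
        model = fit_maxent(exp.transform(F_p), exp.transform(F_b), ModelConfig("L"), exp)
        assert model.beta[0] > 0

    def test_raw_prediction_sums_to_one_over_training_background(self):
        pres, bg = toy_problem(n_bg=200, n_pres=30, n_cov=2, seed=2)
        model = fit_from_covariates(pres, bg, ["a", "b"], ModelConfig("LQ"))
        assert model.predict_cov(bg, output="raw").sum() == pytest.approx(1.0, abs=1e-9)

    def test_objective_monotonically_nonincreasing(self):
        pres, bg = toy_problem(n_bg=300, n_pres=40, n_cov=3, seed=4)
        model = fit_from_covariates(
            pres, bg, ["a", "b", "c"], ModelConfig("LQH", n_hinge_knots=5)
        )
        path = np.asarray(model.objective_path)
        assert (np.diff(path) <= 1e-10).all()

    def test_separable_problem_without_penalty_hits_iteration_cap(self):
        # presences and background are perfectly separated in x; with an
        # (effectively) zero penalty the likelihood has no finite optimum.
        pres = np.linspace(0.8, 1.0, 5)[:, None]
        bg = np.linspace(0.0, 0.5, 30)[:, None]
        config = ModelConfig(
            "L", reg_multiplier=1e-12, max_iterations=25, convergence_tol=1e-14
        )
        with pytest.warns(UserWarning, match="max_iterations"):
            model = fit_from_covariates(pres, bg, ["x"], config)
        assert not model.converged
        assert abs(model.beta[0]) > 5

    @pytest.mark.parametrize("fc,n_cov,seed", [("L", 2, 0), ("LQ", 1, 1), ("L", 3, 2)])
    def test_small_instance_matches_convex_oracle(self, fc, n_cov, seed):
        """On <=8-cell instances the fitted objective matches an independent
        convex solver (L-BFGS-B on the positive/negative split) to 1e-3."""
        rng = np.random.default_rng(seed)
        bg = rng.uniform(0, 1, size=(8, n_cov))
        pres = rng.uniform(0, 1, size=(3, n_cov))
        config = ModelConfig(fc, reg_multiplier=0.5, convergence_tol=1e-9)
        exp = build_features(bg, [f"c{i}" for i in range(n_cov)], fc)
        F_p, F_b = exp.transform(pres), exp.transform(bg)
        lam = feature_penalties(exp, F_b, len(pres), 0.5)
        model = fit_maxent(F_p, F_b, config, exp)
        fitted = penalized_objective(model.beta, F_p, F_b, lam)

        k = F_b.shape[1]

        def split_obj(z):
            beta = z[:k] - z[k:]
            return penalized_objective(beta, F_p, F_b, lam)

        res = minimize(
            split_obj, np.zeros(2 * k), method="L-BFGS-B",
            bounds=[(0, None)] * (2 * k), options={"ftol": 1e-15, "gtol": 1e-12},
        )
        assert fitted == pytest.approx(res.fun, abs=1e-3)
        # local optimality under coordinate perturbation
        for j in range(k):
            for eps in (1e-3, -1e-3):
                pert = model.beta.copy()
                pert[j] += eps
                assert penalized_objective(pert, F_p, F_b, lam) >= fitted - 1e-9

    def test_missing_covariate_layer_raises_on_predict(self, small_stack):
        from dipsdm.maxent import predict

        pres, bg = toy_problem(n_bg=50, n_pres=10)
        model = fit_from_covariates(pres, bg, ["not_a_layer"], ModelConfig("L"))
        with pytest.raises(ValueError, match="missing covariate"):
            predict(model, small_stack)

    def test_serialization_round_trip(self, tmp_path):
        pres, bg = toy_problem(n_bg=60, n_pres=10, n_cov=2, seed=5)
        model = fit_from_covariates(pres, bg, ["a", "b"], ModelConfig("LQH", n_hinge_knots=3))
        path = tmp_path / "model.json"
        model.save(path)
        from dipsdm.maxent import MaxEntModel

        back = MaxEntModel.load(path)
        np.testing.assert_allclose(back.beta, model.beta)
        np.testing.assert_allclose(
            back.predict_cov(bg), model.predict_cov(bg), atol=1e-12
        )
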