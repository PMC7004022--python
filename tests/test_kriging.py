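"""Kriging model: kernel, concentrated likelihood, PSO, prediction, gradients."""

import numpy as np
import pytest

from aquakrig.geometry import features_from_positions
from aquakrig.kriging import (
    LOGLIKE_CAP,
    Kriging,
    KrigingResults,
    PSOSettings,
    SCurve,
    extract_features,
    kernel,
    mae,
    pso_optimize,
    s_curve,
    train,
)


@pytest.fixture(scope="module")
def toy_features(rng=None):
    r = np.random.default_rng(0)
    return r.uniform([0.8, 0.8, 1.5], [1.15, 1.15, 2.2], size=(40, 3))


class TestKernel:
    def test_zero_distance_gives_one(self):
        f = np.array([0.9, 1.0, 1.8])
        assert kernel(f, f, [1.0, 2.0, 3.0], [2, 2, 2]) == 1.0

    def test_single_term_closed_form(self):
        f1 = np.array([0.0, 0.5, 0.5])
        f2 = np.array([1.0, 0.5, 0.5])
        val = kernel(f1, f2, [1.0, 5.0, 5.0], [2.0, 1.0, 1.0])
        assert val == pytest.approx(np.exp(-1.0), rel=1e-14)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            fi, fj = rng.normal(size=(2, 3))
            theta = rng.uniform(0.1, 10, 3)
            p = rng.uniform(0.5, 2.0, 3)
            assert kernel(fi, fj, theta, p) == pytest.approx(
                kernel(fj, fi, theta, p), rel=1e-14
            )

    def test_invalid_hyperparameters_rejected(self):
        f = np.zeros(3)
        with pytest.raises(ValueError):
            kernel(f, f, [0.0, 1, 1], [2, 2, 2])
        with pytest.raises(ValueError):
            kernel(f, f, [1, 1, 1], [2.5, 2, 2])


class TestConcentratedLogLikelihood:
    def test_two_point_hand_formula(self):
        # N = 2: R = [[1+eta, k], [k, 1+eta]]; mu = mean(y) by symmetry
        F = np.array([[0.9, 0.9, 1.8], [1.0, 1.1, 1.9]])
        y = np.array([1.0, 3.0])
        theta = np.array([2.0, 1.0, 0.5])
        m = Kriging(y, F, nugget_rel=1e-8)
        eta = m.nugget_abs
        d = np.abs(F[0] - F[1])
        k = np.exp(-np.sum(theta * d**2))
        mu = 2.0
        resid = y - mu
        Rm = np.array([[1 + eta, k], [k, 1 + eta]])
        sigma2 = float(resid @ np.linalg.solve(Rm, resid)) / 2
        expected = -np.log(sigma2) - 0.5 * np.log(np.linalg.det(Rm))
        assert m.loglike_concentrated(theta, 2.0) == pytest.approx(expected, rel=1e-10)

    def test_constant_targets_capped(self, toy_features):
        m = Kriging(np.full(len(toy_features), 7.0), toy_features)
        assert m.loglike_concentrated(np.array([1.0, 1.0, 1.0]), 2.0) == LOGLIKE_CAP

    def test_shift_invariance_through_trend(self, toy_features):
        # var(y + c) = var(y), so both models carry the same nugget
        y = np.sin(toy_features[:, 0] * 6)
        theta = np.array([100.0, 20.0, 20.0])
        a = Kriging(y, toy_features).loglike_concentrated(theta, 2.0)
        b = Kriging(y + 123.456, toy_features).loglike_concentrated(theta, 2.0)
        assert b == pytest.approx(a, rel=1e-9)


class TestPSO:
    def test_recovers_quadratic_optimum(self):
        x0 = np.array([0.3, -1.2, 2.0])
        best, val = pso_optimize(
            lambda x: -np.sum((x - x0) ** 2),
            bounds=np.array([[-5, 5]] * 3, dtype=float),
            swarm_size=30,
            iterations=200,
            rng_seed=3,
        )
        assert np.allclose(best, x0, atol=1e-3)
        assert val == pytest.approx(0.0, abs=1e-5)

    def test_deterministic(self):
        obj = lambda x: -float(np.sum(x**2))  # noqa: E731
        b = np.array([[-1, 1], [-1, 1]], dtype=float)
        r1 = pso_optimize(obj, b, 10, 50, rng_seed=7)
        r2 = pso_optimize(obj, b, 10, 50, rng_seed=7)
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1]

    def test_all_nonfinite_start_rejected(self):
        with pytest.raises(ValueError):
            pso_optimize(lambda x: -np.inf, np.array([[0, 1]]), 5, 10, rng_seed=0)

    def test_fixed_p_stays_at_two(self, small_labelled):
        res = train(
            small_labelled[:30], "energy", 0, optimize_p=False,
            pso=PSOSettings(swarm_size=10, iterations=30), rng_seed=1,
        )
        assert np.all(res.p == 2.0)

    def test_optimize_p_within_bounds(self, small_labelled):
        res = train(
            small_labelled[:30], "moment", 0, 0, optimize_p=True,
            pso=PSOSettings(swarm_size=12, iterations=40), rng_seed=1,
        )
        assert np.all((res.p >= 0.5) & (res.p <= 2.0))


class TestTrainPredict:
    def test_training_points_reproduced(self, small_labelled):
        res = train(
            small_labelled[:40], "energy", 1,
            pso=PSOSettings(swarm_size=16, iterations=60), rng_seed=4,
        )
        # exact kriging identity: residual_i = nugget * weight_i
        tol = 10.0 * res.nugget * np.max(np.abs(res.weights)) + 1e-10
        assert res.training_residual() <= tol

    def test_constant_targets(self, toy_features):
        res = Kriging(np.full(len(toy_features), 4.2), toy_features).fit(
            theta=np.array([1.0, 1.0, 1.0])
        )
        assert res.mu == pytest.approx(4.2, abs=1e-10)
        assert np.allclose(res.weights, 0.0, atol=1e-10)

    def test_duplicate_features_zero_nugget_rejected(self):
        F = np.array([[0.9, 0.9, 1.8]] * 2 + [[1.0, 1.0, 1.9]])
        with pytest.raises(ValueError, match="nugget"):
            Kriging(np.array([1.0, 2.0, 3.0]), F, nugget_rel=0.0)

    def test_far_from_training_reverts_to_trend(self, small_labelled):
        res = train(
            small_labelled[:30], "energy", 0,
            pso=PSOSettings(swarm_size=10, iterations=30), rng_seed=2,
        )
        far = np.array([50.0, 50.0, 3.0])
        assert res.predict(far) == pytest.approx(res.mu, rel=1e-10)

    def test_smooth_1d_function_vs_reference_gp(self):
        # independent oracle: scikit-learn Gaussian process on the same data
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        rng = np.random.default_rng(8)
        x = np.linspace(0.0, np.pi, 20)
        F = np.column_stack([x, np.full_like(x, 1.0), np.full_like(x, 1.8)])
        y = np.sin(3 * x)
        res = Kriging(y, F, nugget_rel=1e-10).fit(rng_seed=5)
        xv = rng.uniform(0.1, np.pi - 0.1, 200)
        Fv = np.column_stack([xv, np.full_like(xv, 1.0), np.full_like(xv, 1.8)])
        pred = res.predict(Fv)

        gp = GaussianProcessRegressor(
            kernel=ConstantKernel(1.0, (1e-3, 1e4)) * RBF(0.5, (1e-2, 1e2)),
            alpha=1e-10,
            normalize_y=True,
            random_state=0,
        ).fit(x[:, None], y)
        ref = gp.predict(xv[:, None])
        assert np.sqrt(np.mean((pred - np.sin(3 * xv)) ** 2)) < 1e-3
        assert np.sqrt(np.mean((pred - ref) ** 2)) < 1e-3

    def test_gradient_matches_finite_differences(self, standard_models, small_labelled):
        res = standard_models.energy[0]
        h = 1e-5
        worst = 0.0
        for lc in small_labelled[:20]:
            pos = lc.config.positions
            g = res.predict_gradient(pos)
            fd = np.zeros((3, 3))
            for a in range(3):
                for c in range(3):
                    d = np.zeros((3, 3))
                    d[a, c] = h
                    fd[a, c] = (
                        res.predict(features_from_positions(pos + d))
                        - res.predict(features_from_positions(pos - d))
                    ) / (2 * h)
            worst = max(worst, np.max(np.abs(g - fd)) / max(np.max(np.abs(fd)), 1e-10))
        assert worst < 1e-5

    def test_gradient_requires_smooth_kernel(self, toy_features):
        res = Kriging(np.sin(toy_features[:, 0]), toy_features).fit(
            theta=np.array([1.0, 1.0, 1.0]), p=np.array([1.5, 2.0, 2.0])
        )
        with pytest.raises(ValueError, match="p = 2"):
            res.predict_feature_gradient(np.array([0.9, 0.9, 1.8]))

    def test_translation_gives_zero_net_gradient(self, standard_models, small_labelled):
        res = standard_models.energy[2]
        g = res.predict_gradient(small_labelled[3].config.positions)
        assert np.allclose(g.sum(axis=0), 0.0, atol=1e-10)

    def test_serialization_round_trip(self, tmp_path, standard_models):
        res = standard_models.energy[0]
        path = tmp_path / "model.json"
        res.save(path)
        back = KrigingResults.load(path)
        f = np.array([0.95, 1.0, 1.85])
        assert back.predict(f) == pytest.approx(res.predict(f), rel=1e-14)

    def test_corrupted_model_rejected(self, tmp_path, standard_models):
        path = tmp_path / "model.json"
        standard_models.energy[0].save(path)
        import json

        doc = json.loads(path.read_text())
        doc["weights"] = doc["weights"][:-3]
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError):
            KrigingResults.load(path)

    def test_summary_mentions_key_quantities(self, standard_models):
        text = standard_models.energy[0].summary()
        assert "theta" in text and "N_trn" in text and "energy:O" in text


class TestValidationDiagnostics:
    def test_perfect_model_vertical_scurve(self, small_labelled):
        class Exact:
            def __init__(self, atom):
                self.atom = atom

            def predict(self, feats):
                from aquakrig.surrogate import partition_atomic_energies

                return np.array(
                    [
                        lc.atomic_energies[self.atom]
                        for lc in small_labelled[:20]
                    ]
                )

        models = [Exact(a) for a in range(3)]
        sc = s_curve(models, small_labelled[:20], "energy")
        assert np.allclose(sc.errors, 0.0, atol=1e-12)
        assert sc.cumulative_percent[-1] == pytest.approx(100.0)

    def test_scurve_monotone_and_median(self, standard_models, small_labelled):
        sc = s_curve(standard_models.energy, small_labelled[:100], "energy")
        assert np.all(np.diff(sc.errors) >= 0)
        assert np.all(np.diff(sc.cumulative_percent) > 0)
        assert sc.cumulative_percent[-1] == pytest.approx(100.0)
        assert sc.median_error == pytest.approx(np.percentile(sc.errors, 50), rel=1e-9)

    def test_mae_arithmetic(self):
        class Fixed:
            def __init__(self, vals):
                self.vals = np.asarray(vals)

            def predict(self, feats):
                return self.vals

        class LC:
            def __init__(self, e):
                from aquakrig.geometry import seed_configuration

                self.config = seed_configuration()
                self.atomic_energies = np.array([e, 0.0, 0.0])

            @property
            def molecular_energy(self):
                return float(np.sum(self.atomic_energies))

        labelled = [LC(1.0), LC(2.0)]
        models = [Fixed([1.2, 2.4]), Fixed([0, 0]), Fixed([0, 0])]
        assert mae(models, labelled, "energy") == pytest.approx(0.3)

    def test_empty_validation_rejected(self, standard_models):
        with pytest.raises(ValueError):
            mae(standard_models.energy, [], "energy")

    def test_scurve_invariant_enforced(self):
        with pytest.raises(ValueError):
            SCurve(np.array([0.1, 0.2]), np.array([50.0, 99.0]))
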