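import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from enmshift.engine import (
    MaxEntFitter,
    fit_maxent,
    logistic_output,
    project,
    raw_output,
    response_curve,
    training_gain,
)
from enmshift.features import (
    FeatureSpec,
    RegularizationWeights,
    TrainingStats,
    expand_features,
    regularization_weights,
)
from enmshift.geodata import EnvStack, GridHeader, Raster


def scipy_objective_max(Xp, Xb, beta):
    """Independent oracle: maximize the penalized objective with L-BFGS-B
    on the positive/negative split parametrization."""
    n = Xp.shape[1]

    def negJ(ab):
        eta = ab[:n] - ab[n:]
        return -(Xp @ eta).mean() + logsumexp(Xb @ eta) + beta @ (ab[:n] + ab[n:])

    res = minimize(
        negJ, np.zeros(2 * n), bounds=[(0, None)] * 2 * n, method="L-BFGS-B",
        options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return -res.fun


def small_problem(seed=3, n_bg=200, m=20, fc="LQ"):
    rng = np.random.default_rng(seed)
    bg = pd.DataFrame({"x": rng.normal(0, 1, n_bg)})
    pres = pd.DataFrame({"x": rng.normal(0.8, 0.5, m)})
    spec = FeatureSpec.from_label(fc, hinge_knots=2, threshold_knots=2)
    stats = TrainingStats.from_background(bg, spec)
    stats.finalize(spec, bg, pres)
    fp = expand_features(pres, spec, stats)
    fb = expand_features(bg, spec, stats)
    w = regularization_weights(fp, stats, m, 1.0)
    return fp, fb, w


class TestSolver:
    def test_total_shrinkage_uniform_model(self):
        fp, fb, w = small_problem()
        huge = RegularizationWeights(beta=np.full(fp.n_features, 1e6), rm=1.0)
        model, diag = fit_maxent(fp, fb, huge)
        assert np.all(model.coefficients == 0.0)
        assert np.isclose(model.entropy_H, np.log(model.n_background))
        np.testing.assert_allclose(raw_output(model, fb), 1.0 / model.n_background)

    def test_no_signal_small_coefficients(self):
        rng = np.random.default_rng(1)
        bg = pd.DataFrame({"x": rng.normal(0, 1, 500), "y": rng.normal(0, 1, 500)})
        pres = bg.sample(100, random_state=2).reset_index(drop=True)
        fitter = MaxEntFitter(FeatureSpec.from_label("LQ"), rm=1.0)
        model, _ = fitter.fit(pres, bg)
        fm_p = expand_features(pres, model.spec, model.stats)
        fm_b = expand_features(bg, model.spec, model.stats)
        from enmshift.tuning import auc

        a = auc(logistic_output(model, fm_p), logistic_output(model, fm_b))
        assert abs(a - 0.5) < 0.1

    @pytest.mark.parametrize("seed,fc", [(3, "LQ"), (11, "LQ"), (5, "LQH")])
    def test_objective_matches_independent_optimizer(self, seed, fc):
        fp, fb, w = small_problem(seed=seed, fc=fc)
        model, diag = fit_maxent(fp, fb, w, max_iter=50000, tol=1e-12)
        oracle = scipy_objective_max(fp.X, fb.X, w.beta)
        assert abs(diag.objective - oracle) < 1e-6

    def test_kkt_conditions_hold(self):
        fp, fb, w = small_problem(seed=7)
        model, _ = fit_maxent(fp, fb, w, max_iter=50000, tol=1e-12)
        p = np.exp(fb.X @ model.coefficients - model.log_partition)
        grad = fp.X.mean(axis=0) - p @ fb.X
        for eta_j, g_j, b_j in zip(model.coefficients, grad, w.beta):
            if eta_j == 0.0:
                assert abs(g_j) <= b_j + 1e-5
            else:
                assert abs(g_j - b_j * np.sign(eta_j)) <= 1e-5

    def test_ledger_sums_to_total_improvement(self):
        fp, fb, w = small_problem(seed=9)
        model, diag = fit_maxent(fp, fb, w)
        start = -np.log(fb.n_samples)  # objective of the all-zero model
        assert (diag.gain_ledger >= 0).all()
        assert abs(diag.gain_ledger.sum() - (diag.objective - start)) < 1e-6

    def test_shrinkage_monotone_in_rm(self):
        rng = np.random.default_rng(12)
        bg = pd.DataFrame({"x": rng.normal(0, 1, 300), "y": rng.uniform(0, 1, 300)})
        pres = pd.DataFrame({"x": rng.normal(1, 0.5, 25), "y": rng.uniform(0.3, 0.8, 25)})
        k_prev = np.inf
        for rm in (0.5, 1.0, 2.0, 4.0):
            fitter = MaxEntFitter(FeatureSpec.from_label("LQH", hinge_knots=6), rm=rm)
            model, _ = fitter.fit(pres, bg)
            assert model.k_params <= k_prev
            k_prev = model.k_params

    def test_nonfinite_features_error(self):
        fp, fb, w = small_problem()
        fp.X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_maxent(fp, fb, w)


class TestOutputs:
    def test_raw_normalizes_over_background(self, toy_fit):
        model, _, pres, bg = toy_fit
        bg_all = pd.concat([bg, pres], ignore_index=True)
        fm_bg = expand_features(bg_all, model.spec, model.stats)
        assert abs(raw_output(model, fm_bg).sum() - 1.0) < 1e-9

    def test_logistic_monotone_in_raw(self, toy_fit):
        model, _, pres, bg = toy_fit
        fm = expand_features(bg, model.spec, model.stats)
        r = raw_output(model, fm)
        l = logistic_output(model, fm)
        order = np.argsort(r)
        assert np.all(np.diff(l[order]) >= 0)
        np.testing.assert_allclose(
            l, (np.exp(model.entropy_H) * r) / (1 + np.exp(model.entropy_H) * r)
        )

    def test_uniform_model_logistic_half(self):
        fp, fb, w = small_problem()
        huge = RegularizationWeights(beta=np.full(fp.n_features, 1e6), rm=1.0)
        model, _ = fit_maxent(fp, fb, huge)
        np.testing.assert_allclose(logistic_output(model, fb), 0.5)

    def test_training_gain_zero_for_uniform(self):
        fp, fb, w = small_problem()
        huge = RegularizationWeights(beta=np.full(fp.n_features, 1e6), rm=1.0)
        model, _ = fit_maxent(fp, fb, huge)
        assert abs(training_gain(model, fp)) < 1e-12

    def test_fitted_gain_nonnegative_and_recomputable(self, toy_fit):
        model, _, pres, bg = toy_fit
        fm_p = expand_features(pres, model.spec, model.stats)
        g = training_gain(model, fm_p)
        assert g >= 0
        manual = np.log(raw_output(model, fm_p)).mean() + np.log(model.n_background)
        assert abs(g - manual) < 1e-12


class TestProjection:
    @pytest.fixture
    def fitted_world(self, world, presences):
        current, scenarios, niche = world
        from enmshift.workflow import _presence_table, sample_background

        bg = sample_background(current, 1000, seed=3)
        pres = _presence_table(current, presences)
        fitter = MaxEntFitter(FeatureSpec.from_label("LQ"), rm=1.0, max_iter=2000)
        model, _ = fitter.fit(pres, bg)
        return model, current, scenarios

    def test_projection_consistent_with_logistic_output(self, fitted_world):
        model, current, _ = fitted_world
        rast = project(model, current, clamp=False)
        mask = current.joint_mask()
        table = pd.DataFrame({v: current[v].values[mask] for v in model.stats.variables})
        fm = expand_features(table, model.spec, model.stats)
        np.testing.assert_allclose(rast.values[mask], logistic_output(model, fm))

    def test_clamped_projection_equals_boundary_value(self, fitted_world):
        model, current, _ = fitted_world
        hdr = current.header
        # push one variable far out of training range in a copy of the stack
        vals = {v: current[v].values.copy() for v in current.names}
        vals["temp"][0, 0] = model.stats.var_max["temp"] + 50.0
        stack2 = EnvStack({v: Raster(hdr, a) for v, a in vals.items()})
        rast2 = project(model, stack2, clamp=True)
        vals3 = {v: current[v].values.copy() for v in current.names}
        vals3["temp"][0, 0] = model.stats.var_max["temp"]
        stack3 = EnvStack({v: Raster(hdr, a) for v, a in vals3.items()})
        rast3 = project(model, stack3, clamp=True)
        assert rast2.values[0, 0] == rast3.values[0, 0]

    def test_future_projection_differs_only_where_inputs_changed(self, fitted_world):
        model, current, _ = fitted_world
        hdr = current.header
        vals = {v: current[v].values.copy() for v in current.names}
        vals["temp"][10:20, 10:20] += 1.0  # perturb a block
        stack2 = EnvStack({v: Raster(hdr, a) for v, a in vals.items()})
        r1 = project(model, current, clamp=True)
        r2 = project(model, stack2, clamp=True)
        changed = r1.values != r2.values
        block = np.zeros_like(changed)
        block[10:20, 10:20] = True
        assert changed[block].any()
        assert not changed[~block].any()

    def test_missing_variable_errors(self, fitted_world):
        model, current, _ = fitted_world
        partial = EnvStack({"temp": current["temp"]})
        with pytest.raises(KeyError, match="precip"):
            project(model, partial)


class TestResponseCurve:
    def test_single_positive_linear_feature_monotone(self):
        rng = np.random.default_rng(4)
        bg = pd.DataFrame({"x": rng.uniform(0, 1, 300)})
        spec = FeatureSpec.from_label("L")
        stats = TrainingStats.from_background(bg, spec)
        pres = pd.DataFrame({"x": rng.uniform(0.7, 1.0, 30)})
        stats.finalize(spec, bg, pres)
        fp = expand_features(pres, spec, stats)
        fb = expand_features(bg, spec, stats)
        w = regularization_weights(fp, stats, 30, 1.0)
        model, _ = fit_maxent(fp, fb, w)
        model.spec, model.stats = spec, stats
        assert model.coefficients[0] > 0
        curve = response_curve(model, "x", n_points=50)
        assert len(curve) == 50
        assert (curve["suitability"].between(0, 1)).all()
        assert curve["suitability"].is_monotonic_increasing

    def test_unknown_variable_errors(self, toy_fit):
        model = toy_fit[0]
        with pytest.raises(KeyError):
            response_curve(model, "nope")
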