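"""Simultaneous multi-rate least-squares calibration and its diagnostics.

Accuracy of full-scale parameter recovery is exercised in
test_acceptance.py; the tests here use reduced problem sizes (fewer
multi-starts, coarser ramps) to probe the fitting machinery itself.
"""

import numpy as np
import pytest
from sklearn.base import clone

import qlvfit as q
from qlvfit.calibration import curves_to_frame, residual_vector
from conftest import noiseless_curves

SHEAR = q.DeformationMode.SIMPLE_SHEAR


@pytest.fixture(scope="module")
def cerebrum_curves(presets):
    """Noiseless three-rate shear curves from the cerebrum reference model,
    on a coarse grid for speed."""
    return noiseless_curves(presets["cerebrum"], SHEAR, 1.0, n_steps=300)


class TestRSquared:
    def test_identical_curves(self):
        y = np.array([1.0, 2.0, 5.0])
        assert q.r_squared(y, y) == 1.0

    def test_model_equal_to_mean(self):
        data = np.array([1.0, 2.0, 3.0])
        assert q.r_squared(np.full(3, 2.0), data) == pytest.approx(0.0)

    def test_hand_computed_three_point_case(self):
        assert q.r_squared(np.array([1.0, 2.0, 4.0]),
                           np.array([1.0, 2.0, 3.0])) == pytest.approx(0.5)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            q.r_squared(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


class TestResidualVector:
    def test_zero_at_generating_parameters(self, cerebrum_curves):
        config = q.FitConfig(n_steps=300)
        theta = np.array([1.81, 10.1, 0.99, 0.276])
        res = residual_vector(theta, cerebrum_curves, config)
        assert np.max(np.abs(res)) < 1e-9

    def test_perturbed_mu_gives_positive_norm(self, cerebrum_curves):
        config = q.FitConfig(n_steps=300)
        res = residual_vector(np.array([1.81 * 1.1, 10.1, 0.99, 0.276]),
                              cerebrum_curves, config)
        assert np.linalg.norm(res) > 1e-3

    def test_elastic_only_linear_data(self):
        # small-strain linear data with slope k: residuals vanish at mu = k
        # with alpha fixed at 2 and no relaxation terms
        k = 3.4
        strain = np.linspace(0, 0.02, 21)
        curve = q.StressStrainCurve(mode=SHEAR, rate=1.0, strain=strain,
                                    stress=k * strain)
        config = q.FitConfig(n_prony_terms=0, fixed_alpha=2.0, n_steps=100)
        res = residual_vector(np.array([k]), [curve], config)
        assert np.max(np.abs(res)) < 1e-12

    def test_strain_beyond_ramp_rejected(self, cerebrum_curves):
        config = q.FitConfig(n_steps=100, ramp_max_strain=0.5)
        with pytest.raises(ValueError, match="simple_shear"):
            residual_vector(np.array([1.81, 10.1, 0.99, 0.276]),
                            cerebrum_curves, config)


class TestFitMultirate:
    def test_recovery_and_determinism(self, cerebrum_curves, small_fit_config):
        res1 = q.fit_multirate(cerebrum_curves, small_fit_config)
        res2 = q.fit_multirate(cerebrum_curves, small_fit_config)
        assert res1.ogden.terms == res2.ogden.terms
        assert res1.prony.terms == res2.prony.terms
        assert res1.start_costs == res2.start_costs
        assert res1.best_start_index == res2.best_start_index
        np.testing.assert_allclose(res1.ogden.mus, [1.81], rtol=1e-6)
        assert res1.converged and res1.pooled_r2 > 0.9999

    def test_stress_scale_invariance(self, cerebrum_curves, small_fit_config):
        res = q.fit_multirate(cerebrum_curves, small_fit_config)
        c = 7.3
        scaled = [q.StressStrainCurve(mode=x.mode, rate=x.rate, strain=x.strain,
                                      stress=c * x.stress) for x in cerebrum_curves]
        res_c = q.fit_multirate(scaled, small_fit_config)
        np.testing.assert_allclose(res_c.ogden.mus, c * res.ogden.mus, rtol=1e-4)
        np.testing.assert_allclose(res_c.ogden.alphas, res.ogden.alphas, rtol=1e-4)
        np.testing.assert_allclose(res_c.prony.gs, res.prony.gs, rtol=1e-4)
        np.testing.assert_allclose(res_c.prony.taus, res.prony.taus, rtol=1e-4)

    def test_elastic_truth_yields_near_zero_g(self, presets, small_fit_config):
        mat = q.MaterialModel(name="elastic", density=1040.0,
                              ogden=presets["cerebrum"].ogden)
        curves = noiseless_curves(mat, SHEAR, 1.0, n_steps=300)
        res = q.fit_multirate(curves, small_fit_config)
        assert res.prony.gs[0] <= 0.01
        np.testing.assert_allclose(res.ogden.mus, [1.81], rtol=0.01)
        np.testing.assert_allclose(res.ogden.alphas, [10.1], rtol=0.01)

    def test_single_rate_prony_warns(self, cerebrum_curves, small_fit_config):
        with pytest.warns(UserWarning, match="single"):
            res = q.fit_multirate(cerebrum_curves[:1], small_fit_config)
        assert res.warnings

    def test_empty_input_rejected(self, small_fit_config):
        with pytest.raises(ValueError):
            q.fit_multirate([], small_fit_config)

    def test_no_converged_start_raises(self, cerebrum_curves):
        config = q.FitConfig(n_starts=2, n_steps=100, max_nfev=1)
        with pytest.raises(q.FitFailureError):
            q.fit_multirate(cerebrum_curves, config)


class TestOgdenQLVRegressor:
    def test_sklearn_params_roundtrip(self):
        est = q.OgdenQLVRegressor(n_starts=3, random_state=7)
        params = est.get_params()
        assert params["n_starts"] == 3 and params["random_state"] == 7
        est2 = clone(est).set_params(n_steps=200)
        assert est2.get_params()["n_steps"] == 200

    def test_fit_predict_score(self, cerebrum_curves):
        X, y = curves_to_frame(cerebrum_curves)
        est = q.OgdenQLVRegressor(n_starts=4, random_state=0, n_steps=300)
        est.fit(X, y)
        np.testing.assert_allclose(est.ogden_.mus, [1.81], rtol=1e-4)
        pred = est.predict(X)
        assert pred.shape == y.shape
        assert est.score(X, y) > 0.9999

    def test_matches_functional_wrapper(self, cerebrum_curves, small_fit_config):
        X, y = curves_to_frame(cerebrum_curves)
        est = q.OgdenQLVRegressor(n_starts=4, random_state=0, n_steps=300).fit(X, y)
        res = q.fit_multirate(cerebrum_curves, small_fit_config)
        np.testing.assert_allclose(est.ogden_.mus, res.ogden.mus, rtol=1e-8)
        np.testing.assert_allclose(est.result_.start_costs, res.start_costs)

    def test_unfitted_predict_rejected(self, cerebrum_curves):
        X, _ = curves_to_frame(cerebrum_curves)
        with pytest.raises(AttributeError):
            q.OgdenQLVRegressor().predict(X)

    def test_missing_column_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError, match="strain"):
            q.OgdenQLVRegressor().fit(pd.DataFrame({"mode": [], "rate": []}),
                                      np.array([]))


@pytest.fixture(scope="module")
def noisy_reps(presets):
    design = q.ExperimentDesign(name="small", mode=SHEAR,
                                rates=(0.01, 150.0, 300.0), n_replicates=6,
                                max_strain=1.0, n_points=51)
    return q.generate_replicates(presets["cerebrum"], design,
                                 q.NoiseModel(multiplicative=0.05, seed=11))


class TestBootstrap:
    def test_deterministic_given_seed(self, noisy_reps):
        config = q.FitConfig(n_starts=2, n_steps=200)
        a = q.bootstrap_uncertainty(noisy_reps, config, n_boot=3, seed=5)
        b = q.bootstrap_uncertainty(noisy_reps, config, n_boot=3, seed=5)
        assert a == b

    def test_zero_noise_degenerate_intervals(self, presets):
        design = q.ExperimentDesign(name="tiny", mode=SHEAR, rates=(0.01, 300.0),
                                    n_replicates=3, max_strain=1.0, n_points=41)
        reps = q.generate_replicates(presets["cerebrum"], design,
                                     q.NoiseModel(multiplicative=0.0, additive=0.0))
        config = q.FitConfig(n_starts=2, n_steps=200)
        ci = q.bootstrap_uncertainty(reps, config, n_boot=3, seed=0)
        lo, hi = ci["mu_1"]
        assert hi - lo < 1e-6 * 1.81

    def test_intervals_calibrated_under_noise(self, presets):
        # Reduced-cost check that percentile intervals land at the right
        # scale: under 5% noise the mu interval is non-degenerate, a few
        # percent wide, and covers the generating truth for most datasets.
        design = q.ExperimentDesign(name="cov", mode=SHEAR,
                                    rates=(0.01, 150.0, 300.0), n_replicates=6,
                                    max_strain=1.0, n_points=51)
        config = q.FitConfig(n_starts=3, n_steps=200)
        covered = 0
        for seed in range(4):
            reps = q.generate_replicates(presets["cerebrum"], design,
                                         q.NoiseModel(multiplicative=0.05, seed=seed))
            ci = q.bootstrap_uncertainty(reps, config, n_boot=16, seed=100 + seed)
            lo, hi = ci["mu_1"]
            assert 0.0 < hi - lo < 0.5 * 1.81
            covered += lo <= 1.81 <= hi
        assert covered >= 2

    def test_too_few_resamples_rejected(self, noisy_reps):
        with pytest.raises(ValueError):
            q.bootstrap_uncertainty(noisy_reps, q.FitConfig(), n_boot=1, seed=0)
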