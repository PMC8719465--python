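"""Prony relaxation, ramp histories and the two QLV integrators."""

import math

import numpy as np
import pytest

import qlvfit as q
from conftest import noiseless_curves

SHEAR = q.DeformationMode.SIMPLE_SHEAR
UNI = q.DeformationMode.UNIAXIAL_TENSION


class TestPronySeries:
    def test_invariants(self):
        with pytest.raises(q.InvalidParameterError):
            q.PronySeries([(0.6, 1.0), (0.5, 2.0)])  # sum g >= 1
        with pytest.raises(q.InvalidParameterError):
            q.PronySeries([(0.5, -1.0)])
        with pytest.raises(q.InvalidParameterError):
            q.PronySeries([(-0.1, 1.0)])

    def test_decay_constant_constructor(self):
        p = q.PronySeries.from_decay_constants([(0.99, 0.276)])
        assert p.taus[0] == pytest.approx(1 / 0.276)
        assert p.decay_constants[0] == pytest.approx(0.276)

    def test_long_term_fraction(self):
        assert q.PronySeries([(0.9, 1.0)]).long_term_fraction == pytest.approx(0.1)
        assert q.PronySeries.empty().long_term_fraction == 1.0


class TestReducedRelaxation:
    def test_unity_at_zero(self, cerebrum):
        assert q.reduced_relaxation(0.0, cerebrum.prony) == 1.0

    def test_cerebrum_value_at_tau(self, cerebrum):
        tau = cerebrum.prony.taus[0]
        expected = 1 - 0.99 * (1 - math.exp(-1))
        assert q.reduced_relaxation(tau, cerebrum.prony) == pytest.approx(expected, rel=1e-12)

    def test_monotone_with_asymptote(self, cerebrum):
        t = np.geomspace(1e-4, 1000 * cerebrum.prony.taus[0], 200)
        g = q.reduced_relaxation(t, cerebrum.prony)
        assert np.all(np.diff(g) <= 0)
        assert g[-1] == pytest.approx(cerebrum.prony.long_term_fraction, abs=1e-12)

    def test_negative_time_rejected(self, cerebrum):
        with pytest.raises(ValueError):
            q.reduced_relaxation(-1.0, cerebrum.prony)


class TestRampHistory:
    def test_low_rate_shear_grid(self):
        h = q.ramp_history(0.01, 1.0, 4, SHEAR)
        np.testing.assert_allclose(h.time, [0, 25, 50, 75, 100])
        np.testing.assert_allclose(h.strain, 0.01 * h.time, atol=1e-15)

    def test_high_rate_duration(self):
        h = q.ramp_history(300.0, 1.0, 100, SHEAR)
        assert h.time[-1] == pytest.approx(1 / 300)

    def test_uniaxial_excursion(self):
        h = q.ramp_history(150.0, 1.3, 100, UNI)
        assert h.time[-1] == pytest.approx(0.3 / 150)
        assert h.strain[0] == 1.0 and h.strain[-1] == pytest.approx(1.3)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            q.ramp_history(-1.0, 1.0, 10, SHEAR)
        with pytest.raises(ValueError):
            q.ramp_history(1.0, 0.0, 10, SHEAR)
        with pytest.raises(ValueError):
            q.ramp_history(1.0, 1.0, 10, UNI)  # lambda_max must exceed 1
        with pytest.raises(ValueError):
            q.ramp_history(1.0, 1.0, 1, SHEAR)


class TestQLVIntegrators:
    def test_empty_prony_is_elastic(self, cerebrum):
        h = q.ramp_history(0.01, 1.0, 200, SHEAR)
        out = q.qlv_stress_recursive(h, cerebrum.ogden, q.PronySeries.empty())
        inst = q.instantaneous_shear_stress(h.strain, cerebrum.ogden)
        np.testing.assert_array_equal(out.stress, inst)
        quad = q.qlv_stress_quadrature(h, cerebrum.ogden, q.PronySeries.empty(), 2)
        np.testing.assert_allclose(quad.stress, inst, rtol=1e-9, atol=1e-12)

    def test_linear_backbone_closed_form(self):
        # sigma_e = k*gamma (alpha = 2), ramp gamma = r*t:
        # sigma(t) = k r [t - g (t - tau (1 - exp(-t/tau)))]
        k, r, g, tau = 2.0, 0.5, 0.6, 0.3
        backbone = q.OgdenParameters.one_term(k, 2.0)
        prony = q.PronySeries([(g, tau)])
        h = q.ramp_history(r, 1.0, 1000, SHEAR)
        rec = q.qlv_stress_recursive(h, backbone, prony)
        t = h.time[1:]
        closed = k * r * (t - g * (t - tau * (1 - np.exp(-t / tau))))
        np.testing.assert_allclose(rec.stress[1:], closed, rtol=1e-3)

    def test_recursive_matches_quadrature(self, cerebrum):
        h = q.ramp_history(0.01, 1.0, 1000, SHEAR)
        rec = q.qlv_stress_recursive(h, cerebrum.ogden, cerebrum.prony)
        quad = q.qlv_stress_quadrature(h, cerebrum.ogden, cerebrum.prony, 4)
        dev = np.max(np.abs(rec.stress - quad.stress)) / rec.peak_stress
        assert dev < 0.005

    def test_quadrature_self_convergence(self, cerebrum):
        h = q.ramp_history(0.01, 1.0, 400, SHEAR)
        rec = q.qlv_stress_recursive(h, cerebrum.ogden, cerebrum.prony)
        devs = []
        for refinement in (1, 2, 4):
            quad = q.qlv_stress_quadrature(h, cerebrum.ogden, cerebrum.prony, refinement)
            devs.append(np.max(np.abs(quad.stress - rec.stress)) / rec.peak_stress)
        # first-order-or-better: halving the step at least ~halves the deviation
        assert devs[1] <= 0.75 * devs[0]
        assert devs[2] <= 0.75 * devs[1]

    def test_fast_rate_limit_is_instantaneous(self, cerebrum):
        c = q.rate_response_curve(cerebrum, SHEAR, 1e6, 1.0, 1000)
        inst = q.instantaneous_shear_stress(c.strain, cerebrum.ogden)
        np.testing.assert_allclose(c.stress[1:], inst[1:], rtol=0.01)

    def test_slow_rate_limit_is_long_term(self, cerebrum):
        c = q.rate_response_curve(cerebrum, SHEAR, 1e-7, 1.0, 1000)
        lt = cerebrum.prony.long_term_fraction * q.instantaneous_shear_stress(
            c.strain, cerebrum.ogden)
        np.testing.assert_allclose(c.stress[5:], lt[5:], rtol=0.01)

    def test_causality_under_truncation(self, cerebrum):
        h = q.ramp_history(0.01, 1.0, 500, SHEAR)
        full = q.qlv_stress_recursive(h, cerebrum.ogden, cerebrum.prony)
        k = 200
        h_trunc = q.LoadingHistory(mode=SHEAR, time=h.time[:k + 1],
                                   strain=h.strain[:k + 1], nominal_rate=h.nominal_rate)
        trunc = q.qlv_stress_recursive(h_trunc, cerebrum.ogden, cerebrum.prony)
        np.testing.assert_array_equal(trunc.stress, full.stress[:k + 1])

    def test_nonuniform_grid_rejected(self, cerebrum):
        t = np.array([0.0, 1.0, 3.0, 4.0])
        h = q.LoadingHistory(mode=SHEAR, time=t, strain=0.01 * t, nominal_rate=0.01)
        with pytest.raises(ValueError):
            q.qlv_stress_recursive(h, cerebrum.ogden, cerebrum.prony)

    def test_reversed_time_rejected(self):
        with pytest.raises(ValueError):
            q.LoadingHistory(mode=SHEAR, time=np.array([0.0, 2.0, 1.0]),
                             strain=np.array([0.0, 0.02, 0.01]), nominal_rate=0.01)


class TestRateResponse:
    def test_rate_stiffening_cerebellum(self, presets):
        curves = noiseless_curves(presets["cerebellum"], SHEAR, 1.0, n_steps=400)
        s_low, s_mid, s_high = (c.stress for c in curves)
        assert np.all(s_high[1:] >= s_mid[1:] - 1e-12)
        assert np.all(s_mid[1:] >= s_low[1:] - 1e-12)

    def test_zero_g_collapses_rates(self, cerebrum):
        mat = q.MaterialModel(name="elastic", density=1040.0, ogden=cerebrum.ogden,
                              prony=q.PronySeries([(0.0, 1.0)]))
        curves = noiseless_curves(mat, SHEAR, 1.0, n_steps=200)
        for c in curves[1:]:
            np.testing.assert_allclose(c.stress, curves[0].stress, rtol=1e-12)

    def test_vasculature_uniaxial_monotone(self, presets):
        curves = noiseless_curves(presets["vasculature"], UNI, 1.3, n_steps=400)
        for c in curves:
            assert np.all(np.diff(c.stress) > 0)

    def test_convergence_check(self, cerebrum):
        # 1,000 steps is converged for the protocol rates; 3 steps is not
        c = q.rate_response_curve(cerebrum, SHEAR, 0.01, 1.0, n_steps=1000,
                                  check_convergence=True)
        assert c.stress[-1] > 0
        with pytest.raises(RuntimeError, match="not converged"):
            q.rate_response_curve(cerebrum, SHEAR, 0.01, 1.0, n_steps=3,
                                  check_convergence=True)

    def test_material_without_ogden_rejected(self, presets):
        with pytest.raises(q.InvalidParameterError):
            q.rate_response_curve(presets["skull"], SHEAR, 0.01, 1.0, 100)
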