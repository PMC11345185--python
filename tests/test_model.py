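import numpy as np
import pytest

from pfr.channels import ChannelSeries
from pfr.classify import fit_correction
from pfr.model import (CAParameters, CBFEstimator, InversionConfig, cvr,
                       estimate_cbf, forward_flow)


def cpp_of(v, step=60.0):
    v = np.asarray(v, dtype=float)
    return ChannelSeries("CPP", np.arange(len(v)) * step, v, "mmHg", 1 / step)


class TestCAParameters:
    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            CAParameters(-0.1, 0.0)
        with pytest.raises(ValueError):
            CAParameters(0.1, -1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            CAParameters(np.nan, 0.0)


class TestForwardFlow:
    def test_pure_conductance_on_constant_gradient(self):
        q = forward_flow(cpp_of(np.full(20, 80.0)), (0.015, 0.0))
        assert np.allclose(q.v, 1.2)
        assert q.units == "mL/s"

    def test_pure_compliance_on_ramp(self):
        # gradient rising 1 mmHg/s -> derivative term alone carries the flow
        v = 60.0 + np.arange(20) * 60.0  # slope 1 mmHg/s at 60-s steps
        q = forward_flow(cpp_of(v), (0.0, 0.1))
        assert np.allclose(q.v, 0.1)

    def test_unit_conductance_is_identity(self):
        v = 80 + np.sin(np.arange(30))
        q = forward_flow(cpp_of(v), (1.0, 0.0))
        assert np.allclose(q.v, v)

    def test_nan_propagates_to_stencil_neighbors(self):
        v = np.full(10, 80.0)
        v[4] = np.nan
        q = forward_flow(cpp_of(v), (1.0, 0.5))
        assert np.isnan(q.v[3:6]).all()
        assert np.isfinite(q.v[:3]).all() and np.isfinite(q.v[6:]).all()

    def test_per_window_alpha_sequence(self):
        v = np.full(10, 80.0)
        alphas = np.column_stack([np.linspace(0.01, 0.02, 10), np.zeros(10)])
        q = forward_flow(cpp_of(v), alphas)
        assert np.allclose(q.v, alphas[:, 0] * 80.0)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            forward_flow(cpp_of(np.full(10, 80.0)), (-1.0, 0.0))


class TestEstimateCbf:
    def test_forward_inverse_constant_alpha(self, minute_cpp):
        q_true = forward_flow(minute_cpp, (0.015, 0.0))
        est = estimate_cbf(minute_cpp, flow=q_true)
        r = np.corrcoef(q_true.v, est.q.v)[0, 1]
        assert r >= 0.99
        # conductance recovered within 5% where the derivative term vanishes
        assert est.alphas[:, 0].mean() == pytest.approx(0.015, rel=0.05)

    def test_forward_inverse_piecewise_alpha(self, minute_cpp):
        n = len(minute_cpp)
        a1 = np.where(np.arange(n) < n // 2, 0.01, 0.02)
        q_true = forward_flow(minute_cpp,
                              np.column_stack([a1, np.full(n, 1e-3)]))
        est = estimate_cbf(minute_cpp, flow=q_true)
        assert np.corrcoef(q_true.v, est.q.v)[0, 1] >= 0.99

    def test_nonnegativity_always(self, minute_cpp):
        anti = ChannelSeries("CBF", minute_cpp.t,
                             -(minute_cpp.v - minute_cpp.v.mean()),
                             "mL/s", minute_cpp.nominal_rate)
        est = estimate_cbf(minute_cpp, flow=anti)
        assert est.alphas.min() >= 0.0

    def test_sign_guarantee_with_anticorrelated_perfusion_downstream(
            self, minute_cpp):
        """The estimate never chases anti-correlated perfusion: it stays
        non-negatively oriented with CPP, so the downstream calibration
        slope turns negative (what makes nPFR detectable)."""
        anti_perf = -(minute_cpp.v - minute_cpp.v.mean())
        est = estimate_cbf(minute_cpp)
        assert est.diagnostics["corr_cpp"] >= 0.0
        assert fit_correction(est.q.v, anti_perf).m < -0.9

    def test_without_flow_returns_prior_response(self, minute_cpp):
        est = estimate_cbf(minute_cpp)
        assert "prior_only" in est.diagnostics["flags"]
        assert np.corrcoef(est.q.v, minute_cpp.v)[0, 1] >= 0.0
        assert np.allclose(est.alphas[:, 0], 1.0)

    def test_constant_cpp_flags_unidentifiable_alpha2(self):
        est = estimate_cbf(cpp_of(np.full(30, 80.0)))
        assert "alpha2_unidentifiable" in est.diagnostics["flags"]
        assert np.allclose(est.q.v, 80.0)  # alpha1 prior of 1 model unit

    def test_affine_input_preserves_downstream_slope(self, minute_cpp):
        """Rescaling/shifting CPP must not move the standardized slope."""
        perf = np.random.default_rng(5).normal(0, 1, len(minute_cpp)) \
            + 0.5 * (minute_cpp.v - minute_cpp.v.mean())
        est1 = estimate_cbf(minute_cpp)
        scaled = ChannelSeries("CPP", minute_cpp.t, 2.0 * minute_cpp.v + 10.0,
                               "mmHg", minute_cpp.nominal_rate)
        est2 = estimate_cbf(scaled)
        m1 = fit_correction(est1.q.v, perf).m
        m2 = fit_correction(est2.q.v, perf).m
        assert m1 == pytest.approx(m2, abs=1e-9)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="windows"):
            estimate_cbf(cpp_of(np.full(5, 80.0)))

    def test_nan_windows_skipped_and_flagged(self, minute_cpp):
        v = minute_cpp.v.copy()
        v[10:15] = np.nan
        cpp = ChannelSeries("CPP", minute_cpp.t, v, "mmHg",
                            minute_cpp.nominal_rate)
        q_true = forward_flow(cpp, (0.015, 0.0))
        est = estimate_cbf(cpp, flow=q_true)
        assert "windows_skipped" in est.diagnostics["flags"]
        m = np.isfinite(q_true.v)
        assert np.corrcoef(q_true.v[m], est.q.v[m])[0, 1] >= 0.99


class TestCvr:
    def test_arithmetic(self):
        out = cvr(cpp_of(np.full(10, 80.0)),
                  ChannelSeries("CBF", np.arange(10) * 60.0, np.full(10, 1.2),
                                "mL/s", 1 / 60))
        assert np.allclose(out.v, 80.0 / 1.2)

    def test_inverse_of_conductance(self, minute_cpp):
        q = forward_flow(minute_cpp, (0.02, 0.0))
        out = cvr(minute_cpp, q)
        assert np.allclose(out.v, 50.0)

    def test_flow_near_zero_floored_to_nan(self):
        q = ChannelSeries("CBF", np.arange(4) * 60.0,
                          np.array([1.0, 1e-9, -1e-9, -1.0]), "mL/s", 1 / 60)
        out = cvr(cpp_of(np.full(4, 80.0)), q, q_floor=1e-6)
        assert np.isfinite(out.v[[0, 3]]).all()
        assert np.isnan(out.v[[1, 2]]).all()


class TestCBFEstimatorApi:
    def test_get_set_params_round_trip(self):
        est = CBFEstimator(roughness=2.0)
        assert est.get_params()["roughness"] == 2.0
        est.set_params(anchor_weight=0.01)
        assert est.get_params()["anchor_weight"] == 0.01
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_fit_exposes_trailing_underscore_attributes(self, minute_cpp):
        est = CBFEstimator().fit(minute_cpp)
        assert est.alphas_.shape == (len(minute_cpp), 2)
        assert len(est.flow_.v) == len(minute_cpp)

    def test_predict_requires_fit(self, minute_cpp):
        with pytest.raises(ValueError, match="not fitted"):
            CBFEstimator().predict(minute_cpp)
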