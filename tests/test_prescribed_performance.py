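"""Funnel geometry and the bijective error transformation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hhsync import (FunnelBranch, FunnelViolationError, PerformanceSpec, beta,
                    beta_dot, branch_for, funnel_bounds, gamma,
                    inverse_transform, phi, transform_R)
from hhsync.prescribed_performance import phi_partials

SPEC = PerformanceSpec()  # beta(t) = 0.28 e^{-0.6 t} + 0.02, H = 0.9
NN = FunnelBranch.NONNEGATIVE
NP_ = FunnelBranch.NONPOSITIVE


class TestBeta:
    def test_endpoints(self):
        assert beta(0.0, SPEC) == pytest.approx(0.3, abs=1e-15)
        assert beta(50.0, SPEC) == pytest.approx(0.02, abs=1e-12)

    def test_strictly_decreasing_and_positive(self):
        t = np.linspace(0, 20, 500)
        b = beta(t, SPEC)
        assert np.all(np.diff(b) < 0) and np.all(b > 0)

    def test_degenerate_constant_funnel(self):
        flat = PerformanceSpec(beta0=0.1, beta_inf=0.1, kappa=1.0, H=0.9)
        t = np.linspace(0, 5, 50)
        assert np.all(beta(t, flat) == 0.1)
        assert np.all(beta_dot(t, flat) == 0.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            beta(-0.5, SPEC)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PerformanceSpec(beta0=0.02, beta_inf=0.3)   # inverted heights
        with pytest.raises(ValueError):
            PerformanceSpec(kappa=-1.0)
        with pytest.raises(ValueError):
            PerformanceSpec(H=1.2)
        with pytest.raises(ValueError):
            PerformanceSpec(H=0.0)


class TestFunnelBounds:
    def test_initial_bounds(self):
        lo, up = funnel_bounds(0.0, SPEC, NN)
        assert lo == pytest.approx(-0.27, abs=1e-15)   # -H * beta0
        assert up == pytest.approx(0.3, abs=1e-15)

    def test_mirror_branch(self):
        lo, up = funnel_bounds(0.0, SPEC, NP_)
        assert (lo, up) == pytest.approx((-0.3, 0.27), abs=1e-15)

    def test_symmetric_when_H_is_one(self):
        s = PerformanceSpec(H=1.0)
        lo, up = funnel_bounds(1.0, s, NN)
        assert lo == pytest.approx(-up, rel=1e-15)

    def test_nesting_in_time(self):
        lo1, up1 = funnel_bounds(0.5, SPEC, NN)
        lo2, up2 = funnel_bounds(2.0, SPEC, NN)
        assert lo1 < lo2 < 0 < up2 < up1


class TestTransform:
    def test_value_at_zero(self):
        assert transform_R(0.0, SPEC, NN) == pytest.approx((1 - 0.9) / 2, rel=1e-12)

    def test_asymptotes(self):
        assert transform_R(40.0, SPEC, NN) == pytest.approx(1.0, abs=1e-12)
        assert transform_R(-40.0, SPEC, NN) == pytest.approx(-0.9, abs=1e-12)
        assert transform_R(40.0, SPEC, NP_) == pytest.approx(0.9, abs=1e-12)
        assert transform_R(-40.0, SPEC, NP_) == pytest.approx(-1.0, abs=1e-12)

    def test_inverse_at_zero_error(self):
        assert inverse_transform(0.0, 0.0, SPEC, NN) == pytest.approx(math.log(0.9), rel=1e-12)
        sym = PerformanceSpec(H=1.0)
        assert inverse_transform(0.0, 0.3, sym, NN) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=-12.0, max_value=12.0),
           st.floats(min_value=0.0, max_value=10.0),
           st.sampled_from([NN, NP_]))
    def test_round_trip_bijection(self, eps, t, branch):
        """e = beta * R(eps) then eps = R^{-1}(e/beta) recovers eps; and the
        forward map recovers e to 1e-10."""
        e = beta(t, SPEC) * transform_R(eps, SPEC, branch)
        eps_back = inverse_transform(e, t, SPEC, branch)
        assert eps_back == pytest.approx(eps, abs=1e-9)
        e_back = beta(t, SPEC) * transform_R(eps_back, SPEC, branch)
        assert e_back == pytest.approx(e, abs=1e-10)

    def test_monotone_in_error(self):
        t = 0.7
        lo, up = funnel_bounds(t, SPEC, NN)
        es = np.linspace(lo + 1e-6, up - 1e-6, 400)
        eps = [inverse_transform(e, t, SPEC, NN) for e in es]
        assert np.all(np.diff(eps) > 0)

    @pytest.mark.parametrize("e", [0.3, 0.31, -0.27, -0.5])
    def test_wall_contact_raises(self, e):
        with pytest.raises(FunnelViolationError) as exc:
            inverse_transform(e, 0.0, SPEC, NN)
        assert exc.value.t == 0.0 and exc.value.e == e


class TestPhiGamma:
    def test_phi_value_at_start(self):
        # 1/(H beta0 + 0) - 1/(0 - beta0) = 1/0.27 + 1/0.3
        assert phi(0.0, 0.0, SPEC, NN) == pytest.approx(1 / 0.27 + 1 / 0.3, rel=1e-12)

    def test_phi_positive_and_diverges_at_walls(self):
        t = 1.0
        b = beta(t, SPEC)
        assert phi(0.9 * b, t, SPEC, NN) < phi(0.999 * b, t, SPEC, NN)
        assert phi(-0.9 * 0.9 * b, t, SPEC, NN) < phi(-0.999 * 0.9 * b, t, SPEC, NN)
        for e in np.linspace(-0.8 * 0.9 * b, 0.8 * b, 30):
            assert phi(e, t, SPEC, NN) > 0

    @pytest.mark.parametrize("branch", [NN, NP_])
    def test_phi_is_derivative_of_transform(self, branch):
        """Central-difference d eps/d e matches phi to 1e-6 relative."""
        t = 0.4
        b = beta(t, SPEC)
        for e in (-0.2 * b, 0.0, 0.1 * b, 0.6 * b if branch is NN else 0.6 * 0.9 * b):
            h = 1e-7
            num = (inverse_transform(e + h, t, SPEC, branch)
                   - inverse_transform(e - h, t, SPEC, branch)) / (2 * h)
            assert num == pytest.approx(phi(e, t, SPEC, branch), rel=1e-6)

    def test_phi_partials_match_finite_differences(self):
        t, e = 0.8, -0.05
        p, dp_de, dp_dt = phi_partials(e, t, SPEC, NN)
        h = 1e-7
        assert dp_de == pytest.approx(
            (phi(e + h, t, SPEC, NN) - phi(e - h, t, SPEC, NN)) / (2 * h), rel=1e-5)
        assert dp_dt == pytest.approx(
            (phi(e, t + h, SPEC, NN) - phi(e, t - h, SPEC, NN)) / (2 * h), rel=1e-5)

    def test_gamma_zero_cases_and_sign(self):
        assert gamma(0.0, 1.0, SPEC, NN) == 0.0
        flat = PerformanceSpec(beta0=0.1, beta_inf=0.1, kappa=1.0, H=0.9)
        assert gamma(0.05, 1.0, flat, NN) == 0.0
        # shrinking funnel, positive error: drift is negative
        assert gamma(0.1, 0.5, SPEC, NN) < 0

    def test_filtered_error_rate_consistency(self):
        """Along a smooth path e(t) inside the funnel, numeric d eps/dt
        matches phi * (de/dt - (beta_dot/beta) e) to 1e-5 relative."""
        e_path = lambda t: 0.5 * beta(t, SPEC) * math.sin(3.0 * t)
        de_path = lambda t: (0.5 * beta_dot(t, SPEC) * math.sin(3.0 * t)
                             + 1.5 * beta(t, SPEC) * math.cos(3.0 * t))
        for t in (0.2, 0.9, 2.5):
            h = 1e-6
            num = (inverse_transform(e_path(t + h), t + h, SPEC, NN)
                   - inverse_transform(e_path(t - h), t - h, SPEC, NN)) / (2 * h)
            e, de = e_path(t), de_path(t)
            analytic = phi(e, t, SPEC, NN) * (de - beta_dot(t, SPEC) / beta(t, SPEC) * e)
            assert num == pytest.approx(analytic, rel=1e-5)


def test_branch_selection():
    assert branch_for(0.2) is NN
    assert branch_for(0.0) is NN      # equality assigned to the nonnegative case
    assert branch_for(-1e-9) is NP_
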