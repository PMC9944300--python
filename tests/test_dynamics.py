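import numpy as np
import pytest

from invbleb import geometry
from invbleb.dynamics import (NOT_REACHED, collapse_run, collapse_time,
                              radius_rhs, simulate, time_to_steady)
from invbleb.params import Protocol, mmhg_to_pressure
from invbleb.steady import equilibria


def stable_radius(delta_p, params):
    recs = [e for e in equilibria(delta_p, params) if e.stable]
    return recs[-1].r_eq


@pytest.fixture(scope="module")
def growth_traj(ref):
    """Reference growth run: 30 mmHg from a hemispherical nucleus."""
    proto = Protocol(delta_p=mmhg_to_pressure(30.0), t_max=600.0)
    return simulate(ref, proto)


class TestRadiusRate:
    def test_balanced_state_is_fixed_point(self, ref):
        r, Sigma = 2.0, 500.0
        P = 100.0
        dp = P + 2 * Sigma / r
        assert radius_rhs(r, Sigma, P, dp, ref) == pytest.approx(0.0, abs=1e-15)

    def test_nucleation_growth_rate_at_30_mmhg(self, ref):
        # independent arithmetic: (r/4mu) (dp - 2 sigma_0/R0 - 2 Sigma/r)
        dp = mmhg_to_pressure(30.0)
        P = 2 * ref.sigma_0 / ref.R0                  # 82.8
        expected = ref.a / (4 * ref.mu) * (dp - P - 2 * ref.sigma_m / ref.a)
        got = radius_rhs(ref.a, ref.sigma_m, P, dp, ref)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(8.99e-3, rel=1e-3)

    def test_unpressurized_bleb_always_shrinks(self, ref):
        for r in (0.3, 1.0, 4.0):
            assert radius_rhs(r, ref.sigma_0, 82.8, 0.0, ref) < 0


class TestLinearRegimeOracle:
    def test_integrator_matches_closed_form(self, ref):
        """With the cell frozen at (R0, sigma_0) and the bleb tension at
        its plateau, the radius equation is linear: dr/dt = alpha r - beta
        with alpha = (dp - 2 sigma_0/R0)/(4 mu), beta = sigma_0/(2 mu)."""
        dp = mmhg_to_pressure(30.0)
        proto = Protocol(delta_p=dp, t_max=80.0)
        traj = simulate(ref, proto, init=(ref.a, ref.sigma_0),
                        _frozen_cell=True)
        alpha = (dp - 2 * ref.sigma_0 / ref.R0) / (4 * ref.mu)
        beta = ref.sigma_0 / (2 * ref.mu)
        r_exact = (ref.a - beta / alpha) * np.exp(alpha * traj.t) + beta / alpha
        # window stays within the cortex plateau (r < reservoir exhaustion)
        assert r_exact[-1] < 3.5
        np.testing.assert_allclose(traj.r[:, 0], r_exact, rtol=1e-6)


class TestGrowthScenarios:
    def test_high_pressure_grows_to_membrane_branch(self, ref, growth_traj):
        r_star = stable_radius(mmhg_to_pressure(30.0), ref)
        assert np.all(np.diff(growth_traj.r[:, 0]) >= -1e-9)  # monotone growth
        assert growth_traj.r[-1, 0] == pytest.approx(r_star, rel=1e-6)
        assert growth_traj.regime[-1, 0] == "membrane"

    def test_growth_time_about_two_minutes(self, ref, growth_traj):
        r_star = stable_radius(mmhg_to_pressure(30.0), ref)
        tts = time_to_steady(growth_traj, r_star)
        assert 1.0 <= tts <= 2.0

    def test_small_nucleus_at_physiological_pressure_shrinks(self, ref):
        proto = Protocol(delta_p=mmhg_to_pressure(7.0), t_max=600.0)
        traj = simulate(ref, proto, init=(ref.a, ref.sigma_m))
        ev = traj.terminal_event
        assert ev is not None and ev.kind == "collapsed"

    def test_large_nucleus_at_physiological_pressure_grows(self, ref):
        # threshold radius is ~1 um at 7 mmHg; r0 = 2 um is supercritical
        dp = mmhg_to_pressure(7.0)
        proto = Protocol(delta_p=dp, t_max=3600.0)
        traj = simulate(ref, proto, init=(2.0, ref.sigma_m))
        assert traj.r[-1, 0] == pytest.approx(stable_radius(dp, ref), rel=1e-4)


class TestStateInvariants:
    def test_laplace_law_everywhere(self, growth_traj):
        np.testing.assert_allclose(
            growth_traj.P, 2.0 * growth_traj.sigma / growth_traj.R, rtol=1e-12)

    def test_volume_conservation_everywhere(self, ref, growth_traj):
        hemis = (2 * np.pi / 3) * growth_traj.R**3
        caps = np.array([
            geometry.cap_volume(r, geometry.opening_angle(r, ref.a))
            for r in growth_traj.r[:, 0]])
        np.testing.assert_allclose(hemis - caps,
                                   (2 * np.pi / 3) * ref.R0**3, rtol=1e-9)

    def test_times_strictly_increasing(self, growth_traj):
        assert np.all(np.diff(growth_traj.t) > 0)

    def test_pore_constraint_everywhere(self, ref, growth_traj):
        np.testing.assert_allclose(
            growth_traj.r[:, 0] * np.sin(growth_traj.theta[:, 0]), ref.a,
            rtol=1e-9)


class TestCollapse:
    def test_collapse_time_in_reported_band(self, ref):
        traj = collapse_run(ref, mmhg_to_pressure(30.0))
        t_col = collapse_time(traj)
        assert 4.0 <= t_col <= 6.0

    def test_collapse_slower_than_growth(self, ref, growth_traj):
        r_star = stable_radius(mmhg_to_pressure(30.0), ref)
        t_grow = time_to_steady(growth_traj, r_star)
        t_col = collapse_time(collapse_run(ref, mmhg_to_pressure(30.0)))
        assert t_col > t_grow

    def test_reduced_cortical_tension_collapses_slower(self, ref):
        t_ref = collapse_time(collapse_run(ref, mmhg_to_pressure(30.0)))
        soft = ref.replace(sigma_c=ref.sigma_c / 2)
        t_soft = collapse_time(collapse_run(soft, mmhg_to_pressure(30.0)))
        assert t_soft > t_ref

    def test_maintained_pressure_never_collapses(self, ref):
        dp = mmhg_to_pressure(30.0)
        r_star = stable_radius(dp, ref)
        proto = Protocol(delta_p=dp, t_max=600.0)
        traj = simulate(ref, proto, init=(r_star, ref.sigma_0))
        assert traj.terminal_event is None
        assert traj.r[-1, 0] == pytest.approx(r_star, rel=1e-6)

    def test_no_stable_equilibrium_to_prepare(self, ref):
        with pytest.raises(ValueError, match="no stable equilibrium"):
            collapse_run(ref, mmhg_to_pressure(1.0))


class TestTimeToSteady:
    def test_already_at_target(self, ref):
        dp = mmhg_to_pressure(30.0)
        r_star = stable_radius(dp, ref)
        traj = simulate(ref, Protocol(delta_p=dp, t_max=60.0),
                        init=(r_star, ref.sigma_0))
        assert time_to_steady(traj, r_star) == 0.0

    def test_never_reached_is_sentinel(self, ref):
        proto = Protocol(delta_p=mmhg_to_pressure(7.0), t_max=120.0)
        traj = simulate(ref, proto, init=(ref.a, ref.sigma_m))
        assert np.isnan(time_to_steady(traj, 3.6))
        assert np.isnan(NOT_REACHED)
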