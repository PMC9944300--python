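import numpy as np
import pytest

from invbleb.params import mmhg_to_pressure, pressure_to_mmhg
from invbleb.steady import (delta_p_dagger, delta_p_star, equilibria,
                            nucleation_pressure_estimate, pressure_scan,
                            stability)


def grid_scan_oracle(delta_p, params, n_grid=10_000, r_max=30.0):
    """Independent root finder: dense sign scan of the balance residual
    built directly from the model formulas, refined by bisection."""
    a, d, R0 = params.a, params.d, params.R0
    S0 = np.pi * d**2
    S_star = S0 * (1.0 + params.eps_star)
    A0 = 3 * np.pi * R0**2 - np.pi * d**2

    def F(r):
        theta = np.pi - np.arcsin(a / r)
        S = 2 * np.pi * r**2 * (1 - np.cos(theta)) + np.pi * (d**2 - a**2)
        R = (R0**3 + 2 * r**3 * (2 + np.cos(theta))
             * np.sin(theta / 2) ** 4) ** (1 / 3)
        A = 3 * np.pi * R**2 - np.pi * d**2
        Sig = params.sigma_0 + (params.K_m * np.expm1((S - S_star) / S_star)
                                if S > S_star else 0.0)
        sig = params.sigma_0 + (params.K_m * np.expm1(
            (A - A0 * (1 + params.eps_star)) / (A0 * (1 + params.eps_star)))
            if A > A0 * (1 + params.eps_star) else 0.0)
        return 2 * Sig / r + 2 * sig / R - delta_p

    rs = np.linspace(a, r_max, n_grid)
    vals = np.array([F(r) for r in rs])
    roots = []
    for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
        lo, hi = rs[i], rs[i + 1]
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if F(lo) * F(mid) <= 0:
                hi = mid
            else:
                lo = mid
        roots.append(0.5 * (lo + hi))
    return roots


class TestEquilibria:
    def test_two_roots_at_physiological_pressure(self, ref, mm):
        eqs = equilibria(mm(7.0), ref)
        assert [e.branch for e in eqs] == ["cortex", "membrane"]
        assert eqs[0].r_eq == pytest.approx(0.97, abs=0.02)  # ~1 um threshold
        assert eqs[1].r_eq == pytest.approx(3.6, abs=0.05)

    def test_one_root_at_high_pressure(self, ref, mm):
        eqs = equilibria(mm(30.0), ref)
        assert len(eqs) == 1
        assert eqs[0].branch == "membrane"

    def test_empty_below_nucleation_threshold(self, ref, mm):
        assert equilibria(mm(1.0), ref) == []

    @pytest.mark.parametrize("p_mmhg", [3.0, 7.0, 15.0, 25.0, 30.0])
    def test_roots_match_dense_scan_oracle(self, ref, mm, p_mmhg):
        eqs = equilibria(mm(p_mmhg), ref)
        oracle = grid_scan_oracle(mm(p_mmhg), ref)
        assert len(eqs) == len(oracle)
        for e, r_o in zip(eqs, sorted(oracle)):
            assert e.r_eq == pytest.approx(r_o, rel=1e-6)

    @pytest.mark.parametrize("p_mmhg", [3.0, 7.0, 30.0])
    def test_residual_resubstitution(self, ref, mm, p_mmhg):
        for e in equilibria(mm(p_mmhg), ref):
            lhs = 2 * e.Sigma_eq / e.r_eq + 2 * e.sigma_eq / e.R_eq
            assert abs(lhs - e.delta_p) / e.delta_p <= 1e-9


class TestStability:
    def test_cortex_branch_unstable_membrane_stable(self, ref, mm):
        cortex, membrane = equilibria(mm(7.0), ref)
        assert not cortex.stable and not stability(cortex, ref)
        assert membrane.stable and stability(membrane, ref)

    def test_high_pressure_equilibrium_stable(self, ref, mm):
        (e,) = equilibria(mm(30.0), ref)
        assert e.stable


class TestThresholds:
    def test_dagger_closed_form(self, ref):
        # cortex root exits at r = a: 2 sigma_0/a + 2 sigma_0/R0
        expected = 2 * ref.sigma_0 / ref.a + 2 * ref.sigma_0 / ref.R0  # 3394.8
        assert delta_p_dagger(ref) == pytest.approx(expected, rel=1e-5)
        assert pressure_to_mmhg(delta_p_dagger(ref)) == pytest.approx(
            25.46, abs=0.02)

    def test_star_about_two_point_four_mmhg(self, ref):
        assert pressure_to_mmhg(delta_p_star(ref)) == pytest.approx(2.4,
                                                                    abs=0.1)

    def test_star_matches_estimate_within_5_percent(self, ref):
        assert nucleation_pressure_estimate(ref) == pytest.approx(
            delta_p_star(ref), rel=0.05)

    def test_branch_counts_partition_pressure_axis(self, ref):
        grid = mmhg_to_pressure(np.linspace(1.0, 30.0, 12))
        records, dp_star, dp_dag = pressure_scan(ref, grid)
        for dp, recs in records.items():
            if dp < dp_star:
                assert len(recs) == 0
            elif dp < dp_dag:
                assert len(recs) == 2
            else:
                assert len(recs) == 1

    def test_scan_rejects_bad_grid(self, ref):
        with pytest.raises(ValueError, match="increasing"):
            pressure_scan(ref, [3.0, 2.0])


class TestMonotonePredictions:
    def test_threshold_tracks_cortical_tension(self, ref):
        soft = ref.replace(sigma_c=ref.sigma_c * 0.5)
        stiff = ref.replace(sigma_c=ref.sigma_c * 1.5)
        assert delta_p_star(soft) < delta_p_star(ref) < delta_p_star(stiff)

    def test_estimate_linear_in_total_tension(self, ref):
        doubled = ref.replace(sigma_m=2 * ref.sigma_m,
                              sigma_c=2 * ref.sigma_c)
        assert nucleation_pressure_estimate(doubled) == pytest.approx(
            2 * nucleation_pressure_estimate(ref), rel=1e-12)

    def test_larger_reservoir_lowers_threshold(self, ref):
        bigger = ref.replace(eps_star=1.0)
        assert nucleation_pressure_estimate(bigger) < \
            nucleation_pressure_estimate(ref)
        assert delta_p_star(bigger) < delta_p_star(ref)

    def test_softer_cortex_gives_larger_vacuoles(self, ref, mm):
        soft = ref.replace(sigma_c=ref.sigma_c * 0.5)
        r_ref = [e for e in equilibria(mm(7.0), ref) if e.stable][-1].r_eq
        r_soft = [e for e in equilibria(mm(7.0), soft) if e.stable][-1].r_eq
        assert r_soft > r_ref

    def test_volume_increases_with_pressure_on_stable_branch(self, ref, mm):
        vols = []
        for p in np.linspace(3.0, 30.0, 10):
            stable = [e for e in equilibria(mm(p), ref) if e.stable]
            vols.append(stable[-1].vacuole_volume)
        assert np.all(np.diff(vols) > 0)


class TestDegenerateReservoir:
    def test_threshold_below_nucleation_strain(self, ref):
        # eps* below a^2/d^2: no cortex branch, estimate undefined
        tiny = ref.replace(eps_star=1e-5)
        with pytest.raises(ValueError, match="nucleation strain"):
            nucleation_pressure_estimate(tiny)
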