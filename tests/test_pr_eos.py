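import dataclasses
import math

import numpy as np
import pytest

from sccosol.core_data import R_GAS, SolubilityDataset
from sccosol.pr_eos import (
    BAR,
    CO2_OMEGA,
    CO2_PC,
    CO2_TC,
    SQRT2,
    EosBinary,
    SolidEquilibriumInput,
    ambrose_walton_psub,
    fit_interaction_params,
    make_binary,
    mix_vdw2,
    phi_solute,
    predict_isotherm,
    pure_pr_params,
    solve_molar_volume,
    solve_solubility,
    _cubic_z_roots,
)


class TestPureParams:
    def test_alpha_is_one_at_critical_temperature(self):
        p = pure_pr_params(CO2_TC, CO2_PC, CO2_OMEGA, CO2_TC)
        a_crit = 0.45724 * R_GAS**2 * CO2_TC**2 / (CO2_PC * BAR)
        assert p.a == pytest.approx(a_crit, rel=1e-12)

    def test_co2_covolume(self):
        p = pure_pr_params(CO2_TC, CO2_PC, CO2_OMEGA, 318.0)
        assert p.b == pytest.approx(0.07780 * R_GAS * 304.18 / 73.8e5, rel=1e-12)
        assert p.b == pytest.approx(2.666e-5, rel=1e-3)

    def test_zero_acentric_factor_kappa(self):
        # alpha = [1 + kappa (1 - sqrt(Tr))]^2 with kappa = 0.37464 at omega=0
        T, Tc, Pc = 250.0, 304.18, 73.8
        p = pure_pr_params(Tc, Pc, 0.0, T)
        alpha = (1 + 0.37464 * (1 - math.sqrt(T / Tc))) ** 2
        assert p.a == pytest.approx(0.45724 * R_GAS**2 * Tc**2 * alpha / (Pc * BAR), rel=1e-12)


class TestMixingRules:
    def setup_method(self):
        self.binary = make_binary_demo()

    def test_pure_solvent_limit(self):
        a, b = mix_vdw2(self.binary, 0.0)
        assert a == pytest.approx(self.binary.co2.a)
        assert b == pytest.approx(self.binary.co2.b)

    def test_geometric_mean_cross_term_when_k12_zero(self):
        binary = dataclasses.replace(self.binary, k12=0.0)
        a, _ = mix_vdw2(binary, 0.5)
        a11, a22 = binary.co2.a, binary.solute.a
        expected = 0.25 * a11 + 0.25 * a22 + 0.5 * math.sqrt(a11 * a22)
        assert a == pytest.approx(expected, rel=1e-12)

    def test_symmetric_covolume_when_l12_zero(self):
        co2 = self.binary.co2
        binary = EosBinary(co2=co2, solute=co2, k12=0.0, l12=0.0)
        _, b = mix_vdw2(binary, 0.5)
        assert b == pytest.approx(co2.b, rel=1e-12)

    def test_interaction_bounds_enforced(self):
        with pytest.raises(ValueError):
            EosBinary(co2=self.binary.co2, solute=self.binary.solute, k12=2.5)


def make_binary_demo(T=318.0, k12=0.1, l12=0.05):
    from sccosol.core_data import nhm_solute

    return make_binary(nhm_solute(), T, k12, l12)


class TestCubicSolver:
    def test_ideal_gas_limit(self):
        v = solve_molar_volume(0.0, 0.0, 318.0, 150.0)
        assert v == pytest.approx(R_GAS * 318.0 / 150e5, rel=1e-12)

    def test_returned_volume_satisfies_pressure_identity(self):
        binary = make_binary_demo()
        a, b = mix_vdw2(binary, 1e-5)
        for P in (80.0, 150.0, 270.0):
            v = solve_molar_volume(a, b, 318.0, P)
            p_back = R_GAS * 318.0 / (v - b) - a / (v * (v + b) + b * (v - b))
            assert abs(p_back - P * BAR) / (P * BAR) < 1e-10

    def test_three_root_region_selects_minimal_gibbs_root(self):
        """Subcritical pure CO2: choice must match enumerating total Gibbs."""
        T, P = 280.0, 40.0
        pure = pure_pr_params(CO2_TC, CO2_PC, CO2_OMEGA, T)
        a, b = pure.a, pure.b
        rt = R_GAS * T
        A, B = a * P * BAR / rt**2, b * P * BAR / rt
        zs = [z for z in _cubic_z_roots(A, B) if z > B]
        assert len(zs) == 3

        def total_gibbs(z):
            v = z * rt / (P * BAR)
            # molar Gibbs up to a composition-independent constant
            return (
                -rt * math.log(v - b)
                - a / (2 * SQRT2 * b) * math.log((v + (1 + SQRT2) * b) / (v + (1 - SQRT2) * b))
                + P * BAR * v
            )

        best_v = min(zs, key=total_gibbs) * rt / (P * BAR)
        assert solve_molar_volume(a, b, T, P) == pytest.approx(best_v, rel=1e-12)



class TestFugacityCoefficient:
    def test_low_pressure_limit_is_unity(self):
        binary = make_binary_demo()
        assert phi_solute(binary, 318.0, 1e-4, 1e-6) == pytest.approx(1.0, abs=1e-4)

    def test_identical_components_reduce_to_pure_coefficient(self):
        co2 = pure_pr_params(CO2_TC, CO2_PC, CO2_OMEGA, 318.0)
        binary = EosBinary(co2=co2, solute=co2, k12=0.0, l12=0.0)
        a, b = mix_vdw2(binary, 0.3)
        v = solve_molar_volume(a, b, 318.0, 150.0)
        rt = R_GAS * 318.0
        Z = 150e5 * v / rt
        A, B = a * 150e5 / rt**2, b * 150e5 / rt
        ln_pure = (
            Z - 1 - math.log(Z - B)
            - A / (2 * SQRT2 * B) * math.log((Z + (1 + SQRT2) * B) / (Z + (1 - SQRT2) * B))
        )
        assert phi_solute(binary, 318.0, 150.0, 0.3) == pytest.approx(
            math.exp(ln_pure), rel=1e-10
        )

    def test_matches_helmholtz_derivative_oracle(self):
        """ln phi2 must equal d(A_res/RT)/dn2 - ln Z by central finite difference."""
        T, P, y2 = 318.0, 150.0, 0.01
        binary = make_binary_demo(T=T, k12=0.12, l12=0.07)
        a_mix, b_mix = mix_vdw2(binary, y2)
        v = solve_molar_volume(a_mix, b_mix, T, P)
        V = v  # total volume for n = 1 mol
        rt = R_GAS * T

        def helmholtz_res_over_rt(n1, n2):
            n = n1 + n2
            y = n2 / n
            a, b = mix_vdw2(binary, y)
            vm = V / n
            return n * (
                -math.log((vm - b) / vm)
                - a / (2 * SQRT2 * b * rt) * math.log((vm + (1 + SQRT2) * b) / (vm + (1 - SQRT2) * b))
            )

        h = 1e-7
        dF_dn2 = (helmholtz_res_over_rt(1 - y2, y2 + h) - helmholtz_res_over_rt(1 - y2, y2 - h)) / (
            2 * h
        )
        Z = P * BAR * v / rt
        ln_phi_fd = dF_dn2 - math.log(Z)
        assert math.log(phi_solute(binary, T, P, y2)) == pytest.approx(ln_phi_fd, abs=1e-6)


class TestSolubilitySolver:
    def test_ideal_limit_reduces_to_pressure_ratio(self):
        # negligible attraction/covolume makes phi = 1; zero solid volume
        # removes the Poynting factor, so y2 = psub / P exactly
        tiny = pure_pr_params(300.0, 50.0, 0.2, 318.0)
        tiny = dataclasses.replace(tiny, a=1e-30, b=1e-30)
        binary = EosBinary(co2=tiny, solute=tiny, k12=0.0, l12=0.0)
        inp = SolidEquilibriumInput(T=318.0, P=150.0, psub=1.0, v_solid=0.0)
        y = solve_solubility(inp, binary)
        assert y == pytest.approx(1.0 / 150e5, rel=1e-9)

    def test_monotone_in_sublimation_pressure(self, nhm_props):
        binary = make_binary_demo(T=308.0, k12=0.5, l12=0.5)
        ys = [
            solve_solubility(
                SolidEquilibriumInput(T=308.0, P=150.0, psub=p, v_solid=nhm_props.v_molar), binary
            )
            for p in (1e-4, 1e-3, 1e-2)
        ]
        assert ys[0] < ys[1] < ys[2]

    def test_agrees_with_bisection_oracle(self, nhm_props):
        T, P = 308.0, 120.0
        binary = make_binary_demo(T=T, k12=0.559, l12=0.567)
        psub = nhm_props.psub[T]
        inp = SolidEquilibriumInput(T=T, P=P, psub=psub, v_solid=nhm_props.v_molar)
        y_fp = solve_solubility(inp, binary, tol=1e-12)

        p_pa = P * BAR
        pref = psub / p_pa * math.exp((p_pa - psub) * nhm_props.v_molar * 1e-6 / (R_GAS * T))

        def residual(y):
            return y * phi_solute(binary, T, P, y) - pref

        # brute-force: scan a log grid for the first sign change, then bisect
        grid = np.logspace(-12, -1, 200)
        signs = np.sign([residual(y) for y in grid])
        (changes,) = np.nonzero(np.diff(signs) != 0)
        lo, hi = grid[changes[0]], grid[changes[0] + 1]
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if residual(mid) * residual(lo) > 0:
                lo = mid
            else:
                hi = mid
        assert y_fp == pytest.approx(0.5 * (lo + hi), rel=1e-8)


class TestInteractionFit:
    def _isotherm(self, nhm_data, nhm_props, k12, l12):
        iso = nhm_data.isotherm(308.0)
        y = predict_isotherm(iso, nhm_props, k12, l12)
        recs = tuple(
            dataclasses.replace(r, y2=float(v), S=float(v) * 1e4, sd_mean=None, U=None)
            for r, v in zip(iso.records, y)
        )
        return SolubilityDataset(recs, solute=nhm_props, label="synthetic-eos")

    def test_recovers_generating_interaction_parameters(self, nhm_data, nhm_props):
        truth = (0.28, 0.17)  # deliberately off the search grid
        synth = self._isotherm(nhm_data, nhm_props, *truth)
        k12, l12, stats = fit_interaction_params(synth, nhm_props)
        assert k12 == pytest.approx(truth[0], abs=1e-3)
        assert l12 == pytest.approx(truth[1], abs=1e-3)
        assert stats.aard_pct < 1e-4

    def test_requires_three_points(self, nhm_data, nhm_props):
        iso = nhm_data.isotherm(308.0)
        small = SolubilityDataset(iso.records[:2], solute=nhm_props)
        with pytest.raises(ValueError, match="at least 3"):
            fit_interaction_params(small, nhm_props)

    def test_requires_single_temperature(self, nhm_data, nhm_props):
        with pytest.raises(ValueError, match="single-temperature"):
            fit_interaction_params(nhm_data, nhm_props)


class TestAmbroseWalton:
    def test_limit_at_critical_point(self):
        p = ambrose_walton_psub(936.444, 11.77822, 0.5913, 936.443999)
        assert p == pytest.approx(11.77822e5, rel=1e-5)

    def test_domain_error_above_critical(self):
        with pytest.raises(ValueError):
            ambrose_walton_psub(936.444, 11.77822, 0.5913, 940.0)

    def test_monotone_increasing_in_temperature(self):
        ps = [ambrose_walton_psub(936.444, 11.77822, 0.5913, t) for t in (308, 318, 328, 338)]
        assert ps == sorted(ps)
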