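"""Closed-form model equations against independent oracles and identities."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from rnarefold.constants import R, K_B, H_PLANCK
from rnarefold.models import (ExchangeParams, TwoStateParams, WisemanParams,
                              arrhenius_lnk, backward_rate,
                              dilution_corrected_heat, eyring_deltaG,
                              ex2_deltaG_diss, fit_curve, gibbs_free_energy,
                              inversion_recovery_signal, itc_concentrations,
                              linear_fit, two_state_signal, vant_hoff_lnK,
                              wiseman_Q, wiseman_heat_content)


class TestTwoStateSignal:
    def test_initial_and_plateau(self):
        p = TwoStateParams(k_forward=1.0, K=1.0, uncage_fraction=1.0)
        assert two_state_signal(0.0, p, "fold3") == pytest.approx(0.0)
        assert two_state_signal(1e9, p, "fold3") == pytest.approx(0.5)

    def test_derived_25C_values(self):
        # K from the 25 C free-energy separation of -2.60 kJ/mol
        K = math.exp(2600 / (R * 298.15))
        p = TwoStateParams(k_forward=0.24, K=K, uncage_fraction=1.0)
        assert p.k_obs == pytest.approx(0.324, abs=5e-4)
        assert two_state_signal(1e6, p, "fold3") == pytest.approx(0.740, abs=1e-3)

    def test_agrees_with_ode_integration(self):
        """Closed form vs numerical integration of dA/dt = -kf A + kb B."""
        p = TwoStateParams(k_forward=0.13, K=3.7, uncage_fraction=1.0)
        kb = p.k_forward / p.K
        t = np.linspace(0, 40, 100)
        sol = solve_ivp(lambda _, y: [-p.k_forward * y[0] + kb * y[1],
                                      p.k_forward * y[0] - kb * y[1]],
                        (0, 40), [1.0, 0.0], t_eval=t,
                        rtol=1e-11, atol=1e-13)
        b = two_state_signal(t, p, "fold3")
        a = two_state_signal(t, p, "fold5")
        assert np.max(np.abs(b[1:] - sol.y[1][1:]) / sol.y[1][1:]) < 1e-8
        assert np.max(np.abs(a - sol.y[0]) / sol.y[0]) < 1e-8

    def test_population_conservation(self):
        p = TwoStateParams(k_forward=0.05, K=2.5, uncage_fraction=0.88,
                           amplitude=1.3)
        t = np.linspace(0, 100, 31)
        total = two_state_signal(t, p, "fold3") + two_state_signal(t, p, "fold5")
        assert np.allclose(total, p.amplitude)

    def test_printed_variant_negative_at_zero(self):
        # the documented printed form is unphysical for K > 1
        p = TwoStateParams(k_forward=0.1, K=4.0, uncage_fraction=1.0)
        assert two_state_signal(0.0, p, "fold3", printed_form=True) < 0

    def test_rejects_negative_time(self):
        p = TwoStateParams(k_forward=0.1, K=1.0)
        with pytest.raises(ValueError):
            two_state_signal(-1.0, p)


class TestBackwardRate:
    @pytest.mark.parametrize("kf,K,expected", [
        (0.24, 1.0, 0.24),
        (16.6e-3, 5.22, 3.18e-3),
        (0.0, 3.0, 0.0),
    ])
    def test_values(self, kf, K, expected):
        assert backward_rate(kf, K) == pytest.approx(expected, rel=1e-3)

    def test_rejects_nonpositive_K(self):
        with pytest.raises(ValueError):
            backward_rate(0.1, 0.0)


class TestThermodynamicRelations:
    def test_vant_hoff_zero_parameters(self):
        assert vant_hoff_lnK(300.0, 0.0, 0.0) == pytest.approx(0.0)

    def test_vant_hoff_study_parameters(self):
        lnK = vant_hoff_lnK(283.15, -30100.0, -92.0)
        assert lnK == pytest.approx(1.721, abs=2e-3)
        assert math.exp(lnK) == pytest.approx(5.59, abs=0.02)

    def test_gibbs_identity_with_vant_hoff(self):
        """deltaG(exp(lnK(T))) = deltaH - T deltaS exactly."""
        H, S, T = -30100.0, -92.0, 296.0
        K = math.exp(vant_hoff_lnK(T, H, S))
        assert gibbs_free_energy(K, T) == pytest.approx(H - T * S, rel=1e-12)

    @pytest.mark.parametrize("K,T,expected", [
        (1.0, 298.15, 0.0),
        (5.22, 283.15, -3890.0),
        (math.e, 310.0, -R * 310.0),
    ])
    def test_gibbs_values(self, K, T, expected):
        assert gibbs_free_energy(K, T) == pytest.approx(expected, abs=5.0)

    def test_arrhenius_slope(self):
        T = np.array([278.15, 288.15, 298.15])
        lnk = arrhenius_lnk(T, 100e3, 40.0)
        slope = np.polyfit(1 / T, lnk, 1)[0]
        assert slope == pytest.approx(-100e3 / R, rel=1e-10)

    def test_arrhenius_roundtrip_with_linear_fit(self):
        T = np.array([278.15, 288.15, 298.15])
        lnk = arrhenius_lnk(T, 73e3, 28.5)
        slope, intercept, _ = linear_fit(1 / T, lnk)
        assert -R * slope == pytest.approx(73e3, rel=1e-9)
        assert intercept == pytest.approx(28.5, rel=1e-9)


class TestEyring:
    def test_zero_barrier_at_attempt_frequency(self):
        T = 298.15
        k = K_B * T / H_PLANCK
        assert eyring_deltaG(k, T) == pytest.approx(0.0, abs=1e-9)

    def test_barrier_for_25C_forward_rate(self):
        assert eyring_deltaG(0.24, 298.15) == pytest.approx(76.5e3, rel=2e-3)

    def test_strictly_decreasing_in_rate(self):
        k = np.array([0.01, 0.1, 1.0, 10.0])
        dg = eyring_deltaG(k, 298.15)
        assert np.all(np.diff(dg) < 0)


def wiseman_oracle(M_t, X_t, p):
    """Bound-ligand heat via root-finding on the binding mass balance.

    Treating n independent sites of association constant K on each
    macromolecule: free + bound = X_t, bound = n*M_t*K*free/(1+K*free).
    """
    if X_t == 0:
        return 0.0
    def balance(free):
        return free + p.n * M_t * p.K_assoc * free / (1 + p.K_assoc * free) - X_t
    free = brentq(balance, 0.0, X_t, xtol=1e-18, rtol=1e-15)
    bound = X_t - free
    return bound * p.deltaH_bind * p.V0


class TestWisemanQ:
    def setup_method(self):
        self.p = WisemanParams(K_assoc=1 / 12.3e-6, n=2.0, deltaH_bind=-40e3,
                               V0=201.9e-6, M0=40e-6, Xs=920e-6)
        self.schedule = [0.2e-6] + [2e-6] * 19

    def test_no_ligand_no_heat(self):
        assert wiseman_Q(0, self.p, self.schedule) == 0.0

    def test_saturation_limit(self):
        p = WisemanParams(K_assoc=1e9, n=2.0, deltaH_bind=-40e3,
                          V0=200e-6, M0=40e-6, Xs=1e6)
        M_t, X_t = itc_concentrations(40e-6, p.V0, p.M0, p.Xs)
        q = wiseman_Q(1, p, [40e-6])
        assert q == pytest.approx(p.n * M_t * p.deltaH_bind * p.V0, rel=1e-4)

    def test_matches_mass_balance_oracle(self):
        """Closed form vs root-finding on the quadratic mass balance."""
        for i in range(1, 21):
            v = sum(self.schedule[:i])
            M_t, X_t = itc_concentrations(v, self.p.V0, self.p.M0, self.p.Xs)
            q = wiseman_Q(i, self.p, self.schedule)
            q_oracle = wiseman_oracle(M_t, X_t, self.p)
            assert abs(q - q_oracle) <= 1e-9 * abs(q_oracle)

    def test_monotone_in_titrant(self):
        """Heat content grows with ligand at fixed cell concentration."""
        p = WisemanParams(K_assoc=1e5, n=2.0, deltaH_bind=+30e3,
                          V0=201.9e-6, M0=40e-6, Xs=920e-6)
        X = np.linspace(1e-9, 400e-6, 200)
        q = [wiseman_heat_content(40e-6, x, p) for x in X]
        assert np.all(np.diff(q) >= 0)


class TestDilutionCorrectedHeat:
    def test_no_volume_is_difference(self):
        assert dilution_corrected_heat(3.0, 1.0, 0.0, 2e-4) == pytest.approx(2.0)

    def test_constant_heat_content(self):
        q0, dv, v0 = 5.0, 2e-6, 201.9e-6
        assert dilution_corrected_heat(q0, q0, dv, v0) == \
            pytest.approx(dv / v0 * q0)

    def test_telescoping_sum(self):
        rng = np.random.default_rng(5)
        q = np.concatenate([[0.0], np.cumsum(rng.uniform(0, 1, 10))])
        dv, v0 = 2e-6, 201.9e-6
        total = sum(dilution_corrected_heat(q[i], q[i - 1], dv, v0)
                    - dv / v0 * (q[i] + q[i - 1]) / 2 for i in range(1, 11))
        assert total == pytest.approx(q[10] - q[0])


class TestInversionRecovery:
    def test_starts_at_equilibrium(self):
        p = ExchangeParams(k_ex=2.0, R1_imino=3.0, R1_water=1.0)
        assert inversion_recovery_signal(0.0, p, S0=0.7) == pytest.approx(0.7)

    def test_no_exchange_is_flat(self):
        p = ExchangeParams(k_ex=0.0, R1_imino=3.0, R1_water=1.0)
        tau = np.linspace(0, 3, 20)
        assert np.allclose(inversion_recovery_signal(tau, p), 1.0)

    def test_minimum_position_analytic(self):
        """dS/dtau = 0 at tau* = ln(5)/4 for these rates."""
        p = ExchangeParams(k_ex=2.0, R1_imino=3.0, R1_water=1.0,
                           inversion_efficiency=2.0)
        tau = np.linspace(0.0, 2.0, 200001)
        s = inversion_recovery_signal(tau, p)
        assert tau[np.argmin(s)] == pytest.approx(math.log(5) / 4, abs=1e-4)

    def test_continuous_at_degenerate_limit(self):
        tau = np.linspace(0, 2, 50)
        eps = 1e-6
        # R1_imino + k_ex approaches R1_water = 2.0
        near = ExchangeParams(k_ex=1.0, R1_imino=1.0 + eps, R1_water=2.0)
        at = ExchangeParams(k_ex=1.0, R1_imino=1.0, R1_water=2.0)
        s_near = inversion_recovery_signal(tau, near)
        s_at = inversion_recovery_signal(tau, at)
        assert np.max(np.abs(s_near - s_at)) < 1e-5


class TestEx2:
    def test_unit_ratio_gives_RT(self):
        T = 298.15
        assert ex2_deltaG_diss(1.0, math.e, T) == pytest.approx(R * T)

    def test_limit_to_zero(self):
        assert ex2_deltaG_diss(0.999999, 1.0, 298.15) == pytest.approx(0.0, abs=0.1)

    def test_study_basepair_ratio(self):
        """k_ex/k_intr = exp(-16.69 kJ/mol / RT) round trip for C4-G9."""
        ratio = math.exp(-16690 / (R * 298.15))
        assert ratio == pytest.approx(1.19e-3, rel=5e-3)
        assert ex2_deltaG_diss(ratio * 100.0, 100.0, 298.15) == \
            pytest.approx(16690.0, rel=1e-12)

    def test_rejects_ex1(self):
        with pytest.raises(ValueError):
            ex2_deltaG_diss(5.0, 2.0, 298.15)


class TestFitCurve:
    @staticmethod
    def _line(x, a):
        return a * x

    def test_exact_line(self):
        res = fit_curve(self._line, [1.0, 2.0], [2.0, 4.0], initial={"a": 1.0})
        assert res["a"] == pytest.approx(2.0, rel=1e-9)

    def test_fixed_parameter_has_no_stderr(self):
        def model(x, a, b):
            return a * x + b
        res = fit_curve(model, np.arange(5.0), 2 * np.arange(5.0) + 1,
                        initial={"a": 1.0, "b": 1.0}, fixed={"b"})
        assert "b" not in res.standard_errors
        assert "b" in res.fixed_mask
        assert res["b"] == 1.0

    def test_noiseless_recovery_of_exponential(self):
        def model(x, k, a):
            return a * np.exp(-k * x)
        x = np.linspace(0, 5, 30)
        y = model(x, 0.7, 2.0)
        res = fit_curve(model, x, y, initial={"k": 0.3, "a": 1.0})
        assert res["k"] == pytest.approx(0.7, rel=1e-7)
        assert res.success

    def test_deterministic(self):
        def model(x, k, a):
            return a * np.exp(-k * x)
        x = np.linspace(0, 5, 30)
        rng = np.random.default_rng(0)
        y = model(x, 0.7, 2.0) + rng.normal(0, 0.05, 30)
        r1 = fit_curve(model, x, y, initial={"k": 0.3, "a": 1.0})
        r2 = fit_curve(model, x, y, initial={"k": 0.3, "a": 1.0})
        assert r1.parameters == r2.parameters


class TestLinearFit:
    def test_collinear_zero_residual(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, _ = linear_fit(x, 3 * x - 1)
        assert slope == pytest.approx(3.0)
        assert intercept == pytest.approx(-1.0)

    def test_equal_weights_reduce_to_ols(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 12)
        y = 2 * x + rng.normal(0, 0.1, 12)
        s1, i1, _ = linear_fit(x, y)
        s2, i2, _ = linear_fit(x, y, np.full(12, 0.37))
        assert s1 == pytest.approx(s2)
        assert i1 == pytest.approx(i2)

    def test_rejects_degenerate_abscissa(self):
        with pytest.raises(ValueError):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            linear_fit([1.0, 2.0], [1.0, 2.0])
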