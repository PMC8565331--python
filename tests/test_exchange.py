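"""Imino-exchange fits, EX2 base-pair thermodynamics, destabilization maps."""

import math

import numpy as np
import pytest

from rnarefold.constants import R, T_REF, celsius_to_kelvin
from rnarefold.exchange import (BasePairStability, ExchangeRecoveryModel,
                                IntrinsicExchangeModel,
                                InversionRecoverySeries,
                                basepair_thermodynamics,
                                destabilization_profile, fit_exchange_series)
from rnarefold.models import ExchangeParams, inversion_recovery_signal
from rnarefold.synthetic import GeneratorConfig, gen_inversion_recovery


def make_series(k_ex, R1_imino=3.0, R1_water=1.0, eff=1.8, noise=0.0, seed=0,
                n=12, max_tau=2.0, temperature=25.0, base_pair="C4-G9"):
    tau = np.linspace(0, max_tau, n)
    p = ExchangeParams(k_ex=k_ex, R1_imino=R1_imino, R1_water=R1_water,
                       inversion_efficiency=eff)
    y = inversion_recovery_signal(tau, p, S0=1.0)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, n)
    return InversionRecoverySeries(tau, y, base_pair, temperature)


class TestExchangeFit:
    def test_noiseless_roundtrip(self):
        res = fit_exchange_series(make_series(2.0))
        assert res.k_ex == pytest.approx(2.0, rel=1e-6)
        assert not res.flagged

    def test_flat_series_flagged(self):
        tau = np.linspace(0, 2, 12)
        s = InversionRecoverySeries(tau, np.ones(12), "C4-G9", 25.0)
        res = fit_exchange_series(s)
        assert res.flagged

    def test_noisy_recovery_within_ci(self):
        """k_ex = 5 with 3% noise: truth inside 2x the 95% CI in >=90% of reps."""
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            s = make_series(5.0, R1_imino=3.0, R1_water=1.0, noise=0.03,
                            seed=seed)
            res = fit_exchange_series(s)
            lo, hi = res.confidence_interval
            width = hi - lo
            if lo - width / 2 <= 5.0 <= hi + width / 2:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_requires_six_delays(self):
        with pytest.raises(ValueError):
            ExchangeRecoveryModel(make_series(2.0, n=5))


class TestIntrinsicModel:
    def test_reference_rate(self):
        m = IntrinsicExchangeModel(k_ref=100.0, Ea=20e3)
        assert m.rate(T_REF) == pytest.approx(100.0)

    def test_arrhenius_temperature_dependence(self):
        m = IntrinsicExchangeModel(k_ref=100.0, Ea=20e3)
        T = 310.0
        expected = 100.0 * math.exp(-20e3 / R * (1 / T - 1 / T_REF))
        assert m.rate(T) == pytest.approx(expected)


class TestBasePairThermodynamics:
    K_INTR = IntrinsicExchangeModel(k_ref=200.0, Ea=16e3)

    def k_ex_from(self, dH, dS, temps_C):
        out = {}
        for t in temps_C:
            T = celsius_to_kelvin(t)
            out[t] = math.exp(-(dH - T * dS) / (R * T)) * self.K_INTR.rate(T)
        return out

    def test_c4g9_roundtrip(self):
        """Table-style C4-G9 free-RNA parameters: deltaG_diss = 16.69 kJ/mol."""
        k_by_T = self.k_ex_from(16.69e3, 0.0, range(10, 45, 5))
        stab = basepair_thermodynamics(k_by_T, self.K_INTR, base_pair="C4-G9")
        assert stab.deltaG_diss(T_REF) == pytest.approx(16.69e3, rel=1e-6)
        assert stab.deltaH_diss == pytest.approx(16.69e3, rel=1e-5)

    def test_zero_entropy_means_G_equals_H(self):
        k_by_T = self.k_ex_from(20e3, 0.0, (10, 20, 30, 40))
        stab = basepair_thermodynamics(k_by_T, self.K_INTR)
        for T in (280.0, 298.15, 310.0):
            assert stab.deltaG_diss(T) == pytest.approx(stab.deltaH_diss,
                                                        rel=1e-5)

    def test_k_intr_rescale_shifts_entropy_only(self):
        """k_intr -> c*k_intr shifts deltaS by R ln c, leaves deltaH."""
        k_by_T = self.k_ex_from(30e3, 20.0, (10, 20, 30, 40))
        base = basepair_thermodynamics(k_by_T, self.K_INTR)
        c = 3.7
        scaled_model = IntrinsicExchangeModel(k_ref=self.K_INTR.k_ref * c,
                                              Ea=self.K_INTR.Ea)
        scaled = basepair_thermodynamics(k_by_T, scaled_model)
        assert scaled.deltaH_diss == pytest.approx(base.deltaH_diss, abs=1.0)
        assert scaled.deltaS_diss - base.deltaS_diss == \
            pytest.approx(-R * math.log(c), rel=1e-6)

    def test_reporting_identity_machine_precision(self):
        k_by_T = self.k_ex_from(45e3, 80.0, (10, 20, 30, 40))
        stab = basepair_thermodynamics(k_by_T, self.K_INTR)
        assert stab.deltaG_diss(T_REF) == \
            stab.deltaH_diss - T_REF * stab.deltaS_diss

    def test_monotone_k_ex_for_positive_enthalpy(self):
        k_by_T = self.k_ex_from(45e3, 80.0, (10, 20, 30, 40))
        vals = [k_by_T[t] for t in sorted(k_by_T)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_ex1_violation_rejected(self):
        k_by_T = {10.0: 500.0, 20.0: 600.0, 30.0: 700.0}
        with pytest.raises(ValueError, match="EX2"):
            basepair_thermodynamics(k_by_T, self.K_INTR)


def stability(label, dG_kJ, condition):
    """Stability record with the given deltaG at 25 C and zero entropy."""
    return BasePairStability(label, dG_kJ * 1e3, 0.0, condition)


class TestDestabilizationProfile:
    def test_identical_inputs_zero_ddg(self):
        free = [stability("C4-G9", 16.69, "rna_alone")]
        cplx = [stability("C4-G9", 16.69, "complex")]
        prof = destabilization_profile(free, cplx, [25.0])
        assert prof.per_pair["C4-G9"][25.0] == pytest.approx(0.0)

    def test_study_ddg_values(self):
        """ddG at 25 C: C3-G10 4.05 kJ/mol, G10-C15 5.71 kJ/mol."""
        free = [stability("C3-G10", 23.43, "rna_alone"),
                stability("G10-C15", 21.53, "rna_alone")]
        cplx = [stability("C3-G10", 19.38, "complex"),
                stability("G10-C15", 15.82, "complex")]
        prof = destabilization_profile(free, cplx, [25.0])
        assert prof.per_pair["C3-G10"][25.0] == pytest.approx(4.05e3)
        assert prof.per_pair["G10-C15"][25.0] == pytest.approx(5.71e3)

    def test_missing_pairs_reported_absent_not_zero(self):
        free = [stability("C4-G9", 16.69, "rna_alone"),
                stability("G5-C20", 12.0, "rna_alone")]
        cplx = [stability("C4-G9", 14.21, "complex")]
        prof = destabilization_profile(free, cplx, [25.0])
        assert "G5-C20" not in prof.per_pair
        assert "G5-C20" in prof.missing

    def test_fold_means(self):
        free = [stability("C3-G10", 23.43, "rna_alone"),
                stability("C4-G9", 16.69, "rna_alone")]
        cplx = [stability("C3-G10", 19.38, "complex"),
                stability("C4-G9", 14.21, "complex")]
        prof = destabilization_profile(
            free, cplx, [25.0],
            fold_of_pair={"C3-G10": "fold5", "C4-G9": "fold5"})
        assert prof.mean_by_fold("fold5", 25.0) == \
            pytest.approx((4.05e3 + 2.48e3) / 2)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            destabilization_profile([stability("A", 10, "rna_alone")],
                                    [stability("B", 10, "complex")], [25.0])


class TestSyntheticExchange:
    def test_generator_stage_roundtrip(self, make_config):
        """Noiseless generated series recover the generating thermodynamics."""
        cfg = make_config(exchange_noise=0.0, conditions=("rna_alone",),
                          temperatures_C=(10.0, 20.0, 30.0, 40.0))
        series, manifest = gen_inversion_recovery(
            cfg, basepairs={"A8-U17": ("fold3", 36.83, 20.35, 22.52, 8.65)})
        k_by_T = {s.temperature: fit_exchange_series(s).k_ex for s in series}
        stab = basepair_thermodynamics(k_by_T, cfg.k_intr)
        assert stab.deltaH_diss == pytest.approx(36.83e3, rel=1e-4)
        assert stab.deltaS_diss * T_REF == pytest.approx(20.35e3, rel=1e-3)

    def test_ex2_violation_refused(self, make_config):
        cfg = make_config(exchange_noise=0.0, conditions=("rna_alone",),
                          temperatures_C=(40.0,))
        with pytest.raises(ValueError, match="EX2"):
            gen_inversion_recovery(cfg, basepairs={
                "open": ("fold5", -1.0, 0.0, -1.0, 0.0)})

    def test_seed_determinism(self, make_config):
        s1, _ = gen_inversion_recovery(make_config())
        s2, _ = gen_inversion_recovery(make_config())
        assert all(np.array_equal(a.integrals, b.integrals)
                   for a, b in zip(s1, s2))
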