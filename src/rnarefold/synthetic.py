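"""Synthetic raw data for every input modality of the analysis.

Generates, with seeded Gaussian noise, the four kinds of raw input the
pipeline consumes:

* 1D imino spectra — two Lorentzian reporter peaks whose area ratio
  follows a van't Hoff K(T), with line broadening under the chaperone
  complex condition;
* photolysis-triggered refolding traces — the two-state integrated
  rate law with incomplete uncaging (88% by default);
* ITC thermograms — Wiseman one-site heats with the cell-displacement
  dilution correction and the small 0.2 ul pre-injection;
* water inversion-recovery series — two-compartment magnetization
  transfer with k_ex(T) built from per-base-pair opening
  thermodynamics via the EX2 relation.

Defaults reproduce the study conditions (temperature grid 5-40 C,
injection design 40 uM cell / 201.9 ul / 920 uM syringe, 19 x 2 ul).
A fixed seed makes every generator bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import R, celsius_to_kelvin
from .equilibrium import PeakWindow, Spectrum1D
from .exchange import IntrinsicExchangeModel, InversionRecoverySeries
from .itc import ITCExperiment, predicted_heats
from .kinetics import KineticTrace
from .models import (ExchangeParams, TwoStateParams, WisemanParams,
                     inversion_recovery_signal, two_state_signal,
                     vant_hoff_lnK)

__all__ = [
    "GeneratorConfig",
    "gen_spectrum_series",
    "gen_refolding_traces",
    "gen_itc",
    "gen_inversion_recovery",
    "generate_study",
]

#: default temperature grid, degrees C (study range)
DEFAULT_TEMPS_C = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0)

#: conformational equilibrium of the free RNA (van't Hoff parameters)
VANT_HOFF_FREE = {"deltaH": -30.1e3, "deltaS": -92.0}
#: and in the 3-eq chaperone complex
VANT_HOFF_COMPLEX = {"deltaH": -11.87e3, "deltaS": -27.0}

#: forward refolding rates of the free RNA, 1/s, by temperature C
#: (5 and 25 C are the reported means; others interpolate on the
#: Arrhenius line through those two points)
RATES_FREE_5C = 11e-3
RATES_FREE_25C = 240e-3

#: mean chaperone acceleration of the forward rate at 5 C
ACCELERATION_5C = 2.17

#: per-base-pair opening thermodynamics (kJ/mol and kJ/mol at 25 C,
#: converted below), free RNA and complex, used by the exchange generator
BASEPAIR_TABLE = {
    # label: (fold, dH_free, dST_free, dH_cplx, dST_cplx)  [kJ/mol at 25 C]
    "C4-G9":   ("fold5", 16.69, 0.00, 22.80, 8.60),
    "C3-G10":  ("fold5", 93.23, 69.80, 101.49, 82.11),
    "G1-C12":  ("fold5", 35.34, 20.53, 41.78, 30.09),
    "G10-C15": ("fold3", 56.82, 35.29, 47.86, 32.05),
    "G9-C16":  ("fold3", 46.10, 24.75, 27.48, 8.62),
    "A8-U17":  ("fold3", 36.83, 20.35, 22.52, 8.65),
    "A7-U18":  ("fold3", 58.41, 39.25, 62.44, 46.08),
}


def arrhenius_rate_free(T_C: float) -> float:
    """Forward rate of the free RNA on the two-point Arrhenius line."""
    T1, T2 = celsius_to_kelvin(5.0), celsius_to_kelvin(25.0)
    T = celsius_to_kelvin(T_C)
    slope = math.log(RATES_FREE_25C / RATES_FREE_5C) / (1 / T2 - 1 / T1)
    return RATES_FREE_5C * math.exp(slope * (1 / T - 1 / T1))


def equilibrium_K(T_C: float, condition: str = "rna_alone") -> float:
    """K(T) = [3']/[5'] from the condition's van't Hoff parameters."""
    pars = VANT_HOFF_COMPLEX if condition == "complex" else VANT_HOFF_FREE
    return float(np.exp(vant_hoff_lnK(celsius_to_kelvin(T_C), **pars)))


@dataclass
class GeneratorConfig:
    """Study-level configuration of the synthetic generators.

    Noise levels are per modality: spectra and traces specify a
    signal-to-noise ratio (peak height over noise RMS), ITC a relative
    heat noise, inversion recovery a relative integral noise. A fixed
    seed makes the output byte-identical between runs.
    """

    seed: int = 0
    temperatures_C: tuple = DEFAULT_TEMPS_C
    conditions: tuple = ("rna_alone", "complex")
    # spectra
    spectrum_snr: float = 50.0
    spectrum_points: int = 2048
    ppm_range: tuple = (11.0, 15.0)
    peak_ppm: dict = field(default_factory=lambda: {"fold3": 13.2, "fold5": 14.1})
    hwhm_ppm: float = 0.0125          # 15 Hz FWHM at 600 MHz
    complex_broadening: float = 2.0   # linewidth factor under the complex
    # kinetics
    trace_snr: float = 20.0
    trace_points: int = 100
    trace_duration: float | None = None   # default: 5 relaxation times
    uncage_fraction: float = 0.88
    acceleration: float = ACCELERATION_5C
    # ITC
    itc_noise: float = 0.01           # relative to the largest heat
    itc_K_D: float = 12.3e-6
    itc_n: float = 2.0
    itc_deltaH: float = -40e3
    pre_injection_ul: float = 0.2
    n_injections: int = 19
    injection_ul: float = 2.0
    # exchange
    exchange_noise: float = 0.01
    exchange_delays: int = 12
    exchange_max_delay: float = 2.0
    R1_water: float = 1.0
    R1_imino: float = 3.0
    inversion_efficiency: float = 1.8
    k_intr: IntrinsicExchangeModel = field(default_factory=IntrinsicExchangeModel)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


# stream ids so each modality draws from an independent substream
_STREAM_SPECTRA, _STREAM_TRACES, _STREAM_ITC, _STREAM_EXCHANGE = 1, 2, 3, 4


def default_windows(cfg: GeneratorConfig) -> list[PeakWindow]:
    """Integration windows bracketing the two generated reporter peaks."""
    half = 20 * cfg.hwhm_ppm * cfg.complex_broadening
    return [
        PeakWindow("U17", cfg.peak_ppm["fold3"] - half,
                   cfg.peak_ppm["fold3"] + half, "fold3"),
        PeakWindow("U11", cfg.peak_ppm["fold5"] - half,
                   cfg.peak_ppm["fold5"] + half, "fold5"),
    ]


def _lorentzian(x, area, center, hwhm):
    return area / math.pi * hwhm / ((x - center) ** 2 + hwhm ** 2)


def gen_spectrum_series(cfg: GeneratorConfig):
    """Two-peak imino spectra per (temperature, condition).

    The 3'-reporter area is K(T) times the 5'-reporter area (unit area).
    Returns ``(spectra, manifest)``; the manifest records the true K per
    spectrum for recovery tests.
    """
    rng = cfg.rng(_STREAM_SPECTRA)
    ppm = np.linspace(cfg.ppm_range[0], cfg.ppm_range[1], cfg.spectrum_points)
    spectra, manifest = [], []
    for condition in cfg.conditions:
        broaden = cfg.complex_broadening if condition == "complex" else 1.0
        hwhm = cfg.hwhm_ppm * broaden
        for T_C in cfg.temperatures_C:
            K = equilibrium_K(T_C, condition)
            y = (_lorentzian(ppm, K, cfg.peak_ppm["fold3"], hwhm)
                 + _lorentzian(ppm, 1.0, cfg.peak_ppm["fold5"], hwhm))
            if cfg.spectrum_snr and np.isfinite(cfg.spectrum_snr):
                peak_height = 1.0 / (math.pi * hwhm)   # unit-area peak height
                y = y + rng.normal(0.0, peak_height / cfg.spectrum_snr, y.shape)
            spectra.append(Spectrum1D(ppm.copy(), y, T_C, condition))
            manifest.append({"modality": "spectrum", "temperature_C": T_C,
                             "condition": condition, "true_K": K})
    return spectra, manifest


def gen_refolding_traces(cfg: GeneratorConfig, temperatures_C=None,
                         n_replicates: int = 1, conditions=None):
    """Refolding traces (both reporters) per temperature and condition.

    The free-RNA forward rate follows the study Arrhenius line; the
    complex rate is the free rate times the acceleration factor. Noise
    is Gaussian with RMS = plateau / trace_snr.
    """
    rng = cfg.rng(_STREAM_TRACES)
    temps = cfg.temperatures_C if temperatures_C is None else temperatures_C
    conds = cfg.conditions if conditions is None else conditions
    traces, manifest = [], []
    for condition in conds:
        for T_C in temps:
            k_f = arrhenius_rate_free(T_C)
            if condition == "complex":
                k_f = k_f * cfg.acceleration
            K = equilibrium_K(T_C, "rna_alone")
            p = TwoStateParams(k_forward=k_f, K=K,
                               uncage_fraction=cfg.uncage_fraction)
            duration = cfg.trace_duration or 5.0 / p.k_obs
            t = np.linspace(0.0, duration, cfg.trace_points)
            for rep in range(n_replicates):
                for fold, label in (("fold3", "U17"), ("fold5", "U11")):
                    clean = two_state_signal(t, p, reporter=fold)
                    plateau = p.uncage_fraction * K / (K + 1.0)
                    noise_rms = plateau / cfg.trace_snr if cfg.trace_snr else 0.0
                    y = clean + rng.normal(0.0, noise_rms, t.shape)
                    traces.append(KineticTrace(t.copy(), y, label, fold,
                                               T_C, condition))
                    manifest.append({"modality": "trace",
                                     "temperature_C": T_C,
                                     "condition": condition, "fold": fold,
                                     "replicate": rep, "true_k_forward": k_f,
                                     "true_K": K,
                                     "noise_rms": noise_rms})
    return traces, manifest


def gen_itc(cfg: GeneratorConfig, temperature_C: float = 25.0,
            rng: np.random.Generator | None = None):
    """One synthetic ITC titration at the study injection design.

    A 0.2 ul pre-injection (heat kept, flagged small) is followed by 19
    injections of 2 ul. Heat noise is Gaussian with RMS = itc_noise
    times the largest model heat. Returns ``(experiment, manifest)``.
    """
    if rng is None:
        rng = cfg.rng(_STREAM_ITC)
    volumes = [cfg.pre_injection_ul * 1e-6] + \
              [cfg.injection_ul * 1e-6] * cfg.n_injections
    p = WisemanParams(K_assoc=1.0 / cfg.itc_K_D, n=cfg.itc_n,
                      deltaH_bind=cfg.itc_deltaH,
                      V0=201.9e-6, M0=40e-6, Xs=920e-6)
    heats = predicted_heats(p, volumes)
    noise_rms = cfg.itc_noise * float(np.abs(heats).max())
    noisy = heats + rng.normal(0.0, noise_rms, heats.shape)
    exp = ITCExperiment(temperature=temperature_C,
                        injections=list(zip(volumes, noisy)),
                        V0=p.V0, M0=p.M0, Xs=p.Xs,
                        first_injection_small=True)
    manifest = {"modality": "itc", "temperature_C": temperature_C,
                "true_K_D": cfg.itc_K_D, "true_n": cfg.itc_n,
                "true_deltaH": cfg.itc_deltaH, "noise_rms": noise_rms}
    return exp, manifest


def gen_inversion_recovery(cfg: GeneratorConfig, basepairs=None):
    """Inversion-recovery series per (base pair, temperature, condition).

    k_ex(T) is built from each pair's opening thermodynamics through the
    EX2 relation k_ex = exp(-deltaG_diss/RT) * k_intr(T). Refuses to
    generate when any k_ex reaches k_intr (EX2 violation).
    """
    rng = cfg.rng(_STREAM_EXCHANGE)
    table = basepairs if basepairs is not None else BASEPAIR_TABLE
    tau = np.linspace(0.0, cfg.exchange_max_delay, cfg.exchange_delays)
    series, manifest = [], []
    for label, (fold, dH_f, dST_f, dH_c, dST_c) in table.items():
        for condition in cfg.conditions:
            dH, dST = (dH_f, dST_f) if condition == "rna_alone" else (dH_c, dST_c)
            dH, dS = dH * 1e3, dST * 1e3 / 298.15   # to J/mol and J/(mol K)
            for T_C in cfg.temperatures_C:
                T = celsius_to_kelvin(T_C)
                K_diss = math.exp(-(dH - T * dS) / (R * T))
                k_intr = cfg.k_intr.rate(T)
                k_ex = K_diss * k_intr
                if k_ex >= k_intr:
                    raise ValueError(
                        f"EX2 violated for {label} at {T_C} C: "
                        f"k_ex={k_ex:.3g} >= k_intr={k_intr:.3g}")
                p = ExchangeParams(k_ex=k_ex, R1_imino=cfg.R1_imino,
                                   R1_water=cfg.R1_water,
                                   inversion_efficiency=cfg.inversion_efficiency)
                y = inversion_recovery_signal(tau, p, S0=1.0)
                y = y + rng.normal(0.0, cfg.exchange_noise, y.shape) \
                    if cfg.exchange_noise else y
                series.append(InversionRecoverySeries(tau.copy(), y, label,
                                                      T_C, condition))
                manifest.append({"modality": "exchange", "base_pair": label,
                                 "fold": fold, "temperature_C": T_C,
                                 "condition": condition, "true_k_ex": k_ex,
                                 "true_deltaG_diss": dH - T * dS})
    return series, manifest


def generate_study(cfg: GeneratorConfig):
    """All modalities at the study conditions; returns a dict + manifest."""
    spectra, man_s = gen_spectrum_series(cfg)
    traces, man_t = gen_refolding_traces(cfg)
    itc_exp, man_i = gen_itc(cfg)
    exchange, man_e = gen_inversion_recovery(cfg)
    return (
        {"spectra": spectra, "traces": traces, "itc": [itc_exp],
         "exchange": exchange},
        {"seed": cfg.seed,
         "entries": man_s + man_t + [man_i] + man_e},
    )
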