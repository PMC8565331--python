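"""Kinetics stage: photolysis-triggered refolding traces and Arrhenius analysis.

A laser pulse uncages the RNA trapped in the 5'-fold; imino reporter
peaks of both folds are then followed in time. Each trace is fitted to
the integrated rate law of a reversible unimolecular two-state reaction
with the equilibrium constant K(T) held fixed at the value measured for
the unmodified RNA, so the only kinetic parameter is the forward rate
k_5'-3'. The backward rate follows from detailed balance,
k_3'-5' = k_5'-3' / K. Rates at several temperatures give the
activation enthalpy by an Arrhenius fit, and paired free/complex rate
tables give the chaperone acceleration factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R, celsius_to_kelvin
from .models import (ThermoFit, TwoStateParams, fit_curve, linear_fit,
                     two_state_signal)

__all__ = [
    "KineticTrace",
    "RateEntry",
    "RateTable",
    "RefoldingTraceModel",
    "RefoldingTraceResults",
    "fit_refolding_trace",
    "ArrheniusModel",
    "ArrheniusResults",
    "arrhenius_analysis",
    "acceleration_factor",
]


@dataclass
class KineticTrace:
    """One reporter peak's normalized integral vs time after photolysis."""

    time: np.ndarray        # s, strictly increasing, >= 0
    signal: np.ndarray
    peak_label: str
    fold: str               # "fold3" (rising) or "fold5" (decaying)
    temperature: float      # degrees C
    condition: str = "rna_alone"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time[0] < 0 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing and >= 0")
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")


@dataclass
class RateEntry:
    temperature: float      # degrees C
    condition: str
    direction: str          # "5to3" or "3to5"
    rate: float             # 1/s
    error: float            # 1/s
    per_peak: dict[str, float] = field(default_factory=dict)


class RateTable:
    """Rates keyed by (temperature, condition, direction).

    Backward entries are derived from forward ones by k_3'-5' = k_5'-3'/K,
    so that identity holds by construction.
    """

    def __init__(self):
        self._entries: dict[tuple[float, str, str], RateEntry] = {}

    def add(self, entry: RateEntry):
        self._entries[(entry.temperature, entry.condition, entry.direction)] = entry

    def add_forward_with_K(self, temperature, condition, rate, error, K,
                           per_peak=None):
        """Add a forward rate and its detailed-balance backward partner."""
        per_peak = per_peak or {}
        self.add(RateEntry(temperature, condition, "5to3", rate, error, per_peak))
        self.add(RateEntry(temperature, condition, "3to5", rate / K, error / K,
                           {k: v / K for k, v in per_peak.items()}))

    def get(self, temperature, condition, direction) -> RateEntry:
        try:
            return self._entries[(temperature, condition, direction)]
        except KeyError:
            raise KeyError(
                f"no rate for T={temperature}C, {condition}, {direction}") from None

    def entries(self):
        return list(self._entries.values())

    def temperatures(self, condition, direction):
        return sorted(t for (t, c, d) in self._entries
                      if c == condition and d == direction)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"temperature_C": e.temperature, "condition": e.condition,
                 "direction": e.direction, "rate_per_s": e.rate,
                 "rate_err_per_s": e.error} for e in self.entries()]
        return pd.DataFrame(rows)


class RefoldingTraceModel:
    """Two-state refolding rate-law model for one kinetic trace.

    K is fixed at the independently measured equilibrium constant (the
    experiment cannot separate K from the rate on a single trace); the
    amplitude is a free nuisance parameter that absorbs the uncaging
    fraction unless ``fit_uncage_fraction`` is requested. A sensitivity
    mode (``fix_K=False``) co-fits K for diagnostics.
    """

    def __init__(self, trace: KineticTrace, K_at_T: float, *,
                 fix_K: bool = True, uncage_fraction: float = 0.88,
                 fit_uncage_fraction: bool = False, t0: float = 0.0,
                 sigma=None):
        if not K_at_T > 0:
            raise ValueError("K_at_T must be > 0")
        self.trace = trace
        self.K = float(K_at_T)
        self.fix_K = fix_K
        self.uncage_fraction = uncage_fraction
        self.fit_uncage_fraction = fit_uncage_fraction
        self.t0 = t0
        self.sigma = sigma

    def _model(self, t, k_forward, K, amplitude, uncage_fraction):
        p = TwoStateParams(k_forward=k_forward, K=K, amplitude=amplitude,
                           uncage_fraction=uncage_fraction)
        return two_state_signal(np.clip(t - self.t0, 0.0, None), p,
                                reporter=self.trace.fold)

    def fit(self, k_initial: float | None = None) -> "RefoldingTraceResults":
        t, y = self.trace.time, self.trace.signal
        if len(t) < 4:
            raise ValueError("too few points for a refolding fit")
        if k_initial is None:
            span = t[-1] - t[0]
            k_initial = 3.0 / span if span > 0 else 1.0
        # For the rising 3'-reporter the uncaging fraction is a pure scale
        # and is absorbed by the free amplitude; for the decaying
        # 5'-reporter it also sets the non-refolding offset, so it is held
        # at its known value (0.88 by default) unless co-fitted.
        uncage = self.uncage_fraction
        if self.trace.fold == "fold3" and not self.fit_uncage_fraction:
            uncage = 1.0
        fixed = {"uncage_fraction"} if not self.fit_uncage_fraction else set()
        if self.fix_K:
            fixed.add("K")
        initial = {"k_forward": k_initial, "K": self.K,
                   "amplitude": max(abs(y).max(), 1e-6),
                   "uncage_fraction": uncage}
        res = fit_curve(self._model, t, y, self.sigma, initial=initial,
                        fixed=fixed,
                        bounds={"k_forward": (1e-9, np.inf),
                                "K": (1e-9, np.inf),
                                "amplitude": (1e-12, np.inf),
                                "uncage_fraction": (1e-3, 1.0)})
        flagged = not res.success
        k = res["k_forward"]
        se = res.standard_errors.get("k_forward", np.nan)
        # a rate pinned at the bound or with >=100% relative uncertainty
        # means the trace carries no kinetic information (e.g. a constant
        # trace); flag it rather than report a silent pseudo-rate.
        # Missing error bars on an essentially perfect fit are benign.
        scale = float(np.mean(y ** 2)) or 1.0
        perfect = res.residual_norm <= 1e-16 * scale * len(y)
        if k <= 2e-9 or (np.isfinite(se) and se >= k) \
                or (not np.isfinite(se) and not perfect):
            flagged = True
        return RefoldingTraceResults(self, res, flagged)


class RefoldingTraceResults:
    def __init__(self, model: RefoldingTraceModel, fit, flagged: bool):
        self.model = model
        self._fit = fit
        self.flagged = flagged

    @property
    def k_forward(self) -> float:
        return self._fit["k_forward"]

    @property
    def k_forward_err(self) -> float:
        return self._fit.standard_errors.get("k_forward", float("nan"))

    @property
    def k_backward(self) -> float:
        return self.k_forward / self._fit["K"]

    @property
    def amplitude(self) -> float:
        return self._fit["amplitude"]

    @property
    def params(self) -> dict[str, float]:
        return dict(self._fit.parameters)

    def summary(self) -> str:
        tr = self.model.trace
        lines = [
            f"Two-state refolding fit: {tr.peak_label} ({tr.fold}), "
            f"{tr.temperature} C, {tr.condition}",
            f"  K (fixed): {self._fit['K']:.3f}" if self.model.fix_K
            else f"  K (fit):   {self._fit['K']:.3f}",
            f"  k_5'-3' = {self.k_forward * 1e3:.2f} +/- "
            f"{self.k_forward_err * 1e3:.2f} x 10^-3 /s",
            f"  k_3'-5' = {self.k_backward * 1e3:.2f} x 10^-3 /s",
            f"  flagged: {self.flagged}",
        ]
        return "\n".join(lines)


def fit_refolding_trace(trace: KineticTrace, K_at_T: float,
                        **options) -> RefoldingTraceResults:
    """Fit one refolding trace with K fixed; see :class:`RefoldingTraceModel`."""
    return RefoldingTraceModel(trace, K_at_T, **options).fit()


class ArrheniusModel:
    """Arrhenius model ln k = -deltaH_act/(R T) + ln A over a rate table."""

    def __init__(self, temperatures_K, rates, rate_errors=None):
        self.temperatures = np.asarray(temperatures_K, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if len(self.temperatures) < 3:
            raise ValueError("Arrhenius analysis requires >= 3 temperatures")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be > 0")
        self.rate_errors = None if rate_errors is None \
            else np.asarray(rate_errors, dtype=float)

    @classmethod
    def from_rate_table(cls, rates: RateTable, direction: str, condition: str):
        temps = rates.temperatures(condition, direction)
        if len(temps) < 3:
            raise ValueError("Arrhenius analysis requires >= 3 temperatures")
        entries = [rates.get(t, condition, direction) for t in temps]
        k = [e.rate for e in entries]
        err = [e.error for e in entries]
        use_err = err if all(e > 0 for e in err) else None
        return cls(celsius_to_kelvin(np.array(temps)), k, use_err)

    def fit(self) -> "ArrheniusResults":
        x = 1.0 / self.temperatures
        y = np.log(self.rates)
        sig = None if self.rate_errors is None else self.rate_errors / self.rates
        slope, intercept, cov = linear_fit(x, y, sig)
        jac = np.diag([-R, 1.0])
        thermo = ThermoFit(deltaH=-R * slope, deltaS=float("nan"),
                           covariance=jac @ cov @ jac.T,
                           intercept_meaning="arrhenius_lnA")
        return ArrheniusResults(self, thermo, intercept)


class ArrheniusResults:
    def __init__(self, model, thermo: ThermoFit, lnA: float):
        self.model = model
        self.thermo = thermo
        self.lnA = lnA

    @property
    def deltaH_act(self) -> float:
        """Activation enthalpy, J/mol."""
        return self.thermo.deltaH

    @property
    def deltaH_act_err(self) -> float:
        return self.thermo.deltaH_err

    @property
    def lnA_err(self) -> float:
        return float(np.sqrt(self.thermo.covariance[1, 1]))

    def predict_lnk(self, T):
        T = np.asarray(T, dtype=float)
        return -self.deltaH_act / (R * T) + self.lnA

    def summary(self) -> str:
        return (
            "Arrhenius analysis (ln k vs 1/T)\n"
            f"  deltaH_act = {self.deltaH_act / 1000:.1f} +/- "
            f"{self.deltaH_act_err / 1000:.1f} kJ/mol\n"
            f"  ln A       = {self.lnA:.2f} +/- {self.lnA_err:.2f}"
        )


def arrhenius_analysis(rates: RateTable, direction: str,
                       condition: str) -> ArrheniusResults:
    """Fit ln k vs 1/T for one direction and condition of a rate table."""
    return ArrheniusModel.from_rate_table(rates, direction, condition).fit()


def acceleration_factor(rates_free: RateTable, rates_complex: RateTable,
                        temperature: float, direction: str,
                        condition_free: str = "rna_alone",
                        condition_complex: str = "complex"):
    """Chaperone acceleration: k(complex)/k(free) at one temperature.

    When both entries carry per-peak rates with matching labels, the
    per-peak ratios are averaged (unweighted mean +/- SD); otherwise the
    ratio of the aggregate rates with first-order error propagation.
    Returns ``(factor, error)``.
    """
    ef = rates_free.get(temperature, condition_free, direction)
    ec = rates_complex.get(temperature, condition_complex, direction)
    shared = sorted(set(ef.per_peak) & set(ec.per_peak))
    if len(shared) >= 2:
        ratios = np.array([ec.per_peak[p] / ef.per_peak[p] for p in shared])
        return float(ratios.mean()), float(ratios.std(ddof=1))
    ratio = ec.rate / ef.rate
    err = ratio * math.sqrt((ef.error / ef.rate) ** 2 + (ec.error / ec.rate) ** 2)
    return float(ratio), float(err)
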