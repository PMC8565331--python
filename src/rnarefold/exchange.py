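"""Exchange stage: per-base-pair stability from imino solvent exchange.

An imino proton exchanges with water only while its base pair is open.
Water inversion-recovery experiments at increasing mixing delay tau_m
measure the exchange rate k_ex per imino; in the EX2 limit
k_ex = K_diss * k_intr, so exchange rates at several temperatures give
the opening thermodynamics (deltaH_diss, deltaS_diss, deltaG_diss) of
every base pair via a van't Hoff fit of ln K_diss against 1/T.
Comparing free and chaperone-complexed RNA yields the destabilization
map deltadeltaG_diss = deltaG_diss(free) - deltaG_diss(complex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R, T_REF, celsius_to_kelvin
from .models import (ExchangeParams, ThermoFit, fit_curve,
                     inversion_recovery_signal, linear_fit)

__all__ = [
    "InversionRecoverySeries",
    "IntrinsicExchangeModel",
    "ExchangeRecoveryModel",
    "ExchangeRecoveryResults",
    "fit_exchange_series",
    "BasePairStability",
    "basepair_thermodynamics",
    "DestabilizationProfile",
    "destabilization_profile",
]


@dataclass
class InversionRecoverySeries:
    """Imino peak integrals vs inversion-recovery delay for one base pair."""

    tau_m: np.ndarray       # s, strictly increasing, >= 0
    integrals: np.ndarray
    base_pair: str          # e.g. "C4-G9"
    temperature: float      # degrees C
    condition: str = "rna_alone"

    def __post_init__(self):
        self.tau_m = np.asarray(self.tau_m, dtype=float)
        self.integrals = np.asarray(self.integrals, dtype=float)
        if self.tau_m[0] < 0 or np.any(np.diff(self.tau_m) <= 0):
            raise ValueError("tau_m must be strictly increasing and >= 0")
        if self.tau_m.shape != self.integrals.shape:
            raise ValueError("tau_m and integrals must have equal length")


@dataclass
class IntrinsicExchangeModel:
    """Arrhenius model of the intrinsic open-state exchange rate k_intr.

    k_intr(T) = k_ref * exp(-Ea/R * (1/T - 1/T_ref)), configured per
    imino nucleotide type. The defaults below are placeholders of a
    plausible magnitude for imino protons near neutral pH and must be
    replaced by calibrated values for absolute deltaG_diss scales;
    quantities that are ratios between conditions (deltadeltaG_diss) or
    round trips with a fixed model do not depend on them.
    """

    k_ref: float = 2.0e2     # 1/s at T_ref
    Ea: float = 16e3         # J/mol
    T_ref: float = T_REF

    def rate(self, T: float) -> float:
        if T <= 0:
            raise ValueError("T must be > 0")
        return self.k_ref * math.exp(-self.Ea / R * (1.0 / T - 1.0 / self.T_ref))

    def __call__(self, T: float) -> float:
        return self.rate(T)


class ExchangeRecoveryModel:
    """Magnetization-transfer model for one inversion-recovery series.

    S0, k_ex and the apparent imino R1 are free; R1_water and the water
    inversion efficiency are fixed (the experiment cannot determine them
    from one series; a dedicated water-recovery measurement or config
    supplies them).
    """

    def __init__(self, series: InversionRecoverySeries, *,
                 R1_water: float = 1.0, inversion_efficiency: float = 1.8,
                 sigma=None):
        if len(series.tau_m) < 6:
            raise ValueError("need >= 6 delay points")
        self.series = series
        self.R1_water = R1_water
        self.inversion_efficiency = inversion_efficiency
        self.sigma = sigma

    def _model(self, tau, k_ex, R1_imino, S0):
        p = ExchangeParams(k_ex=k_ex, R1_imino=R1_imino,
                           R1_water=self.R1_water,
                           inversion_efficiency=self.inversion_efficiency)
        return inversion_recovery_signal(tau, p, S0)

    def fit(self, initial: dict | None = None) -> "ExchangeRecoveryResults":
        s = self.series
        y = s.integrals
        S0_init = float(y[0]) if y[0] != 0 else float(np.abs(y).max() or 1.0)
        dip = (S0_init - y.min()) / abs(S0_init) if S0_init != 0 else 0.0
        init = {"k_ex": max(1.0, 2.0 * dip), "R1_imino": 2.0, "S0": S0_init}
        if initial:
            init.update(initial)
        res = fit_curve(self._model, s.tau_m, y, self.sigma, initial=init,
                        bounds={"k_ex": (0.0, 1e6),
                                "R1_imino": (1e-3, 1e4),
                                "S0": (1e-12, np.inf)})
        k_ex = res["k_ex"]
        se = res.standard_errors.get("k_ex", float("nan"))
        # depth of the fitted exchange dip relative to the equilibrium level
        curve = self._model(s.tau_m, k_ex, res["R1_imino"], res["S0"])
        dip = float(np.ptp(curve)) / max(abs(res["S0"]), 1e-300)
        scale = float(np.mean(y ** 2)) or 1.0
        perfect = res.residual_norm <= 1e-16 * scale * len(y)
        flagged, reason = False, ""
        if not res.success:
            flagged, reason = True, f"non-convergence: {res.message}"
        elif dip < 1e-3 or (np.isfinite(se) and k_ex - 1.96 * se <= 0) \
                or (not np.isfinite(se) and not perfect):
            flagged, reason = True, "k_ex indistinguishable from 0 (flat series?)"
        return ExchangeRecoveryResults(self, res, k_ex, se, flagged, reason)


class ExchangeRecoveryResults:
    def __init__(self, model, fit, k_ex, k_ex_err, flagged, flag_reason):
        self.model = model
        self._fit = fit
        self.k_ex = k_ex
        self.k_ex_err = k_ex_err
        self.flagged = flagged
        self.flag_reason = flag_reason

    @property
    def confidence_interval(self) -> tuple[float, float]:
        """95% CI of k_ex from the covariance."""
        half = 1.96 * self.k_ex_err
        return self.k_ex - half, self.k_ex + half

    @property
    def params(self) -> dict[str, float]:
        return dict(self._fit.parameters)

    def summary(self) -> str:
        s = self.model.series
        lo, hi = self.confidence_interval
        lines = [
            f"Imino exchange fit: {s.base_pair}, {s.temperature} C, {s.condition}",
            f"  k_ex = {self.k_ex:.3f} /s  (95% CI {lo:.3f} .. {hi:.3f})",
            f"  R1_imino = {self._fit['R1_imino']:.3f} /s (apparent)",
        ]
        if self.flagged:
            lines.append(f"  FLAGGED: {self.flag_reason}")
        return "\n".join(lines)


def fit_exchange_series(series: InversionRecoverySeries,
                        **options) -> ExchangeRecoveryResults:
    """Fit one inversion-recovery series; see :class:`ExchangeRecoveryModel`."""
    return ExchangeRecoveryModel(series, **options).fit()


@dataclass
class BasePairStability:
    """Opening thermodynamics of one base pair under one condition.

    The reporting identity deltaG_diss = deltaH_diss - T_ref*deltaS_diss
    holds by construction; deltaS_diss is stored in J/(mol K) and
    reported as the deltaS_diss*T column at 25 C in Table-style output.
    """

    base_pair: str
    deltaH_diss: float                      # J/mol
    deltaS_diss: float                      # J/(mol K)
    condition: str = "rna_alone"
    k_ex_by_T: dict[float, float] = field(default_factory=dict)   # T_C -> 1/s
    deltaH_err: float = float("nan")
    deltaS_err: float = float("nan")

    def deltaG_diss(self, T: float = T_REF) -> float:
        return self.deltaH_diss - T * self.deltaS_diss

    def deltaG_err(self, T: float = T_REF) -> float:
        # slope/intercept errors are correlated; without the cross term
        # this is an upper bound, matching the conservative Table layout
        return math.hypot(self.deltaH_err, T * self.deltaS_err)


def basepair_thermodynamics(k_ex_by_T: dict[float, float],
                            k_intr_model: IntrinsicExchangeModel,
                            condition: str = "rna_alone",
                            base_pair: str = "",
                            k_ex_err_by_T: dict[float, float] | None = None,
                            ) -> BasePairStability:
    """EX2 + van't Hoff: opening thermodynamics from k_ex at several T.

    ``k_ex_by_T`` maps temperature in degrees C to the fitted exchange
    rate. K_diss(T) = k_ex/k_intr(T) must stay below 1 (EX2 regime);
    a weighted linear fit of ln K_diss against 1/T gives deltaH_diss
    (-R*slope) and deltaS_diss (R*intercept).
    """
    if len(k_ex_by_T) < 3:
        raise ValueError("need >= 3 temperatures")
    temps_C = sorted(k_ex_by_T)
    T = celsius_to_kelvin(np.array(temps_C, dtype=float))
    k_ex = np.array([k_ex_by_T[t] for t in temps_C], dtype=float)
    k_intr = np.array([k_intr_model.rate(t) for t in T])
    if np.any(k_ex <= 0):
        raise ValueError("k_ex must be > 0")
    if np.any(k_ex >= k_intr):
        raise ValueError("EX2 assumption violated: k_ex >= k_intr")
    lnK = np.log(k_ex / k_intr)
    sig = None
    if k_ex_err_by_T is not None:
        sig = np.array([k_ex_err_by_T[t] for t in temps_C]) / k_ex
    slope, intercept, cov = linear_fit(1.0 / T, lnK, sig)
    # opening equilibrium: lnK_diss = -dH/(RT) + dS/R
    dH = -R * slope
    dS = R * intercept
    return BasePairStability(
        base_pair=base_pair, deltaH_diss=dH, deltaS_diss=dS,
        condition=condition, k_ex_by_T=dict(k_ex_by_T),
        deltaH_err=R * math.sqrt(cov[0, 0]),
        deltaS_err=R * math.sqrt(cov[1, 1]),
    )


@dataclass
class DestabilizationProfile:
    """Chaperone-induced destabilization per base pair and per fold.

    ``per_pair`` maps base-pair label -> {T_C: ddG in J/mol}; pairs
    measurable in only one condition are reported in ``missing`` with a
    reason, never as zero.
    """

    per_pair: dict[str, dict[float, float]]
    fold_of_pair: dict[str, str]
    missing: dict[str, str]

    def mean_by_fold(self, fold: str, temperature: float) -> float:
        vals = [prof[temperature] for label, prof in self.per_pair.items()
                if self.fold_of_pair.get(label) == fold
                and temperature in prof]
        if not vals:
            raise KeyError(f"no pairs for fold {fold!r} at {temperature} C")
        return float(np.mean(vals))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, prof in self.per_pair.items():
            for t, ddg in prof.items():
                rows.append({"base_pair": label,
                             "fold": self.fold_of_pair.get(label, ""),
                             "temperature_C": t,
                             "ddG_diss_kJmol": ddg / 1000.0})
        return pd.DataFrame(rows)


def destabilization_profile(free: list[BasePairStability],
                            complexed: list[BasePairStability],
                            temperatures_C,
                            fold_of_pair: dict[str, str] | None = None,
                            ) -> DestabilizationProfile:
    """ddG_diss(T) = deltaG_diss(free) - deltaG_diss(complex) per base pair.

    Only pairs present in both conditions enter the profile; pairs seen
    in one condition only (e.g. broadened beyond detection in the
    complex) are listed as missing with a reason code.
    """
    free_by = {s.base_pair: s for s in free}
    comp_by = {s.base_pair: s for s in complexed}
    shared = sorted(set(free_by) & set(comp_by))
    if not shared:
        raise ValueError("no overlapping base pairs between conditions")
    missing = {}
    for label in sorted(set(free_by) ^ set(comp_by)):
        which = "complex" if label in free_by else "free"
        missing[label] = f"not measured under {which} condition"
    per_pair: dict[str, dict[float, float]] = {}
    for label in shared:
        f, c = free_by[label], comp_by[label]
        per_pair[label] = {
            float(t): f.deltaG_diss(celsius_to_kelvin(t))
            - c.deltaG_diss(celsius_to_kelvin(t))
            for t in temperatures_C
        }
    return DestabilizationProfile(per_pair, dict(fold_of_pair or {}), missing)
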