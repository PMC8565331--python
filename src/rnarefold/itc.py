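"""ITC stage: one-site (Wiseman) binding-isotherm fits for chaperone binding.

Titration of the chaperone into the RNA-containing cell yields one heat
per injection. The heats are modelled by the closed-form one-site heat
content Q with the stoichiometry parameter n, corrected per injection
for the volume displaced from the active cell, and fitted by weighted
least squares for K_D (via the association constant), n and the binding
enthalpy. The thermodynamic signature deltaG = R T ln K_D,
-T deltaS = deltaG - deltaH decomposes the driving forces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R
from .models import WisemanParams, dilution_corrected_heat, fit_curve, wiseman_Q

__all__ = [
    "ITCExperiment",
    "BindingResult",
    "WisemanModel",
    "fit_binding_isotherm",
    "thermodynamic_signature",
]

#: joule per microcalorie
UCAL_TO_J = 4.184e-6


@dataclass
class ITCExperiment:
    """One titration: injection schedule, measured heats, concentrations.

    ``injections`` is a list of ``(volume_L, heat_J)``. A small first
    pre-injection (typically 0.2 ul) equilibrates the syringe tip; its
    heat is unreliable and is excluded from the fit when
    ``first_injection_small`` is set, but its volume still enters the
    dilution bookkeeping.
    """

    temperature: float                      # degrees C
    injections: list[tuple[float, float]]
    V0: float = 201.9e-6                    # L
    M0: float = 40e-6                       # M (cell RNA)
    Xs: float = 920e-6                      # M (syringe chaperone)
    first_injection_small: bool = False
    condition: str = ""

    def __post_init__(self):
        if self.V0 <= 0:
            raise ValueError("V0 must be > 0")
        if any(v <= 0 for v, _ in self.injections):
            raise ValueError("injection volumes must be > 0")

    @property
    def volumes(self) -> np.ndarray:
        return np.array([v for v, _ in self.injections])

    @property
    def heats(self) -> np.ndarray:
        return np.array([q for _, q in self.injections])

    @property
    def temperature_K(self) -> float:
        return self.temperature + 273.15

    @classmethod
    def from_csv(cls, path, temperature, V0=201.9e-6, M0=40e-6, Xs=920e-6,
                 first_injection_small=False, condition=""):
        """Read columns injection_index, volume_ul, heat_ucal."""
        df = pd.read_csv(path).sort_values("injection_index")
        inj = [(v * 1e-6, q * UCAL_TO_J)
               for v, q in zip(df["volume_ul"], df["heat_ucal"])]
        return cls(temperature, inj, V0, M0, Xs, first_injection_small, condition)


@dataclass
class BindingResult:
    """Fitted binding parameters and the derived thermodynamic signature."""

    K_D: float              # M
    n: float
    deltaH_bind: float      # J/mol
    deltaG: float           # J/mol
    minus_T_deltaS: float   # J/mol
    standard_errors: dict[str, float] = field(default_factory=dict)
    temperature_K: float = 298.15
    flagged: bool = False
    flag_reason: str = ""
    c_value: float = float("nan")

    def summary(self) -> str:
        lines = [
            f"One-site binding fit at {self.temperature_K - 273.15:.1f} C",
            f"  K_D      = {self.K_D * 1e6:8.2f} uM"
            + (f" +/- {self.standard_errors.get('K_D', float('nan')) * 1e6:.2f}"
               if self.standard_errors else ""),
            f"  n        = {self.n:8.2f}",
            f"  deltaH   = {self.deltaH_bind / 1000:+8.2f} kJ/mol",
            f"  deltaG   = {self.deltaG / 1000:+8.2f} kJ/mol",
            f"  -T*deltaS= {self.minus_T_deltaS / 1000:+8.2f} kJ/mol "
            f"({'entropy-opposed' if self.minus_T_deltaS > 0 else 'entropy-favored'})",
            f"  c value  = {self.c_value:.1f}",
        ]
        if self.flagged:
            lines.append(f"  FLAGGED: {self.flag_reason}")
        return "\n".join(lines)


def predicted_heats(p: WisemanParams, schedule) -> np.ndarray:
    """Model per-injection heats deltaQ(i) (J) for an injection schedule."""
    out = np.empty(len(schedule))
    q_prev = 0.0
    for i, dv in enumerate(schedule, start=1):
        q_i = wiseman_Q(i, p, schedule)
        out[i - 1] = dilution_corrected_heat(q_i, q_prev, dv, p.V0)
        q_prev = q_i
    return out


class WisemanModel:
    """One-site Wiseman isotherm model for an ITC experiment.

    ``fit()`` estimates K_assoc, n and deltaH by weighted least squares
    on the dilution-corrected per-injection heats. Results with a
    Wiseman c value (K_assoc * n * M0) outside [1, 1000], or with all
    heats indistinguishable from zero, are flagged low-confidence.
    """

    def __init__(self, experiment: ITCExperiment, sigma=None):
        self.experiment = experiment
        self.sigma = sigma
        n_usable = len(experiment.injections) - int(experiment.first_injection_small)
        if n_usable < 10:
            raise ValueError("need >= 10 usable injections")

    def _model(self, idx, K_assoc, n, deltaH):
        e = self.experiment
        p = WisemanParams(K_assoc=K_assoc, n=n, deltaH_bind=deltaH,
                          V0=e.V0, M0=e.M0, Xs=e.Xs)
        all_heats = predicted_heats(p, list(e.volumes))
        return all_heats[np.asarray(idx, dtype=int)]

    def fit(self, initial: dict | None = None) -> BindingResult:
        e = self.experiment
        heats = e.heats
        idx = np.arange(len(heats))
        if e.first_injection_small:
            idx = idx[1:]
        y = heats[idx]

        scale = float(np.abs(y).max())
        if scale <= 0 or not np.isfinite(scale):
            return self._flagged_result("all heats zero")
        init = {"K_assoc": 1.0 / 15e-6, "n": 2.0,
                "deltaH": -30e3 if y.sum() < 0 else 30e3}
        if initial:
            init.update(initial)
        res = fit_curve(self._model, idx, y, self.sigma, initial=init,
                        bounds={"K_assoc": (1.0, 1e12),
                                "n": (0.05, 50.0),
                                "deltaH": (-1e7, 1e7)})
        K_assoc = res["K_assoc"]
        n = res["n"]
        dH = res["deltaH"]
        T = e.temperature_K
        K_D = 1.0 / K_assoc
        dG = R * T * math.log(K_D)
        c = K_assoc * n * e.M0
        flagged, reason = False, ""
        if not res.success:
            flagged, reason = True, f"non-convergence: {res.message}"
        elif not (1.0 <= c <= 1000.0):
            flagged, reason = True, f"c value {c:.2g} outside [1, 1000]"
        errs = {}
        se_K = res.standard_errors.get("K_assoc")
        if se_K is not None and np.isfinite(se_K):
            errs["K_D"] = se_K / K_assoc ** 2        # |d(1/K)/dK| * se
            errs["deltaG"] = R * T * se_K / K_assoc  # d(ln K_D) propagation
        for name in ("n", "deltaH"):
            se = res.standard_errors.get(name)
            if se is not None and np.isfinite(se):
                errs[name] = se
        return BindingResult(
            K_D=K_D, n=n, deltaH_bind=dH, deltaG=dG,
            minus_T_deltaS=dG - dH, standard_errors=errs,
            temperature_K=T, flagged=flagged, flag_reason=reason, c_value=c,
        )

    def _flagged_result(self, reason: str) -> BindingResult:
        T = self.experiment.temperature_K
        return BindingResult(K_D=float("nan"), n=float("nan"),
                             deltaH_bind=float("nan"), deltaG=float("nan"),
                             minus_T_deltaS=float("nan"), temperature_K=T,
                             flagged=True, flag_reason=reason)


def fit_binding_isotherm(experiment: ITCExperiment,
                         initial: dict | None = None,
                         sigma=None) -> BindingResult:
    """Fit the one-site isotherm to an ITC experiment; see :class:`WisemanModel`."""
    return WisemanModel(experiment, sigma=sigma).fit(initial)


def thermodynamic_signature(result: BindingResult, T: float | None = None):
    """Decompose binding into (deltaG, deltaH, -T*deltaS) at temperature T.

    deltaG = R T ln K_D (negative for micromolar binding);
    -T deltaS = deltaG - deltaH. Returns a dict that also classifies the
    sign of the entropic term.
    """
    if not (result.K_D > 0 and np.isfinite(result.K_D)):
        raise ValueError("K_D must be > 0")
    T = result.temperature_K if T is None else T
    dG = R * T * math.log(result.K_D)
    mTdS = dG - result.deltaH_bind
    return {
        "deltaG": dG,
        "deltaH": result.deltaH_bind,
        "minus_T_deltaS": mTdS,
        "entropy_term_sign": "positive" if mTdS > 0 else
                             ("negative" if mTdS < 0 else "zero"),
    }
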