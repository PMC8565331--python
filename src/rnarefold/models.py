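"""Closed-form model equations and generic fitting contracts.

This module holds every analytic model used by the analysis stages:

* the integrated rate law of a reversible unimolecular two-state
  reaction (photolysis-triggered refolding between the 5'- and 3'-fold),
* van't Hoff and Arrhenius linearizations and the Eyring barrier,
* the one-site Wiseman heat-content isotherm for ITC with the
  per-injection dilution correction,
* the two-compartment magnetization-transfer curve for water
  inversion-recovery imino exchange, and the EX2 relation turning
  exchange rates into base-pair dissociation free energies,

plus a generic weighted least-squares ``fit_curve`` contract (lmfit
underneath) and a closed-form weighted ``linear_fit``.

All energies are J/mol, temperatures K, rates 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import lmfit

from .constants import R, K_B, H_PLANCK

__all__ = [
    "TwoStateParams",
    "ThermoFit",
    "WisemanParams",
    "ExchangeParams",
    "FitResult",
    "two_state_signal",
    "backward_rate",
    "vant_hoff_lnK",
    "gibbs_free_energy",
    "arrhenius_lnk",
    "eyring_deltaG",
    "wiseman_Q",
    "wiseman_heat_content",
    "itc_concentrations",
    "dilution_corrected_heat",
    "inversion_recovery_signal",
    "ex2_deltaG_diss",
    "fit_curve",
    "linear_fit",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class TwoStateParams:
    """Parameters of the reversible two-state refolding rate law.

    ``k_forward`` is the 5'->3' rate constant (1/s); ``K`` the equilibrium
    constant [3']/[5']; ``uncage_fraction`` the fraction of molecules
    photochemically released into the reaction (incomplete uncaging).
    """

    k_forward: float
    K: float
    amplitude: float = 1.0
    uncage_fraction: float = 0.88

    def __post_init__(self):
        if not (self.k_forward >= 0 and np.isfinite(self.k_forward)):
            raise ValueError("k_forward must be finite and >= 0")
        if not (self.K > 0 and np.isfinite(self.K)):
            raise ValueError("K must be finite and > 0")
        if not (0 < self.uncage_fraction <= 1):
            raise ValueError("uncage_fraction must be in (0, 1]")

    @property
    def k_backward(self) -> float:
        return backward_rate(self.k_forward, self.K)

    @property
    def k_obs(self) -> float:
        """Observed relaxation rate k_forward * (1 + 1/K)."""
        return self.k_forward * (1.0 + 1.0 / self.K)


@dataclass
class ThermoFit:
    """(deltaH, deltaS) from a linear fit in 1/T.

    ``intercept_meaning`` records whether the intercept was deltaS/R
    (van't Hoff) or ln A (Arrhenius); the slope is -deltaH/R either way.
    """

    deltaH: float
    deltaS: float
    covariance: np.ndarray
    intercept_meaning: str = "vant_hoff_deltaS_over_R"

    def __post_init__(self):
        c = np.asarray(self.covariance, dtype=float)
        if c.shape != (2, 2):
            raise ValueError("covariance must be 2x2")
        if not np.allclose(c, c.T, atol=1e-10 * max(1.0, np.abs(c).max())):
            raise ValueError("covariance must be symmetric")
        self.covariance = c

    @property
    def deltaH_err(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def deltaS_err(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    def deltaG(self, T: float) -> float:
        """deltaH - T*deltaS, J/mol."""
        return self.deltaH - T * self.deltaS


@dataclass
class WisemanParams:
    """One-site Wiseman isotherm parameters.

    ``K_assoc`` is the association constant (1/M, so K_assoc = 1/K_D);
    ``n`` the stoichiometry; ``deltaH_bind`` the molar binding enthalpy
    (J/mol, any sign); ``V0`` the active cell volume (L); ``M0`` the
    initial macromolecule (RNA) cell concentration (M); ``Xs`` the
    syringe ligand concentration (M).
    """

    K_assoc: float
    n: float
    deltaH_bind: float
    V0: float
    M0: float
    Xs: float

    def __post_init__(self):
        for name in ("K_assoc", "n", "V0", "M0", "Xs"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def K_D(self) -> float:
        return 1.0 / self.K_assoc


@dataclass
class ExchangeParams:
    """Magnetization-transfer parameters of the imino exchange curve."""

    k_ex: float
    R1_imino: float
    R1_water: float
    inversion_efficiency: float = 1.8

    def __post_init__(self):
        if self.k_ex < 0:
            raise ValueError("k_ex must be >= 0")
        if self.R1_imino <= 0 or self.R1_water <= 0:
            raise ValueError("relaxation rates must be > 0")
        if not (0 < self.inversion_efficiency <= 2):
            raise ValueError("inversion_efficiency must be in (0, 2]")


@dataclass
class FitResult:
    """Outcome of a weighted least-squares fit.

    ``standard_errors`` contains only the free parameters; fixed ones are
    listed in ``fixed_mask``. ``success`` is False on non-convergence —
    failures are flagged, never silent.
    """

    parameters: dict[str, float]
    standard_errors: dict[str, float]
    fixed_mask: frozenset[str]
    residual_norm: float
    n_points: int
    success: bool = True
    message: str = ""
    covariance: np.ndarray | None = None
    param_order: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> float:
        return self.parameters[name]


# ---------------------------------------------------------------------------
# two-state refolding
# ---------------------------------------------------------------------------

def two_state_signal(t, p: TwoStateParams, reporter: str = "fold3",
                     printed_form: bool = False):
    """Normalized reporter signal of the reversible two-state refolding.

    After photolysis the system starts as pure 5'-fold and relaxes to the
    equilibrium [3']/[5'] = K with observed rate k_obs = k_forward*(1+1/K).
    The 3'-fold reporter rises from 0 to uncage_fraction*amplitude*K/(K+1);
    the 5'-fold reporter decays from amplitude to the complementary level.

    ``printed_form`` evaluates the variant with an extra factor K on the
    exponential term. That form has S(0) < 0 whenever K > 1, which is
    inconsistent with the pure-5'-fold initial condition, so it is kept
    for documentation only and never used in fits.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    for v in (p.k_forward, p.K, p.amplitude, p.uncage_fraction):
        if not np.isfinite(v):
            raise ValueError("non-finite parameter")
    k_obs = p.k_forward * (1.0 + 1.0 / p.K)
    frac3 = p.K / (p.K + 1.0)
    decay = np.exp(-k_obs * t)
    pref = p.K if printed_form else 1.0
    if reporter == "fold3":
        return p.uncage_fraction * p.amplitude * frac3 * (1.0 - pref * decay)
    if reporter == "fold5":
        # population remaining in the 5'-fold; the caged (non-uncaged)
        # fraction stays 5'-folded and keeps contributing.
        relax = 1.0 / (p.K + 1.0) + frac3 * pref * decay
        return p.amplitude * ((1.0 - p.uncage_fraction) + p.uncage_fraction * relax)
    raise ValueError(f"unknown reporter {reporter!r}")


def backward_rate(k_forward: float, K: float) -> float:
    """3'->5' rate from detailed balance: k_backward = k_forward / K."""
    if not K > 0:
        raise ValueError("K must be > 0")
    return k_forward / K


# ---------------------------------------------------------------------------
# equilibrium / activation thermodynamics
# ---------------------------------------------------------------------------

def vant_hoff_lnK(T, deltaH: float, deltaS: float):
    """ln K(T) = -deltaH/(R T) + deltaS/R."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("T must be > 0")
    return -deltaH / (R * T) + deltaS / R


def gibbs_free_energy(K, T):
    """deltaG = -R T ln K (J/mol); K = [3']/[5'], negative favors 3'."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("K must be > 0")
    if np.any(np.asarray(T) <= 0):
        raise ValueError("T must be > 0")
    return -R * np.asarray(T, dtype=float) * np.log(K)


def arrhenius_lnk(T, deltaH_act: float, lnA: float):
    """ln k(T) = -deltaH_act/(R T) + ln A."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("T must be > 0")
    return -deltaH_act / (R * T) + lnA


def eyring_deltaG(k, T):
    """Activation free energy from transition-state theory.

    deltaG_act = R T ln(k_B T / (h k)), with unit transmission coefficient.
    """
    k = np.asarray(k, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(k <= 0):
        raise ValueError("k must be > 0")
    if np.any(T <= 0):
        raise ValueError("T must be > 0")
    return R * T * np.log(K_B * T / (H_PLANCK * k))


# ---------------------------------------------------------------------------
# ITC: Wiseman isotherm with cell-displacement dilution
# ---------------------------------------------------------------------------

def itc_concentrations(cumulative_volume: float, V0: float, M0: float, Xs: float):
    """Cell concentrations after injecting a cumulative volume v.

    Standard perfusion-cell convention: injected liquid displaces an equal
    volume of the (partially mixed) cell content, giving

        M_t = M0 * (1 - v/2V0) / (1 + v/2V0)
        X_t = Xs * (v/V0)    / (1 + v/2V0)

    Returns (M_t, X_t) in M.
    """
    r = cumulative_volume / V0
    M_t = M0 * (1.0 - r / 2.0) / (1.0 + r / 2.0)
    X_t = Xs * r / (1.0 + r / 2.0)
    return M_t, X_t


def wiseman_heat_content(M_t: float, X_t: float, p: WisemanParams) -> float:
    """Total heat content Q of the cell at concentrations (M_t, X_t), J."""
    if X_t <= 0 or M_t <= 0:
        return 0.0
    a = 1.0 + X_t / (p.n * M_t) + 1.0 / (p.n * p.K_assoc * M_t)
    disc = a * a - 4.0 * X_t / (p.n * M_t)
    if disc < -1e-12 * a * a:
        raise ValueError("Wiseman discriminant negative: model violation")
    disc = max(disc, 0.0)
    return p.n * M_t * p.deltaH_bind * p.V0 / 2.0 * (a - math.sqrt(disc))


def wiseman_Q(i: int, p: WisemanParams, schedule: Sequence[float]) -> float:
    """Heat content Q(i) after injection i (J).

    ``schedule`` is the list of injection volumes in L; ``i`` = 0 means
    before any injection (Q = 0). Concentrations come from
    :func:`itc_concentrations` at the cumulative injected volume.
    """
    if i < 0:
        raise ValueError("i must be >= 0")
    if any(v <= 0 for v in schedule):
        raise ValueError("injection volumes must be > 0")
    if i == 0:
        return 0.0
    v = float(np.sum(schedule[:i]))
    M_t, X_t = itc_concentrations(v, p.V0, p.M0, p.Xs)
    return wiseman_heat_content(M_t, X_t, p)


def dilution_corrected_heat(Q_i: float, Q_prev: float, dV_i: float, V0: float) -> float:
    """Measured heat of one injection, corrected for cell displacement.

    deltaQ(i) = Q(i) - Q(i-1) + (dV_i/V0) * (Q(i) + Q(i-1)) / 2

    The displaced-volume term uses the average of the heat content before
    and after the injection.
    """
    if not V0 > 0:
        raise ValueError("V0 must be > 0")
    return Q_i - Q_prev + (dV_i / V0) * (Q_i + Q_prev) / 2.0


# ---------------------------------------------------------------------------
# imino exchange
# ---------------------------------------------------------------------------

def inversion_recovery_signal(tau, p: ExchangeParams, S0: float = 1.0):
    """Imino peak integral after water inversion, vs mixing delay tau.

    Two-compartment magnetization transfer: inverted water magnetization
    flows into the imino proton through solvent exchange (rate k_ex) while
    both pools relax longitudinally, giving

        S(tau) = S0 * [1 - eff * k_ex/(R1_imino + k_ex - R1_water)
                         * (exp(-R1_water tau) - exp(-(R1_imino+k_ex) tau))]

    At the degenerate point R1_imino + k_ex = R1_water the difference of
    exponentials collapses to tau*exp(-R1_water*tau) analytically.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    lam = p.R1_imino + p.k_ex
    denom = lam - p.R1_water
    if abs(denom) < 1e-9 * max(lam, p.R1_water):
        transfer = p.k_ex * tau * np.exp(-p.R1_water * tau)
    else:
        transfer = (p.k_ex / denom) * (np.exp(-p.R1_water * tau) - np.exp(-lam * tau))
    return S0 * (1.0 - p.inversion_efficiency * transfer)


def ex2_deltaG_diss(k_ex: float, k_intr: float, T: float) -> float:
    """Base-pair dissociation free energy in the EX2 exchange limit.

    In EX2 the observed exchange rate is k_ex = K_diss * k_intr, so
    deltaG_diss = -R T ln(k_ex / k_intr) > 0 for k_ex < k_intr.
    """
    if not (0 < k_ex < k_intr):
        raise ValueError("EX2 regime requires 0 < k_ex < k_intr")
    if not T > 0:
        raise ValueError("T must be > 0")
    return -R * T * math.log(k_ex / k_intr)


# ---------------------------------------------------------------------------
# generic fitting
# ---------------------------------------------------------------------------

def fit_curve(model: Callable, x, y, sigma=None, *,
              initial: Mapping[str, float],
              fixed: frozenset | set | Sequence[str] = (),
              bounds: Mapping[str, tuple[float, float]] | None = None) -> FitResult:
    """Weighted nonlinear least squares of ``y = model(x, **params)``.

    ``model`` takes the abscissa as first argument and every parameter as
    a keyword. Parameters named in ``fixed`` are held at their initial
    value and excluded from the standard errors. Deterministic given
    identical inputs and initials. Non-convergence is flagged on the
    result, never silent.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fixed = frozenset(fixed)
    bounds = bounds or {}
    free = [name for name in initial if name not in fixed]
    if not free:
        raise ValueError("at least one free parameter required")
    if len(y) < len(free):
        raise ValueError("fewer points than free parameters")

    params = lmfit.Parameters()
    for name, value in initial.items():
        lo, hi = bounds.get(name, (-np.inf, np.inf))
        params.add(name, value=value, vary=name not in fixed, min=lo, max=hi)

    weights = None if sigma is None else 1.0 / np.asarray(sigma, dtype=float)

    def residual(pars):
        vals = {name: pars[name].value for name in initial}
        r = model(x, **vals) - y
        return r if weights is None else r * weights

    out = lmfit.minimize(residual, params, method="leastsq")
    pars = {name: float(out.params[name].value) for name in initial}
    errs = {}
    for name in free:
        se = out.params[name].stderr
        errs[name] = float(se) if se is not None else float("nan")
    # error bars can be legitimately unavailable on a zero-residual fit;
    # convergence alone decides success, callers inspect the NaN stderr
    success = bool(out.success)
    return FitResult(
        parameters=pars,
        standard_errors=errs,
        fixed_mask=fixed,
        residual_norm=float(np.sum(np.asarray(out.residual) ** 2)),
        n_points=int(len(y)),
        success=success,
        message=str(out.message),
        covariance=getattr(out, "covar", None),
        param_order=tuple(out.var_names),
    )


def linear_fit(x, y, sigma_y=None):
    """Closed-form weighted linear least squares y = slope*x + intercept.

    Returns (slope, intercept, covariance). Used for van't Hoff
    (x = 1/T, y = ln K) and Arrhenius (y = ln k) analyses. Requires at
    least 3 points so the error estimate has a residual degree of freedom
    when weights are not supplied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("linear_fit requires >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: all x equal")
    if sigma_y is None:
        w = np.ones_like(x)
    else:
        w = 1.0 / np.asarray(sigma_y, dtype=float) ** 2
    S = w.sum()
    Sx = (w * x).sum()
    Sy = (w * y).sum()
    Sxx = (w * x * x).sum()
    Sxy = (w * x * y).sum()
    delta = S * Sxx - Sx * Sx
    slope = (S * Sxy - Sx * Sy) / delta
    intercept = (Sxx * Sy - Sx * Sxy) / delta
    cov = np.array([[S, -Sx], [-Sx, Sxx]]) / delta
    if sigma_y is None:
        # scale by residual variance when no weights are given
        resid = y - slope * x - intercept
        dof = len(x) - 2
        cov = cov * (resid @ resid) / dof if dof > 0 else cov * np.nan
    return float(slope), float(intercept), cov
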