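"""Diagnostic figures for the fitted models (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt
    _, ax = plt.subplots()
    return ax


def plot_vant_hoff(results, ax=None):
    """ln K against 1/T with the fitted line."""
    ax = _axes(ax)
    m = results.model
    x = 1.0 / m.temperatures
    ax.plot(x, np.log(m.K_values), "o", label="data")
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, results.predict_lnK(1.0 / grid), "-", label="fit")
    ax.set_xlabel("1/T (1/K)")
    ax.set_ylabel("ln K")
    ax.legend()
    return ax


def plot_refolding_fit(results, ax=None):
    """Kinetic trace with the fitted two-state relaxation curve."""
    ax = _axes(ax)
    tr = results.model.trace
    ax.plot(tr.time, tr.signal, ".", ms=3, label=f"{tr.peak_label} ({tr.fold})")
    pars = results.params
    from .models import TwoStateParams, two_state_signal
    p = TwoStateParams(k_forward=pars["k_forward"], K=pars["K"],
                       amplitude=pars["amplitude"],
                       uncage_fraction=pars["uncage_fraction"])
    ax.plot(tr.time, two_state_signal(tr.time, p, reporter=tr.fold), "-",
            label="fit")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized signal")
    ax.legend()
    return ax


def plot_binding_isotherm(experiment, result=None, ax=None):
    """Per-injection heats against molar ratio, with the model curve."""
    ax = _axes(ax)
    v = np.cumsum(experiment.volumes)
    ratio = (experiment.Xs * (v / experiment.V0)
             / (1 + v / (2 * experiment.V0))) / \
        (experiment.M0 * (1 - v / (2 * experiment.V0))
         / (1 + v / (2 * experiment.V0)))
    ax.plot(ratio, experiment.heats / 4.184e-6, "o", label="data")
    if result is not None and not result.flagged:
        from .itc import predicted_heats
        from .models import WisemanParams
        p = WisemanParams(K_assoc=1 / result.K_D, n=result.n,
                          deltaH_bind=result.deltaH_bind, V0=experiment.V0,
                          M0=experiment.M0, Xs=experiment.Xs)
        ax.plot(ratio, predicted_heats(p, list(experiment.volumes)) / 4.184e-6,
                "-", label="fit")
    ax.set_xlabel("molar ratio [chaperone]/[RNA]")
    ax.set_ylabel("heat per injection (ucal)")
    ax.legend()
    return ax
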