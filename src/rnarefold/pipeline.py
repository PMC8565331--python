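"""Pipeline orchestration: run all stages from one config, write reports.

The pipeline runs the stages in dependency order — equilibrium first
(kinetics needs K(T)), then kinetics; ITC and exchange are independent —
and assembles the refolding energy diagram (equilibrium deltaG, Eyring
barriers in both directions, binding deltaG per conformer) at the
reference temperature. Outputs are diffable CSV/JSON files plus a
provenance block (package version, seed, config hash).

Raw inputs are CSV files written either by an instrument export or by
the synthetic generators (``rnarefold generate``); the dialects are the
ones documented on each stage's reader.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import R, T_REF, celsius_to_kelvin
from .equilibrium import (EquilibriumSeries, Spectrum1D, VantHoffModel,
                          equilibrium_constant, integrate_peak)
from .exchange import (InversionRecoverySeries, IntrinsicExchangeModel,
                       basepair_thermodynamics, destabilization_profile,
                       fit_exchange_series)
from .itc import ITCExperiment, fit_binding_isotherm, thermodynamic_signature
from .kinetics import (KineticTrace, RateTable, acceleration_factor,
                       arrhenius_analysis, fit_refolding_trace)
from .models import eyring_deltaG, gibbs_free_energy
from .structures import (max_compatible_hybrid, mutually_exclusive_pairs,
                         parse_dotbracket)
from .synthetic import (GeneratorConfig, default_windows, generate_study)

__all__ = ["RunConfig", "run_pipeline", "assemble_energy_diagram",
           "EnergyDiagram", "write_study_csv", "load_study_csv"]

#: joule per microcalorie (mirrors itc.UCAL_TO_J)
_UCAL = 4.184e-6


@dataclasses.dataclass
class RunConfig:
    """Run-level configuration; loadable from YAML or JSON."""

    outdir: str = "results"
    seed: int = 0
    datadir: str | None = None          # raw-input CSVs; None -> generate
    stages: tuple = ("structures", "equilibrium", "kinetics", "itc", "exchange",
                     "report")
    T_ref: float = T_REF
    # structure block: two dot-bracket strings for the competing folds
    length: int = 20
    dotbracket_5prime: str = "((((....))))........"
    dotbracket_3prime: str = "....((((((....))))))"
    # exchange stage
    k_intr: IntrinsicExchangeModel = dataclasses.field(
        default_factory=IntrinsicExchangeModel)
    generator: GeneratorConfig | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw and f.name not in ("k_intr", "generator"):
                kwargs[f.name] = raw[f.name]
        cfg = cls(**kwargs)
        if "k_intr" in raw:
            cfg.k_intr = IntrinsicExchangeModel(**raw["k_intr"])
        gen_kwargs = dict(raw.get("generator", {}))
        gen_kwargs.setdefault("seed", cfg.seed)
        cfg.generator = GeneratorConfig(**gen_kwargs)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps({f.name: repr(getattr(self, f.name))
                           for f in dataclasses.fields(self)}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# CSV round trips for the synthetic study
# ---------------------------------------------------------------------------

def write_study_csv(data: dict, manifest: dict, outdir) -> None:
    """Write generated raw data in the stage CSV dialects."""
    out = Path(outdir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    for s in data["spectra"]:
        name = f"spectrum_{s.condition}_{s.temperature:g}C.csv"
        pd.DataFrame({"ppm": s.ppm, "intensity": s.intensity}).to_csv(
            out / "spectra" / name, index=False)
    rows = []
    for i, tr in enumerate(data["traces"]):
        rows.append(pd.DataFrame({
            "time_s": tr.time, "signal": tr.signal, "peak_label": tr.peak_label,
            "fold": tr.fold, "temperature_C": tr.temperature,
            "condition": tr.condition, "trace_id": i}))
    pd.concat(rows).to_csv(out / "traces.csv", index=False)
    for j, exp in enumerate(data["itc"]):
        pd.DataFrame({
            "injection_index": np.arange(len(exp.injections)),
            "volume_ul": exp.volumes * 1e6,
            "heat_ucal": exp.heats / _UCAL,
        }).to_csv(out / f"itc_{j}.csv", index=False)
    rows = []
    for s in data["exchange"]:
        rows.append(pd.DataFrame({
            "tau_s": s.tau_m, "integral": s.integrals, "base_pair": s.base_pair,
            "temperature_C": s.temperature, "condition": s.condition}))
    pd.concat(rows).to_csv(out / "exchange.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_study_csv(datadir) -> dict:
    """Read raw data back in the same dialects (inverse of write_study_csv)."""
    d = Path(datadir)
    spectra = []
    for f in sorted((d / "spectra").glob("spectrum_*.csv")):
        stem = f.stem.split("_")          # spectrum_<condition...>_<T>C
        condition = "_".join(stem[1:-1])
        temperature = float(stem[-1].rstrip("C"))
        spectra.append(Spectrum1D.from_csv(f, temperature, condition))
    traces = []
    df = pd.read_csv(d / "traces.csv")
    for _, grp in df.groupby("trace_id"):
        traces.append(KineticTrace(
            grp["time_s"].to_numpy(), grp["signal"].to_numpy(),
            grp["peak_label"].iloc[0], grp["fold"].iloc[0],
            float(grp["temperature_C"].iloc[0]), grp["condition"].iloc[0]))
    itc = [ITCExperiment.from_csv(f, temperature=25.0,
                                  first_injection_small=True)
           for f in sorted(d.glob("itc_*.csv"))]
    exchange = []
    df = pd.read_csv(d / "exchange.csv")
    for (bp, T, cond), grp in df.groupby(["base_pair", "temperature_C",
                                          "condition"]):
        grp = grp.sort_values("tau_s")
        exchange.append(InversionRecoverySeries(
            grp["tau_s"].to_numpy(), grp["integral"].to_numpy(),
            bp, float(T), cond))
    return {"spectra": spectra, "traces": traces, "itc": itc,
            "exchange": exchange}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_structures(cfg: RunConfig) -> dict:
    a = parse_dotbracket(cfg.dotbracket_5prime, "5prime")
    b = parse_dotbracket(cfg.dotbracket_3prime, "3prime")
    conflicts = mutually_exclusive_pairs(a, b)
    hybrid, count = max_compatible_hybrid(a, b)
    return {
        "5prime_pairs": [[p.i, p.j] for p in a.sorted_pairs()],
        "3prime_pairs": [[p.i, p.j] for p in b.sorted_pairs()],
        "mutually_exclusive": sorted([[pa.i, pa.j], [pb.i, pb.j]]
                                     for pa, pb in conflicts),
        "hybrid_pairs": [[p.i, p.j] for p in sorted(hybrid)],
        "hybrid_count": count,
    }


def _stage_equilibrium(data: dict, cfg: RunConfig) -> dict:
    windows = default_windows(cfg.generator or GeneratorConfig(seed=cfg.seed))
    w3 = next(w for w in windows if w.fold == "fold3")
    w5 = next(w for w in windows if w.fold == "fold5")
    out = {}
    for condition in sorted({s.condition for s in data["spectra"]}):
        specs = sorted((s for s in data["spectra"] if s.condition == condition),
                       key=lambda s: s.temperature)
        temps, Ks, errs = [], [], []
        for s in specs:
            a3 = integrate_peak(s, w3, all_windows=windows)
            a5 = integrate_peak(s, w5, all_windows=windows)
            K, err = equilibrium_constant(a3, a5)
            temps.append(celsius_to_kelvin(s.temperature))
            Ks.append(K)
            errs.append(err)
        series = EquilibriumSeries(np.array(temps), np.array(Ks),
                                   np.array(errs), condition)
        res = VantHoffModel.from_series(series).fit()
        out[condition] = {"series": series, "fit": res}
    return out


def _stage_kinetics(data: dict, equilibrium: dict, cfg: RunConfig) -> dict:
    rate_tables: dict[str, RateTable] = {}
    for condition in sorted({t.condition for t in data["traces"]}):
        table = RateTable()
        temps = sorted({t.temperature for t in data["traces"]
                        if t.condition == condition})
        for T_C in temps:
            # K is fixed from the free-RNA equilibrium at every condition,
            # matching how the traces are analysed
            eq = equilibrium.get("rna_alone")
            K = float(np.exp(eq["fit"].predict_lnK(celsius_to_kelvin(T_C)))) \
                if eq else 1.0
            per_peak = {}
            for tr in data["traces"]:
                if tr.condition != condition or tr.temperature != T_C:
                    continue
                res = fit_refolding_trace(tr, K)
                if not res.flagged:
                    per_peak[f"{tr.peak_label}:{tr.fold}"] = res.k_forward
            if not per_peak:
                continue
            rates = np.array(list(per_peak.values()))
            err = rates.std(ddof=1) if len(rates) > 1 else 0.0
            table.add_forward_with_K(T_C, condition, float(rates.mean()),
                                     float(err), K, per_peak)
        rate_tables[condition] = table
    arrhenius = {}
    for condition, table in rate_tables.items():
        for direction in ("5to3", "3to5"):
            if len(table.temperatures(condition, direction)) >= 3:
                arrhenius[(condition, direction)] = arrhenius_analysis(
                    table, direction, condition)
    accel = {}
    if "rna_alone" in rate_tables and "complex" in rate_tables:
        shared = set(rate_tables["rna_alone"].temperatures("rna_alone", "5to3")) \
            & set(rate_tables["complex"].temperatures("complex", "5to3"))
        for T_C in sorted(shared):
            accel[T_C] = acceleration_factor(
                rate_tables["rna_alone"], rate_tables["complex"], T_C, "5to3")
    return {"rates": rate_tables, "arrhenius": arrhenius, "acceleration": accel}


def _stage_itc(data: dict) -> list:
    return [fit_binding_isotherm(exp) for exp in data["itc"]]


def _stage_exchange(data: dict, cfg: RunConfig) -> dict:
    k_ex: dict[tuple[str, str], dict[float, float]] = {}
    k_err: dict[tuple[str, str], dict[float, float]] = {}
    for s in data["exchange"]:
        res = fit_exchange_series(s)
        if res.flagged:
            continue
        k_ex.setdefault((s.base_pair, s.condition), {})[s.temperature] = res.k_ex
        k_err.setdefault((s.base_pair, s.condition), {})[s.temperature] = \
            res.k_ex_err
    stabilities: dict[str, list] = {"rna_alone": [], "complex": []}
    for (bp, condition), by_T in k_ex.items():
        if len(by_T) < 3:
            continue
        stab = basepair_thermodynamics(by_T, cfg.k_intr, condition, bp,
                                       k_err[(bp, condition)])
        stabilities.setdefault(condition, []).append(stab)
    profile = None
    if stabilities["rna_alone"] and stabilities["complex"]:
        temps = sorted({s.temperature for s in data["exchange"]})
        profile = destabilization_profile(stabilities["rna_alone"],
                                          stabilities["complex"], temps)
    return {"stabilities": stabilities, "profile": profile}


@dataclasses.dataclass
class EnergyDiagram:
    """Free-energy levels of the refolding process at one temperature.

    The consistency residual deltaG - (barrier_forward - barrier_backward)
    is zero to propagation error because the equilibrium constant and the
    rate ratio measure the same quantity.
    """

    T: float
    deltaG_equilibrium: float            # J/mol, -RT ln K
    deltaG_barrier_forward: float        # J/mol, Eyring on k_5'-3'
    deltaG_barrier_backward: float       # J/mol, Eyring on k_3'-5'
    deltaG_bind: dict = dataclasses.field(default_factory=dict)  # per conformer
    condition: str = "rna_alone"

    @property
    def consistency_residual(self) -> float:
        return self.deltaG_equilibrium - (self.deltaG_barrier_forward
                                          - self.deltaG_barrier_backward)

    def as_dict(self) -> dict:
        return {
            "T_K": self.T, "condition": self.condition,
            "deltaG_equilibrium_kJmol": self.deltaG_equilibrium / 1e3,
            "deltaG_barrier_forward_kJmol": self.deltaG_barrier_forward / 1e3,
            "deltaG_barrier_backward_kJmol": self.deltaG_barrier_backward / 1e3,
            "deltaG_bind_kJmol": {k: v / 1e3 for k, v in self.deltaG_bind.items()},
            "consistency_residual_kJmol": self.consistency_residual / 1e3,
        }


def assemble_energy_diagram(k_forward: float, k_backward: float, T: float,
                            binding: dict | None = None,
                            condition: str = "rna_alone") -> EnergyDiagram:
    """Energy diagram from forward/backward rates and optional binding dG.

    deltaG = -RT ln(k_forward/k_backward); the barriers come from the
    Eyring equation per direction. ``binding`` maps a conformer label to
    its ITC binding free energy (J/mol).
    """
    K = k_forward / k_backward
    return EnergyDiagram(
        T=T,
        deltaG_equilibrium=float(gibbs_free_energy(K, T)),
        deltaG_barrier_forward=float(eyring_deltaG(k_forward, T)),
        deltaG_barrier_backward=float(eyring_deltaG(k_backward, T)),
        deltaG_bind=dict(binding or {}),
        condition=condition,
    )


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _write_reports(outdir: Path, results: dict, cfg: RunConfig) -> None:
    if "structures" in results:
        (outdir / "structures.json").write_text(
            json.dumps(results["structures"], indent=1))
    if "equilibrium" in results:
        rows, fits = [], {}
        for condition, block in results["equilibrium"].items():
            s, fit = block["series"], block["fit"]
            for T, K, err in zip(s.temperatures, s.K_values, s.K_errors):
                rows.append({"T_C": T - 273.15, "condition": condition,
                             "K": K, "K_err": err,
                             "dG_kJmol": float(gibbs_free_energy(K, T)) / 1e3})
            fits[condition] = {
                "deltaH_kJmol": fit.deltaH / 1e3,
                "deltaH_err_kJmol": fit.bse["deltaH"] / 1e3,
                "deltaS_JmolK": fit.deltaS,
                "deltaS_err_JmolK": fit.bse["deltaS"],
                "dG_gradient_JmolK": fit.dG_gradient,
                "deltaG_Tref_kJmol": float(fit.deltaG(cfg.T_ref)) / 1e3,
            }
        pd.DataFrame(rows).to_csv(outdir / "equilibrium.csv", index=False)
        (outdir / "vant_hoff.json").write_text(json.dumps(fits, indent=1))
    if "kinetics" in results:
        kin = results["kinetics"]
        frames = [t.to_frame() for t in kin["rates"].values()]
        if frames:
            pd.concat(frames).to_csv(outdir / "rates.csv", index=False)
        arr = {f"{cond}:{direction}": {
                   "deltaH_act_kJmol": fit.deltaH_act / 1e3,
                   "deltaH_act_err_kJmol": fit.deltaH_act_err / 1e3,
                   "lnA": fit.lnA}
               for (cond, direction), fit in kin["arrhenius"].items()}
        (outdir / "arrhenius.json").write_text(json.dumps(arr, indent=1))
        pd.DataFrame([{"temperature_C": T, "direction": "5to3",
                       "factor": f, "factor_err": e}
                      for T, (f, e) in kin["acceleration"].items()]
                     ).to_csv(outdir / "acceleration.csv", index=False)
    if "itc" in results:
        pd.DataFrame([{
            "temperature_C": r.temperature_K - 273.15,
            "K_D_uM": r.K_D * 1e6, "n": r.n,
            "deltaH_kJmol": r.deltaH_bind / 1e3,
            "deltaG_kJmol": r.deltaG / 1e3,
            "minus_TdS_kJmol": r.minus_T_deltaS / 1e3,
            "flagged": r.flagged} for r in results["itc"]]
        ).to_csv(outdir / "binding.csv", index=False)
        (outdir / "signature.json").write_text(json.dumps(
            [{k: (v if not isinstance(v, float) else v / 1e3)
              for k, v in thermodynamic_signature(r).items()}
             for r in results["itc"] if not r.flagged], indent=1))
    if "exchange" in results:
        exch = results["exchange"]
        rows = []
        for condition, stabs in exch["stabilities"].items():
            for s in stabs:
                rows.append({
                    "base_pair": s.base_pair, "condition": condition,
                    "dH_diss_kJmol": s.deltaH_diss / 1e3,
                    "dS_diss_T_kJmol": s.deltaS_diss * cfg.T_ref / 1e3,
                    "dG_diss_kJmol": s.deltaG_diss(cfg.T_ref) / 1e3})
        pd.DataFrame(rows).to_csv(outdir / "table1_style.csv", index=False)
        if exch["profile"] is not None:
            exch["profile"].to_frame().to_csv(outdir / "ddg.csv", index=False)
    if "energy_diagram" in results:
        (outdir / "energy_diagram.json").write_text(json.dumps(
            [d.as_dict() for d in results["energy_diagram"]], indent=1))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages in dependency order; return the result bundle.

    When ``cfg.datadir`` is None the raw inputs are generated by the
    synthetic module at the study conditions (seeded by ``cfg.seed``).
    All outputs are written under ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen_cfg = cfg.generator or GeneratorConfig(seed=cfg.seed)
    cfg.generator = gen_cfg
    if cfg.datadir is not None:
        data = load_study_csv(cfg.datadir)
    else:
        data, _ = generate_study(gen_cfg)

    results: dict = {}
    if "structures" in cfg.stages:
        results["structures"] = _stage_structures(cfg)
    if "equilibrium" in cfg.stages:
        results["equilibrium"] = _stage_equilibrium(data, cfg)
    if "kinetics" in cfg.stages:
        if "equilibrium" not in results:
            raise ValueError("kinetics stage requires the equilibrium stage")
        results["kinetics"] = _stage_kinetics(data, results["equilibrium"], cfg)
    if "itc" in cfg.stages:
        results["itc"] = _stage_itc(data)
    if "exchange" in cfg.stages:
        results["exchange"] = _stage_exchange(data, cfg)
    if "report" in cfg.stages and "kinetics" in results:
        diagrams = []
        for condition, table in results["kinetics"]["rates"].items():
            temps = table.temperatures(condition, "5to3")
            T_C = min(temps, key=lambda t: abs(t - (cfg.T_ref - 273.15)))
            fwd = table.get(T_C, condition, "5to3")
            bwd = table.get(T_C, condition, "3to5")
            binding = {}
            for r in results.get("itc", []):
                if not r.flagged:
                    binding["bistable_rna"] = r.deltaG
            diagrams.append(assemble_energy_diagram(
                fwd.rate, bwd.rate, celsius_to_kelvin(T_C), binding, condition))
        results["energy_diagram"] = diagrams

    _write_reports(outdir, results, cfg)
    provenance = {"package": "rnarefold", "version": __version__,
                  "seed": cfg.seed, "config_hash": cfg.config_hash(),
                  "stages": list(cfg.stages)}
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    results["provenance"] = provenance
    return results
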