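# rnarefold

Thermodynamics and kinetics of bistable-RNA refolding, and its
acceleration by an RNA chaperone, from NMR and ITC measurements.

A bistable RNA populates two mutually exclusive hairpin folds (a
5′-fold and a 3′-fold) separated by a high energy barrier. This package
implements the complete quantitative analysis of such a system:

- **Equilibrium** — integrate one imino reporter peak per fold in 1D
  spectra, form K(T) = I(3′)/I(5′), and fit
  ln K = −ΔH°/RT + ΔS°/R (van't Hoff) for the refolding enthalpy,
  entropy and the free-energy gradient dΔG/dT = −ΔS°.
- **Kinetics** — fit photolysis-triggered refolding traces to the
  integrated rate law of a reversible unimolecular two-state reaction,
  S₃′(t) = f·A·[K/(K+1)]·(1 − e^(−k_obs t)) with
  k_obs = k₅′→₃′·(1 + 1/K) and K fixed from the equilibrium stage; the
  backward rate follows from detailed balance, k₃′→₅′ = k₅′→₃′/K.
  Rates over temperature give ΔH‡ (Arrhenius) and ΔG‡ (Eyring), and
  paired free/chaperone rate tables give the acceleration factor.
- **ITC** — fit per-injection heats to the one-site Wiseman heat
  content Q = (nMₜΔH V₀/2)·[1 + Xₜ/nMₜ + 1/nKMₜ − √((1 + Xₜ/nMₜ +
  1/nKMₜ)² − 4Xₜ/nMₜ)] with per-injection cell-displacement dilution
  correction, yielding K_D, n, ΔH and the thermodynamic signature
  (ΔG, ΔH, −TΔS).
- **Exchange** — fit water inversion-recovery imino series for k_ex per
  base pair; in the EX2 limit ΔG_diss = −RT ln(k_ex/k_intr), so k_ex(T)
  gives per-base-pair opening thermodynamics and the chaperone
  destabilization map ΔΔG_diss = ΔG_diss(free) − ΔG_diss(complex).
- **Structures** — mutually exclusive base pairs of the two folds and
  the maximum compatible (pseudoknotted) hybrid pair set.
- **Synthetic data** — seeded generators for every raw input modality
  at the study conditions, used by the test-suite and the default
  pipeline run.

Each stage is a statsmodels-style model object whose `fit()` returns a
results object with estimates, standard errors and a `summary()` table:
`VantHoffModel`, `RefoldingTraceModel`, `ArrheniusModel`,
`WisemanModel`, `ExchangeRecoveryModel`.

## Worked example

```python
import numpy as np
from rnarefold import EquilibriumSeries, vant_hoff_analysis, vant_hoff_lnK
from rnarefold.synthetic import GeneratorConfig, gen_itc
from rnarefold.itc import fit_binding_isotherm

T = 273.15 + np.arange(10.0, 41.0, 5.0)
K = np.exp(vant_hoff_lnK(T, -30.1e3, -92.0))   # conformer ratio [3']/[5']
print(vant_hoff_analysis(EquilibriumSeries(T, K, np.zeros_like(K))).summary())

exp, truth = gen_itc(GeneratorConfig(seed=0, itc_noise=0.01))
print(fit_binding_isotherm(exp).summary())
```

prints

```
Van't Hoff analysis (ln K vs 1/T)
  condition:        rna_alone
  n temperatures:   7
  deltaH  =    -30.10 +/- 0.00 kJ/mol
  deltaS  =    -92.00 +/- 0.00 J/(mol K)
  deltaG(25C) =   -2.67 kJ/mol
  d(deltaG)/dT =   +92.0 J/(mol K)

One-site binding fit at 25.0 C
  K_D      =    12.54 uM +/- 0.51
  n        =     2.02
  deltaH   =   -39.92 kJ/mol
  deltaG   =   -27.98 kJ/mol
  -T*deltaS=   +11.95 kJ/mol (entropy-opposed)
  c value  = 6.5
```

The van't Hoff fit recovers the generating enthalpy and entropy of the
conformational equilibrium exactly on noiseless input (negative ΔG:
the 3′-fold is favored; the positive gradient means the equilibrium
shifts toward the 5′-fold on heating). The ITC fit recovers the
micromolar dissociation constant and stoichiometry n ≈ 2 from a 1%
noise thermogram; −TΔS > 0 marks enthalpy-driven, entropy-opposed
binding.

## Command line

```sh
rnarefold generate --out data --seed 1        # synthetic raw inputs
rnarefold all --data data --out results       # every stage + report
rnarefold itc --out results --seed 1          # single stage
```

Outputs are diffable CSV/JSON files (`equilibrium.csv`,
`vant_hoff.json`, `rates.csv`, `arrhenius.json`, `acceleration.csv`,
`binding.csv`, `table1_style.csv`, `ddg.csv`, `energy_diagram.json`)
plus a provenance block with seed and config hash.

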