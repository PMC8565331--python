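# Methods

This note documents the models implemented in `rnarefold`, their
assumptions, the numerical choices made where the design was open, and
what the synthetic generators do and do not emulate.

## System and conventions

The system is a 20-nucleotide bistable RNA that interconverts between
two mutually exclusive hairpins, the 5′-fold (four-base-pair helix,
GNRA-type tetraloop, long 3′ overhang) and the 3′-fold (six-base-pair
helix, YNMG-type tetraloop). All equilibrium constants are the
population ratio K = [3′]/[5′], so negative ΔG = −RT ln K favors the
3′-fold. Internally everything is SI (J/mol, K, s, L, M) with
R = 8.314 J/(mol K); reports use kJ/mol, °C, μM and 10⁻³ s⁻¹.
Temperatures enter in °C at the I/O boundary and are converted once.

## Two-state refolding rate law

After laser photolysis of the caged RNA the system starts as pure
5′-fold and relaxes toward equilibrium with observed rate
k_obs = k₅′→₃′(1 + 1/K). The rising 3′-reporter is

S₃′(t) = f·A·[K/(K+1)]·(1 − e^(−k_obs t)),

with f the uncaging fraction (default 0.88 — photolysis runs nearly but
not exactly to completion) and A a free amplitude. The decaying
5′-reporter keeps the non-uncaged fraction as a constant offset:
S₅′(t) = A·[(1−f) + f·(1/(K+1) + (K/(K+1))e^(−k_obs t))]. The two
reporters sum to A at all times (population conservation), and the
closed form matches numerical integration of dA/dt = −k_f A + k_b B to
better than 1e−8 relative.

A variant of the rate law with an extra factor K on the exponential
term is retained behind a `printed_form` flag for documentation; it
evaluates to a negative signal at t = 0 whenever K > 1, which
contradicts the pure-5′ initial condition, so it is never fitted.

Per-trace fits hold K fixed at the value measured for the unmodified
RNA at that temperature: a single relaxation trace determines only
k_obs and a plateau, so K and the rate cannot be separated from the
rising reporter. For the decaying reporter the offset does identify K,
and a sensitivity mode (`fix_K=False`) co-fits it as a diagnostic. The
uncaging fraction is absorbed into the amplitude for the rising
reporter (pure scale) and held at its known value for the decaying one
(where it also sets the offset). A constant or uninformative trace is
flagged (rate at bound, ≥100% relative standard error, or residuals
inconsistent with a perfect fit), never silently returned as a rate.

Per-peak rates at one temperature/condition are aggregated as an
unweighted mean ± SD; the backward rate table is populated by detailed
balance, k₃′→₅′ = k₅′→₃′/K, so that identity holds to machine
precision.

## Linearized thermodynamics

Van't Hoff (ln K vs 1/T) and Arrhenius (ln k vs 1/T) analyses use a
closed-form weighted linear least squares with σ(ln x) = σ(x)/x;
ΔH = −R·slope, and the intercept is ΔS/R or ln A respectively. At
least three temperatures are required so the unweighted variant has a
residual degree of freedom. The Eyring barrier
ΔG‡ = RT ln(k_B T / h k) (transmission coefficient 1) complements the
Arrhenius enthalpy; reports label which analysis produced a number.
The energy-diagram assembly checks the identity
ΔG = ΔG‡(5′→3′) − ΔG‡(3′→5′), which holds exactly when the rates come
from one rate table.

## Peak integration

K(T) comes from one isolated imino reporter peak per fold — by default
U17 for the 3′-fold and U11 for the 5′-fold, with the assignment kept
in configuration since reporter labeling conventions vary. Two
integrators are provided: `window_sum` (trapezoid over the window after
median-baseline subtraction; loses ~1% to Lorentzian tail truncation at
±80 half-widths) and the default `lorentzian_fit` (single Lorentzian
plus free offset inside the window), which is robust to the line
broadening observed upon chaperone binding and recovers a fully
contained peak to 1e−6. The area error is the baseline noise RMS
outside all windows times the window width, an SNR-style estimate. If
the Lorentzian fit fails it falls back to `window_sum` with a warning.

## ITC: one-site Wiseman isotherm

The heat content after injection i is the printed closed form with
stoichiometry n, association constant K = 1/K_D and molar enthalpy ΔH;
concentrations follow the standard perfusion-cell displacement
convention M_t = M₀(1 − v/2V₀)/(1 + v/2V₀),
X_t = X_s(v/V₀)/(1 + v/2V₀) for cumulative injected volume v. The
measured heat of injection i is
ΔQ(i) = Q(i) − Q(i−1) + (dV_i/V₀)(Q(i)+Q(i−1))/2 — the displaced-volume
term uses the average of the neighbouring heat contents (a published
variant with divisor 1 is treated as a typographical slip; the
generator mirrors the /2 convention so round trips are exact). The
model curve agrees with an independent per-injection mass-balance
root-finding oracle to < 1e−9 relative.

Default experiment geometry is the study design: 201.9 μl cell, 40 μM
RNA, 920 μM titrant, a 0.2 μl pre-injection followed by 19 × 2 μl. The
pre-injection's heat is excluded from the fit but its volume stays in
the dilution bookkeeping. Fits with Wiseman c = K·n·M₀ outside
[1, 1000] or an all-zero thermogram are flagged low-confidence. n is
reported purely as the stoichiometry parameter of the one-site form,
without a cooperativity interpretation. Heats are canonically stored in
J; the CSV dialect uses μcal as instruments export it.

## Imino exchange and base-pair stability

Water inversion-recovery transfers inverted water magnetization into an
imino proton through solvent exchange. The two-compartment form

S(τ) = S₀[1 − ε·(k_ex/(R1_imino + k_ex − R1_water))·(e^(−R1_water τ) −
e^(−(R1_imino+k_ex) τ))]

is fitted with S₀, k_ex and the apparent imino R1 free; the water R1
and the inversion efficiency ε (default 1.8 ≈ 2×0.9) are fixed from
configuration or a dedicated water-recovery measurement, since one
series cannot determine them. The degenerate point
R1_imino + k_ex = R1_water is handled by the analytic limit
τ·e^(−R1_water τ) and the curve is continuous across it.

In the EX2 limit k_ex = K_diss·k_intr, so ln K_diss vs 1/T gives
ΔH_diss and ΔS_diss and ΔG_diss(25 °C) = ΔH_diss − 298.15·ΔS_diss —
an identity that holds by construction in every report. The intrinsic
rate k_intr is not measurable here and is supplied as a per-imino-type
Arrhenius model whose defaults (200 s⁻¹ at 25 °C, Ea = 16 kJ/mol) are
placeholders of plausible magnitude: rescaling k_intr by c shifts
ΔS_diss by −R ln c and leaves ΔH_diss untouched, so destabilization
differences ΔΔG_diss between conditions and fixed-model round trips are
independent of it, while absolute ΔG_diss scales are only as good as
the supplied k_intr. Any k_ex ≥ k_intr is rejected as an EX2
violation. Base pairs broadened beyond detection under one condition
are reported as missing with a reason, never as ΔΔG = 0.

## Structures

Folds are configured as dot-bracket strings or explicit 1-based pair
lists. Mutually exclusive pairs are all cross-fold pairs sharing a
nucleotide. The maximum compatible hybrid — the largest pseudoknotted
union of pairs from both folds — is found by exact branch-and-bound
over the conflict graph (pair sets here are ≤ ~24 pairs), with ties
broken toward the lexicographically smallest sorted pair set for
determinism. Note the enumerated hybrid is a combinatorial construct;
a mechanistic transition-state model may retain fewer pairs.

## Synthetic data

The generators emulate, with additive i.i.d. Gaussian noise and seeded
RNGs (fixed seed ⇒ byte-identical output): Lorentzian two-peak spectra
whose area ratio follows the van't Hoff K(T) (ΔH° = −30.1 kJ/mol,
ΔS° = −92 J/(mol K) for the free RNA; −11.87 kJ/mol, −27 J/(mol K)
in the chaperone complex) with 2× line broadening under the complex;
refolding traces on the Arrhenius line through the measured 5 °C and
25 °C forward rates (11 and 240 ×10⁻³ s⁻¹), with 0.88 uncaging and a
2.17-fold complex acceleration; Wiseman thermograms at the study
injection design (K_D = 12.3 μM, n = 2, ΔH = −40 kJ/mol); and
inversion-recovery series built from a per-base-pair opening
thermodynamics table via EX2. The default temperature grid is 5–40 °C
in 5 °C steps.

Not emulated: spin-physics lineshapes beyond Lorentzians, correlated
or multiplicative noise, baseline drift and phase errors, instrument
power traces, chaperone-bound intermediate states, and peak overlap
beyond Lorentzian tails. Passing recovery tests therefore demonstrate
estimator correctness and calibration under the stated noise model, not
robustness to every artifact of real spectrometer or calorimeter data.

## Problem sizes

Stochastic recovery tests use 50 refolding replicates (100 points over
60 s at SNR 20), 100 ITC replicates (20 injections at 1% heat noise)
and 25 paired trace sets for the acceleration factor; deterministic
round trips use 7-temperature grids and 4096-point spectra. These sizes
give standard errors well below the effects being checked while keeping
the whole suite in seconds.

## Known limitations

- Absolute ΔG_diss values depend on the placeholder intrinsic exchange
  model; only differences between conditions are calibration-free.
- The equilibrium stage assumes the two reporter peaks are isolated;
  heavily overlapped peaks would need a joint multi-peak fit.
- The ITC stage fits one titration at a time; replicate averaging is
  done downstream, and titrant-into-buffer blanks are subtracted only
  when a reference experiment is supplied.
- Arrhenius and van't Hoff analyses assume temperature-independent
  ΔH over the studied range (linearity in 1/T).
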