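# Methods

## Model structure and assumptions

`senopbk` simulates oral dosing of senecionine N-oxide (SENO) or
senecionine (SEN) in rat with a flow-limited, perfusion-rate-limited PBK
model. Each compound has small-intestine (SI) and large-intestine (LI)
lumen pools and distributes over blood, liver, richly perfused, slowly
perfused and fat compartments; tissue uptake is flow-limited,
QT·(CB − CT/PT). The compartment set is configurable (any subset of
peripheral tissues can be supplied through the `flows` / `volumes` /
`partition` dictionaries), which is also how the reduced three-compartment
configuration used for solver cross-checks is built.

Processes:

* **Absorption.** The oral dose is split at t=0: F·dose into the dosed
  compound's SI pool, (1−F)·dose into a feces pool. F is therefore both
  the systemic bioavailability of the simulation and the multiplier of the
  adduct budget, keeping the two uses of F mutually consistent; this choice
  is isolated in `build_odes`. SI→liver uptake is first order (`ka_SENO`,
  `kb1`), SI→LI transit is first order (`kt`), and SEN formed or present in
  the LI is taken up to the liver (`kb2`).
* **N-oxide reduction.** Gut-microbial SENO→SEN reduction in the LI lumen
  and hepatic SENO→SEN reduction (cumulative flux ALM1) are
  Michaelis–Menten. SENO that is neither reduced nor in a pool is cleared
  from blood into urine, first order (`CLu_SENO`). Without some
  non-reductive SENO elimination every absorbed N-oxide molecule would
  eventually become SEN and the AUC-based REP would approach 1 at long
  times, which contradicts the observed in-vivo value (0.88); renal
  excretion of the more polar N-oxide is the physiologically natural
  pathway.
* **SEN clearance.** Total hepatic SEN clearance (oxidation, N-oxidation,
  hydrolysis, glucuronidation combined) is a single Michaelis–Menten flux
  (cumulative ALM2) driven by the venous-equilibrium liver concentration
  CVL_SEN = CL_SEN/PL_SEN. SEN has no extra-hepatic elimination, and all
  SEN enters the circulation through the liver — the two structural facts
  that make the AUC and adduct endpoints coincide in the linear,
  no-depletion regime (see invariants).
* **7-GS-DHP bookkeeping (±ALM4′).** Pyrrole formation plus glutathione
  conjugation is a sub-flux of ALM2, so subtracting and re-adding it in the
  liver balance leaves the mass balance untouched while allowing its
  quantification. Implemented literally: the ODE system integrates
  ∫CVL_SEN dt as a state, and ALM4(t) = kcat_invivo · residual · ∫CVL_SEN dt
  is a derived observable. SEN kinetics are therefore bit-for-bit
  independent of the 7-GS-DHP catalytic efficiency, which forces the
  normalized sensitivity coefficient of that kcat on the SEN AUC to be
  exactly zero and makes the AUC-based REP invariant to the depletion
  level.

## Parameters

Measured / anchored quantities (exact, unit-checked):

| parameter | value | units | meaning |
|---|---|---|---|
| `Lslope2c` | 0.0023 | mL min⁻¹ mg⁻¹ S9 | in-vitro first-order kcat of 7-GS-DHP formation from SEN |
| `S9_yield` | 143 | mg g⁻¹ liver | S9 protein yield |
| `liver_wt_frac` | 34 | g kg⁻¹ bw | rat liver weight |
| scaled kcat | 0.1677 | L h⁻¹ | product of the above × BW × 60/1000; always recomputed, never stored |
| F | 0.082 | – | oral bioavailability of SEN (literature value); 1.0 available for comparison |
| f | 0.20 | – | fraction of dose bioactivated to non-DNA-binding pyrroles |
| residual kcat | 1.0 / 0.63 / 10⁻⁴ | – | at 0.1 / 55 / 200 μmol kg⁻¹ bw, linear in dose between anchors, clamped outside |
| molar masses | 335.40 / 351.40 | g mol⁻¹ | SEN (C₁₈H₂₅NO₅) / SENO (C₁₈H₂₅NO₆), for mg kg⁻¹ and min·μg mL⁻¹ conversions |

Physiological and prior-pathway kinetic defaults are **placeholders from
standard rat PBK practice** (cardiac output 5.38 L h⁻¹ for a 0.25 kg rat
split 25/51/17/7% over liver/richly/slowly/fat; volumes 7.4/3.4/5/65/7% of
bw; first-order uptake and transit constants of order 0.3–1 h⁻¹). Two of
them are anchored to reported study conditions rather than guessed freely:

* hepatic SEN intrinsic clearance (`VmaxLM2c`/`KmLM2` = 68 μmol h⁻¹ kg⁻¹ /
  10 μM, CLint ≈ 1.7 L h⁻¹) reproduces the ≈1:1 split between 7-GS-DHP and
  protein adducts at 55 μmol kg⁻¹ bw, F = 0.082, f = 0.20, full kcat;
* the slowest transport steps (kb2 = 0.4 h⁻¹, microbial reduction
  first-order limit 0.5 h⁻¹) keep absorption and elimination ≳99.9%
  complete within the 24-h AUC window, so the adduct budget evaluated at
  24 h is self-consistent with the infinite-horizon identities it rests on.

No headline quantity (REP ratios, kcat scaling, dose conversions,
sensitivity zeros) depends on the placeholder values; the PBK-predicted REP
pair does, and is reported as a model prediction, not a measured constant.

## REP computation

Method 1: REP₁ = AUC_SEN(SENO arm)/AUC_SEN(SEN arm), AUCs carried as ODE
states over 0–24 h. Method 2: the bioactivation budget F·f·dose (SEN arm)
or F·f·REP₁·dose (SENO arm, REP₁ self-consistently from the same dose) is
split as protein = budget − ALM4(24 h); REP₂ is the protein-amount ratio.
DNA adducts are assumed not to shift the split. A budget smaller than the
simulated 7-GS-DHP amount raises an explicit inconsistency error naming
F, f and the kcat as candidate causes; in the fraction-bioactivated scan
such grid points are flagged `infeasible` and skipped rather than fatal.
The depletion multiplier applies to the SEN arm only (the
`depletion_both_arms` switch enables symmetric depletion for exploration).
Unit conversions (μmol·h L⁻¹ ↔ min·μg mL⁻¹, μmol kg⁻¹ ↔ mg kg⁻¹) happen
only at the reporting layer and cancel from every REP ratio.

## In-vitro kinetics

Rates are computed per replicate from blank-corrected metabolite
concentrations, v = max(0, C_full − C_blank)/(t·[S9]), negatives clipped
with a warning count. The kcat is the through-origin least-squares slope
(all replicate points, via statsmodels OLS without constant; equal to
Σ[S]v/Σ[S]²). Because replicate scatter in the assay is proportional to the
measured concentration (constant CV), the reported standard error is
model-based, SE = kcat·ĉv·√Σ[S]⁴/Σ[S]² with ĉv from relative residuals;
an HC1 sandwich SE backs the optional free-intercept comparison fit.
Saturating Michaelis–Menten fitting is out of scope (formation is linear
up to 50 μM; saturation would only appear at blood concentrations far
above any dose considered here).

## Synthetic data

The incubation generator emulates the assay design: 8 log-spaced substrate
levels over 0.5–50 μM, n = 3 replicates, 60-min incubations at
1 mg mL⁻¹ S9 in 0.1 mL, first-order product formation
C = kcat·[S]·t·[S9], Gaussian noise with CV 0.10 on measured
concentrations (truncated at 0), no-NADPH blanks at background level.
The CV is a generator default (real replicate scatter is not tabulated),
chosen as typical LC-MS/MS replicate precision. The generator does not
emulate calibration curves, peak integration, matrix effects, substrate
depletion over the incubation, or inter-batch S9 variability — so passing
recovery tests demonstrates correctness of the estimator under the stated
noise model, not robustness to those real-data features. An in-vivo
profile generator (model curve × mean-preserving lognormal noise) exists
for I/O and AUC round-trip testing only.

## Numerics

* Solver: LSODA (stiff-capable, adaptive) with rtol 1e-8, atol 1e-10 μmol,
  dense output, 1201 output points per 24 h. The contract is
  tolerance-based; BDF/Radau give the same trajectories to reporting
  precision.
* Mass balance (pools + ALM2 + urine + feces = dose) is checked at every
  output time; residual > 1e-6 relative raises an error. ALM1 is an
  internal transfer and ALM4 a sub-flux of ALM2; neither enters the
  balance.
* AUC queries use Simpson quadrature on the dense interpolant (32769
  points), which matches the ODE-integrated AUC state to ~1e-8 relative;
  state queries interpolate the dense solution and are exact on grid nodes.
* Negative solver excursions beyond 1e-7·dose raise an error; smaller ones
  are tolerated as solver noise.
* Cross-checks: a fixed-step classic Runge–Kutta reference on the reduced
  three-compartment configuration (step 1e-4 h in the acceptance suite,
  1e-3 h in the unit suite) agrees with the adaptive solution to <1e-4
  relative on the 24-h blood concentration; dose-linearity and a
  closed-form AUC identity hold in the linearized configuration (every
  (Vmax, Km) pair scaled ×10⁶ at fixed ratio).
* Sensitivity: forward difference at +5% (central difference behind a
  flag); perturbing `QC` rescales all flows proportionally so the flow
  balance QC = ΣQT holds identically by construction.

## Problem sizes

Default analyses use 24-h simulations (≈0.05–0.15 s each); the dose scan
uses 12 log-spaced doses over 0.1–200 μmol kg⁻¹ bw; the
fraction-bioactivated scan 12 points over 0.125–0.400; Monte-Carlo
parameter-recovery checks use 200 seeded datasets of 24 points. Long-
horizon identity checks integrate to 500–2000 h.

## Known limitations

* The exact parameter set and compartment topology of the original
  SENO/SEN model are not published in text form; defaults here are
  documented placeholders, so simulated absolute AUC/adduct magnitudes are
  indicative. The config-driven compartment set allows dropping in a
  complete parameter table without code changes.
* F, f and the residual-kcat anchors are adopted study conditions, not
  fitted here; no formal optimization against in-vivo data is performed.
* No human extrapolation, plasma protein binding, biliary recirculation,
  enterohepatic cycling, pyrrole-DNA adduct kinetics, or inter-individual
  variability.
* GSH depletion is represented phenomenologically (dose-dependent residual
  kcat), not by a mechanistic GSH turnover submodel.
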