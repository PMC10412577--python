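# Methods

## Scope and units

The package correlates equilibrium solubility of a crystalline solute in
supercritical CO₂ measured by a static sampling method. Units are fixed
throughout: temperature K, pressure bar, CO₂ density kg/m³ (numerically equal
to g/L), solubility and vial concentration g/L, mole fraction dimensionless,
enthalpy kJ/mol, R = 8.314 J/(mol·K). The equation-of-state module works in
SI internally (Pa, m³/mol) and converts bar by ×10⁵ at its boundary. CO₂
density is always an input column (tabulated from a reference equation of
state at measurement time), never recomputed; a user-supplied density
callback is accepted for synthetic grids.

## Data model and reduction

A solubility record is one (T, P, ρ, y₂, S) observation with optional
standard deviation of the mean and expanded uncertainty of y₂. The reduction
operations implement the static-sampling balance: a loop volume Vl = 600 µL of
saturated fluid is flushed into a collection vial holding Vs = 5 mL of
solvent, so S = C·Vs/Vl and y₂ = n₂/(n₂ + n_CO₂) with n₂ = C·Vs/M_w and
n_CO₂ = Vl·ρ/44.01. Relative combined standard uncertainty is the
root-sum-square of sensitivity-weighted component uncertainties and is
expanded with coverage factor k = 2.

The packaged 24-point nilotinib hydrochloride monohydrate (NHM) table stores
the published y₂ and S columns verbatim. The two columns are *not* mutually
consistent with the reduction equations — recomputing y₂ from S exceeds the
stored y₂ by a near-constant factor ≈ 1.5 on every row. Both columns are
preserved as printed and every regression targets the stored columns; the
reduction operations implement the equations as written. Resolving the
inconsistency would require the raw absorbance data, which do not exist in
any deposit.

## Density-based correlations

All ten registry models (Chrastil, Bian, Gordillo, Jafari-Nejad,
Garlapati–Madras, MST, Jouyban, Sparks, Bartle, Sodeifian) are log-linear in
their adjustable parameters: a design row X(T, P, ρ) and a fixed inverse
link map the linear predictor to the native output (concentration in g/L for
Chrastil and Sparks, T·ln(y₂P) for MST, mole fraction otherwise). Reference
constants not fixed by the formulas are declared on the model record and
configurable: Bartle's P_ref = 1 bar and ρ_ref = 700 kg/m³ (the literature
convention), Sparks' reduced density uses ρ_c(CO₂) = 467.6 kg/m³. Pressure
enters the formulas in bar and temperature in K exactly as tabulated.

Fitting is two-stage: ordinary least squares in the model's log/native-linear
space gives the first start; further starts perturb it (multiplicative
Gaussian, 10% scale); each start is polished by Nelder–Mead on the requested
objective (`aard`, `sse_log`, or `sse_linear`; AARD by default since it is
the headline comparison metric), and the winner is re-polished with restarted
simplices because Nelder–Mead collapses prematurely on the piecewise-linear
AARD surface. Defaults: 32 starts, seed 20230809, objective tolerance 1e-10.
Chrastil/Sparks AARD is measured against the S column, all other models
against y₂ (MST after inverting its native output); in the dilute regime the
relative errors in concentration and mole fraction coincide to first order,
so the comparison is space-invariant.

AARD% uses the degrees-of-freedom denominator 100/(N−Z)·Σ|Δ|/y. R_adj and
the F-value take Q = number of independent regressors = Z − 1 (the intercept
excluded); the observed-vs-predicted R² is the standard coefficient of
determination. A perfect fit reports F as infinite with an explicit flag.

On the packaged 24-point table the direct-AARD optima found by this pipeline
(and confirmed by independent differential-evolution searches over wide
boxes) are ≈12.1% for Chrastil, ≈8.19% for Bian and ≈11.53% for MST; these
are global minima of the stated objective on these data.

## Heuristic optimizers

The toolbox includes a seeded real-coded genetic algorithm (population 64,
tournament selection of size 3, blend crossover, Gaussian mutation with σ =
5% of the bound width, one elite, 200 generations) and a simulated annealer
(geometric cooling 0.95 applied every 50 of 10⁴ steps, Gaussian proposals
clipped to bounds). Both consume a numpy Generator seeded from the
configuration, return the best point visited, and are never worse than the
best initial population member. They exist for the non-log-linear
regressions (expanded-liquid theory) and as reference optimizers in tests.

## Peng–Robinson solid–fluid equilibrium

Pure-component parameters follow the standard PR forms
κ = 0.37464 + 1.54226ω − 0.26992ω², a(T) = 0.45724·R²Tc²α/Pc,
b = 0.07780·RTc/Pc. The vdW2 mixing rules are quadratic in both a and b with
a₁₂ = (1−k₁₂)√(a₁₁a₂₂) and b₁₂ = (1−l₁₂)(b₁₁+b₂₂)/2. The compressibility
cubic is solved with `numpy.roots`; among real roots above the covolume the
fluid root of minimal Gibbs energy is selected (verified in tests against an
explicit enumeration of total Gibbs energy per root).

The partial fugacity coefficient of the solute uses the composition
derivatives of both quadratic rules,

ln φ₂ = (b̄₂/b)(Z−1) − ln(Z−B) − A/(2√2B)·[2Σⱼyⱼa₂ⱼ/a − b̄₂/b]·ln[(Z+(1+√2)B)/(Z+(1−√2)B)],

with b̄₂ = 2(y₁b₁₂ + y₂b₂₂) − b. This is the only expression consistent with
the quadratic covolume rule; it reduces to the textbook form when b is
linear, and it is validated against a central-finite-difference derivative of
the residual Helmholtz energy (tolerance 1e-6). The variant that keeps the
textbook b₂₂/b term while mixing b quadratically was evaluated and rejected:
it is thermodynamically inconsistent and fits the data far worse.

Solubility solves the fixed point
y₂ = (P₂ˢφ₂ˢ)/(Pφ₂(y₂))·exp[(P−P₂ˢ)v₂/RT] with φ₂ˢ = 1, damping factor 0.5,
initial guess P₂ˢ/P·10³ clamped to (10⁻¹⁵, 0.05), relative tolerance 1e-10,
at most 500 iterations, y₂ clamped to (0, 0.1). Sublimation pressures come
from the solute record (tabulated per isotherm) with an Ambrose–Walton
corresponding-states fallback, and can be overridden per call.

(k₁₂, l₁₂) regression per isotherm minimizes OF = Σ|y₂ᵉˣᵖ−y₂ᶜᵃˡᶜ|/y₂ᵉˣᵖ on a
coarse grid over [−1, 1]² (step 0.05) followed by restarted Nelder–Mead
polish of the four best nodes. The multi-node polish matters: the objective
has a narrow curved funnel inside a wide plateau (where predictions collapse
to ~0 and every point contributes a relative error of 1), and the global
basin is not always under the single best node. Fit statistics use Z = Q = 2.

On the packaged data the fitted pairs are ≈(0.56, 0.57) at 308 K rising to
≈(0.64, 0.67) at 338 K, and the per-isotherm AARD (Z = 2) increases
monotonically with temperature, 5.2% → 8.8% → 13.5% → 38.9%. The
temperature trend reflects the fixed per-isotherm sublimation pressure: the
corresponding-states estimate is least reliable far above the measurement
floor, and the steep low-density end of the hottest isotherm is poorly
captured by two mixing-rule corrections.

## Ambrose–Walton sublimation pressure

ln(P/Pc) = f⁽⁰⁾ + ωf⁽¹⁾ + ω²f⁽²⁾ with the Wagner-form functions of
τ = 1 − T/Tc divided by T/Tc. Valid for 0 < T < Tc; at τ = 0 it returns Pc
exactly. With the packaged solute constants it reproduces the four tabulated
sublimation pressures to better than 1%.

## Expanded-liquid theory (modified Wilson)

The supercritical phase is treated as an expanded liquid, so equilibrium is
y₂γ₂(y₂) = exp[(ΔH_fus/R)(1/Tm − 1/T)]. γ₂ is the binary Wilson model with
Λ₁₂ = (v₂/v₁)exp(−λ′₁₂Tc/T) and Λ₂₁ = (v₁/v₂)exp(−λ′₂₁Tc/T); the
high-pressure modification replaces the constant solute liquid volume with
the linear law v₂ = αρ_r + β in the solvent's reduced density. This is the
standard two-parameter modified Wilson used for SC-CO₂ expanded-liquid
modeling, adopted here as the interpretation matching the four regressed
parameters (λ′₁₂, λ′₂₁, α, β); the exact closed form used in the original
study is not public. Tc defaults to the solvent's 304.18 K (configurable).
ΔH_fus for the packaged solute is not published; it defaults to Walden's
rule ΔH_fus = 56.5·Tm J/mol, exposed as an override — only the ideal
solubility prefactor depends on it and the regressed parameters absorb scale
error. v₁ = M_CO₂/ρ per record.

The scalar solver uses damped substitution (0.5, tolerance 1e-10). The
regression hot path uses a vectorized solver over all records with undamped
substitution for the first 60 iterations (γ₂ is nearly composition-
independent at these dilutions, so the undamped map contracts in a few
steps) and damped continuation afterwards; tests pin the two solvers
together and against bisection of the monotone residual.

The four-parameter fit is global-then-local: a seeded GA plus 512
Latin-hypercube probes of the bounded box (λ′ ∈ [−10, 40], α ∈ [−100, 100],
β ∈ [0.1, 400] cm³/mol); the 20 most promising starts are each refined by
three cycles alternating bounded trust-region least squares on log residuals
with Nelder–Mead on the AARD objective. The least-squares stage gives exact
convergence on noiseless data; the cycling walks the nearly flat ridge the
activity model exhibits (β and λ′₂₁ trade off almost perfectly over a
30 K temperature window). Zero-noise synthetic data are recovered to better
than 10⁻³ relative in all four parameters.

On the packaged NHM table this model form reaches AARD ≈ 24% (default
budget; independent differential evolution finds the same basin), i.e. it
correlates these data worse than the best density-based models. Since the
original study's exact activity expression and fusion enthalpy are not
recoverable, the ELT stage is validated by parameter-recovery and oracle
equivalence rather than by matching a published error figure.

## Derived thermodynamics

Enthalpies come from van't Hoff-type slopes: ΔH_total = −R·a₁ with a₁ the
Chrastil 1/T coefficient, ΔH_vap = −R·a₁ from Bartle, and
ΔH_sol = ΔH_total − ΔH_vap reported both signed and as a magnitude (the
conventional quotation is the negative, exothermic value). A positive Bartle
slope triggers an "exothermic-implausible" warning rather than an error.

The crossover zone is the minimal pressure interval containing all pairwise
intersection pressures of fitted y₂(P) isotherms, computed on a 1-bar grid
with sign-change bracketing and linear refinement; it is reported as an
interval because a point crossover is an idealization the fitted curves do
not share. The MST self-consistency diagnostic regresses T·ln(y₂P) − a₂T on
ρ and reports the line, its R², and per-isotherm mean residuals; collapse of
all isotherms onto one line (R² near 1; ≈0.98 for the packaged table)
indicates thermodynamically consistent data. A degenerate density range
flags the diagnostic unreliable instead of reporting a line.

## Synthetic data

Surface generation evaluates a ground-truth registry model on a T×P grid
(default: the 4×6 grid of the packaged study, 308–338 K × 120–270 bar, with
bilinear interpolation of the packaged density table) and applies
multiplicative lognormal noise with unit mean and a chosen coefficient of
variation (default 5%, matching the declared relative standard uncertainty
band of the measurements; the error model is multiplicative because
solubility spans orders of magnitude and all fit metrics are relative). The
S column is derived from the noisy y₂ through the dilute conversion, so the
two columns are consistent by construction — deliberately unlike the
packaged table. Random Chrastil ground truths sample a₀ ∈ [4, 7],
a₁ ∈ [−9000, −4000] K, with the intercept pinned so mid-grid mole fractions
land in 10⁻⁶·⁵–10⁻⁵·⁵, mirroring poorly soluble drugs.

Multi-drug feature tables attach sampled melting temperature (400–520 K),
Walden-rule fusion enthalpy, and a Clausius–Clapeyron sublimation-pressure
law to each drug's 24-record surface; 18 drugs give the 432-row benchmark
layout. What the generator does **not** emulate: real inter-drug structure
(features are independent draws, not correlated as in chemistry), isotherm
crossings driven by solute vapor pressure, or heteroscedastic instrument
error — so passing tests demonstrate correctness of the pipeline, not
predictive power on real mixtures.

## ML harness

Feature tables carry exactly six predictors (T, P, ρ, ΔH_fus, Tm, P_sub) and
the y₂ target. The split is row-wise by default, floor(0.75·n) training rows
(324/108 at n = 432), seeded and reproducible; a drug-wise grouped split is
available for leakage-aware evaluation since the original protocol does not
state which was used. Metrics (MAE, MSE, R²) are computed on the held-out
partition only, via scikit-learn. Model families are injected through the
fit/predict contract; the package does not pin particular regressor
implementations, and the CLI's `ml-bench` wires in scikit-learn's random
forest, decision tree, and two MLP depths as references. Published benchmark
scores for this protocol depend on seventeen external literature datasets
and are therefore out of reach of a self-contained package; the harness is
validated by metric identities and split arithmetic instead.

## Problem sizes and budgets

All regressions in the tests and the acceptance script run on the 24-point
packaged table or the 24-cell synthetic grid; the PR grid search is 41×41
nodes × 6 pressures; the ELT global stage uses 512 probes plus a
64-member GA. These sizes were chosen because they already reach the global
optima identified by much larger independent searches (wide-box differential
evolution with multiple seeds).

## Known limitations

* The printed y₂/S inconsistency of the packaged table is preserved, not
  repaired; conversions and fixture disagree by ≈1.5× by design.
* Published AARD figures for this system are internally inconsistent with
  the stated AARD definition (see the global-minimum values above); this
  package always reports the degrees-of-freedom form and documents the
  discrepancy rather than matching the printed numbers.
* Sublimation-pressure "modification" during EoS fitting (mentioned but not
  specified in the original study) is not reproduced; tabulated values are
  used verbatim with a per-call override.
* No uncertainty intervals on fitted parameters; no alternative EoSs or
  mixing rules; no group-contribution property estimators (critical
  constants are consumed as inputs).
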