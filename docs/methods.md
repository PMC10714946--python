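# Methods

## Model structure and assumptions

The disposition model is a linear whole-body PBPK circuit. A
subcutaneous depot empties by first-order absorption (dA_SC/dt = −k_a·A_SC,
initialised/incremented by F·Dose at each dose event — bolus into the
depot, not an infusion) directly into venous plasma. Venous blood passes
the lung in series at full cardiac output; arterial blood perfuses
eleven systemic tissues in parallel, with gut and spleen draining
portally through the liver. Tissue uptake is flow-limited against
tissue:plasma partition coefficients; because drug in red cells is
negligible for a large peptide, inter-compartment transport uses plasma
flows (blood flow × (1 − hematocrit)), and the reported concentration is
venous plasma. Plasma volume is split 2:1 venous:arterial.

Elimination is linear everywhere:

* **Peptidase.** A hypothetical peptidase expressed in every tissue at
  1 µmol/L with specific clearance 0.35 L/µmol/min. Its raw intrinsic
  clearance (≈21 h⁻¹ per litre of tissue) would overpredict total
  clearance by orders of magnitude under perfusion-limited assumptions;
  physically the limitation is membrane permeability of a 4.8 kDa
  peptide. Both effects are absorbed into one dimensionless calibration
  factor multiplying the intrinsic clearance in all tissues at once
  (package default 1.08e-3, frozen from the bundled calibration
  workflow, seed 20231128, 5000 draws).
* **Renal.** The reported renal constant (0.12 min⁻¹) has an ambiguous
  normalization, so the engine instead treats the operative renal plasma
  clearance CL_renal (L/h, acting on kidney emergent concentration) as
  the free quantity and, by default, solves it with Brent's method so
  that the renally eliminated fraction of a dose equals f_urine = 0.66 —
  an unambiguous, externally reported constraint. Eliminated fractions
  are computed exactly from the linear system (∫x dt = −A⁻¹x₀).

Because every process is first order, the state matrix A fully describes
the system. `simulate()` integrates with an implicit stiff solver
(LSODA or BDF, rtol 1e-8, atol 1e-10 ng, piecewise between dose events,
analytic Jacobian) and also offers an exact eigendecomposition route
(`method="analytic"`) used by the calibration search and population
sweeps, where thousands of simulations are needed. The two routes agree
to better than 1e-6 relative in the tests; mass balance
(F·dose = body + eliminated) is enforced at 1e-6 relative on every call.
Output is a uniform grid, default Δt = 0.5 h; Tmax is therefore reported
at grid resolution with ties broken to the earliest time.

## Distribution

Partition coefficients use a simplified tissue-composition equation
Kp = σ_ecw·f_ew + γ·f_iw + 10^logP·f_lip + β·f_prot(1−fu), with bundled
water/lipid/protein fractions per organ. γ = 1/(1+(MW/500)²) ≈ 0.011
damps intracellular access (membrane-impermeant peptide); the lipid term
is negligible at logP −6.8. σ_ecw = 0.45 — the fraction of interstitial
space accessible to the peptide — was fixed a priori so that the
reference adult V_ss ≈ 8 L, the apparent distribution volume implied by
the adult clinical PK (CL/F·T1/2/ln 2 ≈ 8.2 L at F = 0.81, consistent
with the label's ~10 L/F). This is the "middle-out" philosophy applied
to distribution: the observable kinetics are pinned by calibration, and
the spatial detail of Kp is deliberately not load-bearing (a flat-Kp
variant with the same V_ss reproduces the calibrated profile within 5 %
after recalibration; changing V_ss itself, e.g. Kp ≡ 1, is *not*
absorbable by clearance-only calibration).

## Calibration

`calibrate()` is a seeded random search: n log-uniform draws of
(k_a, peptidase factor) within bounds (defaults k_a ∈ [0.01, 1] h⁻¹,
factor ∈ [1e-5, 0.1]), CL_renal solved per draw from the urine-fraction
constraint (drawing it and rejecting to a ±0.01 band would discard
nearly all draws), objective = Σ [log(simulated/target)]² over
{AUC_0-inf, Cmax, T1/2} with equal weights, followed by an optional
Nelder–Mead polish in log space (default on, 200 iterations). Training
targets are the observed single-dose 5 mg adult parameters
(AUC 90500 ng·h/mL, Cmax 397 ng/mL, T1/2 123 h). With V_ss fixed at
≈8 L the three targets are nearly mutually consistent, and the
calibrated model lands within 1.05-fold of the observed AUC and within
3 % of the observed half-life. Identifiability note: under this
objective k_a is informed only by Cmax, whose sensitivity to k_a is weak
(~2 % per 20 % of k_a at these time scales), so k_a recovery is
guaranteed only against noise-free targets; the clearance constants are
sharply identified through AUC and the urine-fraction split.

## Physiology and virtual populations

Anthropometry medians by age/sex come from a bundled synthetic
growth-reference table (smooth CDC-style curves; explicitly labelled
synthetic, not a published dataset), with reference adults resembling
the Asian trial cohorts (male 72 kg/171 cm, female 58 kg/158 cm). Ages
up to and including 18 follow the pediatric curves; older individuals
use the reference adult. Organ masses scale allometrically with body
weight (exponent 1; brain 0.15), adipose absorbing the residual so organ
masses sum exactly to body weight at density 1 kg/L. Cardiac output
scales as weight^0.75; organ flows are fixed fractions of cardiac
output; GFR is 120 mL/min/1.73 m² × BSA (Du Bois) — adult-like
maturation, valid for ages ≥ 10, which is why younger ages are out of
scope. Individual variability is multiplicative truncated-normal
(weight CV 10 %, height CV 3.5 %, ±2.5 SD), one integer seed per
individual or population.

Obesity: target BMI is drawn uniformly in [1.05, 1.30] × the 95th
percentile of the bundled LMS curves; kidney and liver scale ×1.15
(reading "an increase of 115 %" as ×1.15), remaining lean organs ×1.05
except brain ×1.0 (brain mass is weight-invariant), adipose absorbs the
rest; flows rescale proportionally to new organ volumes (raising cardiac
output) and GFR with kidney volume. All factors are configurable; the
exact factors used in the source obesity population are not public, so
these are documented package defaults.

## Pediatric extrapolation and dose bands

`extrapolate()` keeps the drug record (and the calibrated k_a and
peptidase factor) bit-exact, swaps the physiology, and rescales renal
clearance by the GFR ratio (fu ratio = 1). The dose-band search
simulates each individual at each candidate dose
{5, 4.375, 3.75, 3.125, 2.5} mg (single dose, as in the reference
comparison) and qualifies a dose when the population **arithmetic mean**
AUC_0–168h *and* Cmax both lie inside the adult reference range
(43459–63467 ng·h/mL; 305.7–488.3 ng/mL). The mean-inside-range rule is
a documented choice (the alternative, fraction-of-individuals inside
range, is exposed through the per-dose diagnostics). If only the full
5 mg dose qualifies the recommendation is "no adjustment"; if none
qualifies the result carries diagnostics instead of a band. Age bands
are sampled uniformly: children [10,12), early adolescents [12,15),
adolescents [15,18). Band results at the margins (doses whose mean falls
within a few percent of a range edge) can flip with the population seed
at small n; the stable surface is the children-normal band, the
monotone non-decrease of bands with age, and no adjustment for obese
adolescents.

## Synthetic trials

`generate_trial()` draws per-subject multipliers (log-normal, median 1)
for k_a, total clearance (both elimination routes jointly, preserving
the urine fraction) and distribution volume (via Kp), simulates each
subject exactly, samples at a clinical-style grid (dense first week plus
weekly tails to 672 h) and applies mean-1 log-normal residual error
(default CV 15 %). Per-subject NCA of the noisy sparse profile yields a
clinical-style PK table. The generator emulates trial summary tables,
not real-data features such as BLQ censoring, dropout, covariate
effects or absorption-site variability — passing tests therefore show
pipeline correctness, not clinical validity. Note that the arithmetic
mean of per-subject AUC converges to AUC_median·exp(σ_CL²/2) (AUC
depends only on the clearance multiplier), and per-subject Cmax is the
maximum of noisy samples and hence upward-biased — both are properties
of real NCA tables too.

## Numerical choices and problem sizes

Tolerances: ODE rtol 1e-8/atol 1e-10 ng; mass balance 1e-6; urine
fraction solved to 1e-10. NCA: linear-up/log-down trapezoid, λz by
maximum adjusted r² over all suffix tails after Tmax (≥3 points,
evaluated in O(n) with suffix sums), extrapolated tail C_last/λz. The
test suite runs calibration at 1500 draws and dose-band populations of
20 per band (50 + 50 per sex is the full study configuration, available
via `recommend_doses`); the acceptance script uses the full 5000-draw
search. Degenerate inputs (zero-dose regimens, identically zero or
monotone-rising profiles, collapsed bounds, infeasible obesity targets)
raise typed errors or return exact trivial results, covered by tests.

## Known limitations

No target-mediated disposition, lymphatic two-pore uptake, nonlinear
elimination or immunogenicity; IV/oral routes out of scope. The
pediatric model is unverifiable against clinical data (none exist); the
obesity organ-scaling factors and the growth reference are documented
stand-ins. Fold-error direction follows the printed comparison tables
(predicted/observed) rather than the stated formula, with a flag to
invert.
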