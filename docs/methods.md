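# Methods

## Scope and model structure

`spcpbpk` implements a whole-body, perfusion-rate-limited PBPK model for
four Spatholobi Caulis constituents after oral dosing. The disposition
system has eleven circulatory compartments — lung, liver, kidney, heart,
muscle, spleen, brain, rest-of-body, gut tissue, arterial blood, venous
blood — each flow-limited: the blood leaving tissue *i* is in
equilibrium with the tissue at the partition ratio *k*ᵢ, so tissue
uptake and washout are governed entirely by Qᵢ, Vᵢ and kᵢ. The state
additionally carries three gut-lumen amounts (undissolved solid,
dissolved drug, gallbladder bile) and two cumulative elimination tallies
(metabolized, renally excreted) used for mass-balance accounting.

Structural conventions, all checked by tests:

* The lung is perfused at cardiac output from the venous pool; the
  artery is fed by lung outflow; the seven systemic tissue flows (liver
  incl. portal, kidney, heart, muscle, spleen, brain, rest) sum exactly
  to cardiac output. The venous return collects every tissue outflow
  Qᵢ·Cᵢ/kᵢ. The spleen returns directly to the vein (as the model is
  written), while the gut tissue drains into the liver via the portal
  flow; the hepatic arterial inflow is Q_L − Q_GI.
* The gut tissue compartment needed to close the portal inflow has no
  tabulated partition coefficient; it uses the rest-of-body value (the
  minimal closure consistent with the liver inflow term).
* The state holds blood concentrations; reported plasma concentration is
  C_V/R_bp.

## Compound parameters and units

All compound inputs are transcribed verbatim into
`data/table1_compounds.csv` (physicochemical, binding, metabolic) and
`data/table2_kp.csv` (13-tissue partition coefficients). Public units
follow the tables: µg/mL, L/h, mg/kg, mg/mL, cm/s. Two conventions are
worth calling out:

* **f_up is stored in percent** exactly as tabulated (e.g. `8.403`) and
  converted internally. The fraction unbound in blood, which the hepatic
  term needs but the source tables never define, is computed as
  f_b = (f_up/100)/R_bp, clipped to (0, 1] — the standard
  plasma-to-blood conversion.
* The internal unit system is µg / mL / h; flows and volumes are
  converted once when a model is compiled.

Base doses are 0.062, 0.11, 0.71 and 1.31 mg/kg for constituents 1–4,
corresponding to 30 g crude drug/kg; higher crude-drug doses scale these
proportionally.

## Clearance calibration

The tabulated total clearance (treated as plasma clearance; the tables
do not say) is converted to blood clearance CL/R_bp and split 70 %
renal / 30 % hepatic-intrinsic by default — the kidney is taken as the
dominant excretory organ, and the split is an explicit configuration
knob (`ModelConfig.renal_fraction`). For the CYP1A2/CYP2C9 substrates
the hepatic pathway is Michaelis–Menten with the tabulated K_M
(converted to mass units); the tabulated Vmax (nM/min/nM enzyme) cannot
be applied without an enzyme-abundance figure, so Vmax is scaled such
that the low-concentration limit f_b·Vmax/K_M equals the calibrated
intrinsic clearance, preserving the saturation concentration implied by
K_M. Daidzin, which has no tabulated enzyme parameters, gets a linear
hepatic pathway of the same intrinsic magnitude.

Elimination is **restricted (unbound-driven)**: the intrinsic hepatic
and renal clearances are calibrated at the baseline f_b and scale with
f_b when f_up or R_bp is perturbed. This choice is what makes AUC
strongly sensitive to f_up — the dominant sensitivity reported for all
four constituents — measurable at all; with a fully
total-clearance-based parameterization the f_up perturbation would
cancel out of the calibrated model.

## Oral absorption and enterohepatic recirculation

Dissolution follows Noyes–Whitney for a monodisperse powder:
rate = 3·D·(C_s − C_lumen)·M_solid/(ρ·r·h), with aqueous diffusion
coefficient D = 7×10⁻⁶ cm²/s, true density ρ = 1.2 g/mL,
diffusion-layer thickness h = min(r, 30 µm), and default particle radius
r = 25 µm (not tabulated; overridable per compound and per run). The
lumen fluid volume (6 mL rat, 250 mL human) bounds the dissolved
concentration at saturation. Absorption of dissolved drug is first
order with ka = 2·Papp/R_int (cylindrical surface-to-volume; R_int =
0.18 cm rat, 1.25 cm human), times an `absorption_scale` calibration
multiplier used to match an observed Tmax.

Enterohepatic recirculation diverts `biliary_fraction` (default 0.15) of
hepatic elimination into a bile pool; the gallbladder empties into the
lumen as a fast first-order release during a 0.5 h window starting at
3 h (8-*O*-methylretusin) or 6 h (the others) — the times of the
observed secondary plasma peaks. All EHC parameters are overridable.

Sweeping LogD perturbs a membrane-affinity factor that scales the
absorption rate constant linearly with the multiplier on the
distribution coefficient; the tabulated partition coefficients are
deliberately left untouched (re-deriving Kp from LogD is out of scope,
and the tabulated values are treated as ground truth).

## Physiology fixtures

Rat (0.25 kg, cardiac output 6.6 L/h) and human (70 kg, 390 L/h)
volumes and flows are standard fractional reference values of the Brown
et al. compilation style, normalized so the flow-sum invariant holds
exactly, and shipped as editable YAML (`data/rat.yaml`,
`data/human.yaml`) so users can substitute their own. A separate
13-tissue volume block serves the Vss composition
Vss = V_p + V_e·E/P + Σ V_t·Kp_t; the erythrocyte:plasma ratio defaults
to 1.0 and is a per-call override. The human model carries the rat
partition coefficients over (species-invariant passive partitioning, in
line with the passive-diffusion assumption of the source model); this is
the dominant extrapolation uncertainty. Human clearance comes from
single-species allometry with exponent 0.75 on total clearance (the
unbound-clearance variant is available by scaling with the f_up ratio).

## Non-compartmental analysis and qualification

AUC uses the linear trapezoid (matching the DAS-era tooling the
reference values were produced with); AUC₀→t defaults to the last
sampling time (12 h rat, 24 h human). λ_z comes from log-linear least
squares over the tail window after Tmax maximizing adjusted R²
(minimum three points); a non-decaying tail is flagged inestimable
rather than extrapolated. Ties in Cmax resolve to the earliest time.
Fold error is the symmetric ratio 10^|log₁₀(Calc/Obs)| and is rounded to
two decimals when compared against printed table cells; qualification
requires every FE < 2 and calculated-vs-observed R² ≥ 0.8, computed on
untransformed concentrations (scale-invariant correlation).

## Synthetic observed data

The reference concentration–time data exist only as mean ± SD (n = 5)
figures at 12 sampling times (0.083–12 h), so the generator emulates
exactly that structure: lognormal replicates with median equal to the
model value and log-SD √ln(1+cv²), default cv = 0.2 (a placeholder for
a typical inter-animal spread, not an estimate of the study's own
error), optional LLOQ flooring, summarized to mean/SD/n. Note the
analytic mean of this distribution is model·exp(σ²/2) (≈ +2 % at
cv = 0.2); the large-sample consistency test asserts against that exact
value. What the generator does *not* emulate: between-animal kinetic
heterogeneity (a single parameter set generates all replicates),
correlated residuals within an animal, and assay-specific error floors
— so passing recovery tests demonstrate estimator correctness under the
assumed error model, not robustness to real-data misspecification.

Parameter recovery fits the model to observed means by weighted least
squares (1/mean² weights) over a subset of {ka, CL_total,
biliary_fraction}, using Nelder–Mead in log/logit space started from the
nominal values, with the ODE solver relaxed to rtol 10⁻⁶ inside the
objective (the fit tolerance dominates).

## Numerical choices

* Stiff integration with LSODA, rtol 10⁻⁸, atol 10⁻¹² µg, integrated
  piecewise between discontinuities (dose boluses, emptying-window
  edges); dense output sampled on a 0.01 h grid for Tmax resolution.
  Halving the grid step changes Cmax by < 0.1 % (tested).
* Sub-tolerance negative solver noise is clipped to zero; anything
  beyond 10⁻⁹ of peak raises.
* Mass balance (dose = lumen + bile + Σ Cᵢ·Vᵢ + eliminated) is tracked
  with dedicated cumulative states; the residual is reported with every
  run and asserted ≤ 10⁻⁶ (elimination off) / 10⁻⁴ (accounted).
* Tmax calibration brackets the target on a coarse log-spaced
  absorption-scale scan and refines by log-bisection; because the
  emptying peak can become the global maximum, Tmax is not monotone in
  the scale and the calibrator returns the closest achievable Tmax when
  the target is unreachable.
* Problem sizes: simulations span 12 h (rat) / 24 h (human) at 0.01 h
  output resolution; recovery experiments use the 12-point study
  sampling design with n = 5 replicates.

## Known limitations and data inconsistencies

* **Two printed fold-error cells are wrong in the source table.** In the
  doubled-dose comparison, recomputing FE from the printed
  isolariciresinol pairs gives 1.18 (Cmax) and 1.07 (Tmax) against
  printed FE values of 1.16 and 1.20. The fixtures store the printed
  numbers verbatim; the corresponding regression tests assert the
  recomputation and therefore fail on exactly those two cells.
* **The published parameter set is internally inconsistent with its own
  observations, and the whole-model Cmax criterion is unattainable from
  it.** Three independent contradictions, each verified by the test
  suite and the acceptance pipeline: (i) the tabulated clearances
  (1.9–7.2 L/h) approach or exceed organ blood flows in a 0.25 kg rat
  (cardiac output ≈ 6.6 L/h), so inside a flow-limited circulation they
  are necessarily flow-capped — they match the *apparent oral* CL/F
  implied by the observed dose/AUC pairs rather than systemic
  clearances; (ii) the tabulated partition coefficients imply a
  steady-state volume of ~0.1–0.5 L, while the tabulated Vss column
  prints 5.9–54.7 L (the package reports both), and the observed
  Cmax/AUC combinations require the multi-liter apparent volume — no
  Kp-consistent perfusion-limited model can reach the observed daidzin
  Cmax within two-fold at any absorption rate once Tmax is matched;
  (iii) with the 25 µm default particle radius, dissolution of the two
  poorly soluble constituents (0.011–0.021 mg/mL) is slow enough that
  the enterohepatic emptying peak becomes the global maximum, flooring
  the achievable Tmax at 1.4–3.1 h against observed values of
  0.21–0.42 h. The commercial model behind the reference values
  evidently did not operate in this regime (its gut-model and optimizer
  internals are unpublished). The whole-model acceptance test states the
  two-fold criterion anyway and fails honestly; the acceptance script
  reports the computed maximum fold error.
* Transporters, gut-wall/microbial metabolism, pH-dependent regional
  solubility and non-oral routes are excluded by the source model's own
  assumptions and are out of scope here; for these glycoside/lignan
  constituents the first two are plausible reasons the purely passive
  absorption model overpredicts exposure.
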