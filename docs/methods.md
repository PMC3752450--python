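# Methods

## The model

`nasotrans` simulates a monolayer of human nasal epithelial (HNE) cells
separating two well-stirred salines: the airway lumen and the interstitial
(serosal) fluid. A single cell compartment carries six dynamical variables —
volume per unit epithelial area `W_i` (cm³ cm⁻²), moles of Na⁺, K⁺ and Cl⁻
per unit area, and the apical and basolateral membrane potentials. The
potential conventions are

    V_a = ψ_cell − ψ_lumen,   V_b = ψ_cell − ψ_serosa,
    V_t = ψ_lumen − ψ_serosa = V_b − V_a,

with the serosal bath as earth, so a healthy epithelium has a lumen-negative
V_t of a few millivolts.

Transport pathways:

* **Channels** (apical ENaC and CFTR; basolateral K⁺ and Cl⁻ channels) carry
  Goldman–Hodgkin–Katz (GHK) constant-field currents, parameterised by the
  membrane permeabilities `P_Na_ap`, `P_Cl_ap`, `P_K_bl`, `P_Cl_bl` (μm/s).
  The removable singularity of the GHK expression at V = 0 is replaced by its
  analytic limit P·z·F·(c_in − c_out) for |zFV/RT| < 10⁻⁶.
* **Na⁺/K⁺-ATPase** (basolateral): a saturating cycle model, flux
  ρ_NaK·v_max·(Na_i/(Na_i+K_Na))³·(K_s/(K_s+K_K))², exporting 3 Na⁺ and
  importing 2 K⁺ per cycle (one net charge out).
* **NKCC1** (basolateral): an electroneutral two-conformation carrier with
  rapid-equilibrium binding of 1 Na⁺, 1 K⁺ and 2 Cl⁻ per cycle. The cycle
  flux vanishes exactly when [Na][K][Cl]² is equal on the two faces and is
  inward when the serosal product is larger.
* **Paracellular shunt**: GHK currents across the tight junction with −V_t as
  the driving potential (serosa as the "inner" face). The junction is
  non-selective and also passes the gluconate-like substitute anion, with a
  configurable permeability relative to its Cl⁻ branch
  (`pa_selectivity["imp"]`, default 1). At the default the junction is blind
  to an iso-osmotic luminal Cl⁻ substitution and produces no diffusion
  potential — forced by the physiology the model must reproduce: epithelia
  with no apical Cl⁻ conductance show near-zero low-Cl⁻ V_t responses, which
  is impossible if the junction rectifies a 115 → 3 mM Cl⁻ swap.
* **Water**: osmotic flux J_w = P_w·ΔS through each membrane, with ΔS the
  total solute difference (Na⁺+K⁺+Cl⁻+impermeant).

Mass balances and the equivalent circuit (Kirchhoff's law at the lumen node
and at the earthed serosa node, membrane capacitance C_m = 1 μF cm⁻²) give
six coupled stiff ODEs. Positive channel current is positive charge out of
the cell; positive carrier flux is into the cell; positive water flux is
serosal→mucosal.

**Impermeant-species closure.** The intracellular impermeant amount `N_imp`
and mean valence `z_imp` are set once at initialisation by (i) osmotic
balance with the serosal bath at the reference composition
([Na]ᵢ, [K]ᵢ, [Cl]ᵢ) = (25, 120, 45) mM for a 10 μm cell column and
(ii) exact equality of intracellular net charge with the capacitive charge
at the initial potentials (bulk electroneutrality up to ~10⁻¹² mol cm⁻²).
This yields z_imp ≈ −1, the standard closure for epithelial cell models.
The dynamics conserve (ionic charge − capacitive charge) exactly.

## Steady states

Two routes are implemented and cross-checked in the test suite:

* **relaxation** — stiff integration (LSODA) in doubling time windows until
  the relative rate max(|Ṅ/N|, |Ẇ/W|, |V̇|/25 mV) < 10⁻⁹ s⁻¹, with
  trajectories flagged non-physiological on negative volume/moles or
  |V| > 200 mV;
* **root** — Newton solution of the algebraic system in log-volume/log-mole
  variables. Because the dynamics conserve net charge minus capacitive
  charge, the raw Jacobian is singular; the basolateral charging equation is
  replaced by the conserved-charge closure, which restores full rank and
  pins the state to the correct invariant manifold.

`solve_steady_batch` runs the same root system as a damped (Levenberg)
Newton iteration vectorised over ~10⁴–10⁵ parameter sets at once, with row
weighting that balances the milliseconds-to-hours spread of the relaxation
times, per-sample adaptive damping, and step clipping. Perturbed conditions
(ENaC block, low luminal Cl⁻, CFTR knockout) sit tens of millivolts from the
basal warm start, outside the Newton basin, so they are reached through a
short continuation schedule (block factors 0.25 → 0.05 → 0; luminal Cl⁻
40 → 12 → 3 mM). Samples that fail to converge are flagged and counted as
discarded, never silently accepted; the flag rate at the default
configuration is ≲1% of uniform draws.

## Observables and protocols

The nine filtered observables are basal [Na⁺]ᵢ, [Cl⁻]ᵢ, V_a, V_b, V_t and
the *changes* ΔV_a and ΔV_t after two perturbations applied independently
from the basal state: complete amiloride block (P_Na_ap → 0) and luminal
low-Cl⁻ substitution ([Cl⁻]_l → 3 mM, replaced mole-for-mole by impermeant
anion at constant osmolarity). The published constraint table gives closed
ranges per observable and condition (non-CF, CF); classification is
inclusive at the bounds. The clinical nasal-PD protocol composes the same
perturbations sequentially in time (amiloride at 5 min, low Cl⁻ with
amiloride maintained at 10 min) and is integrated as a time course.

A note on the two ΔV_a observables: the constraint table's row labels for
these entries are given here as changes rather than post-perturbation
absolute values. The absolute reading is internally inconsistent for the
healthy condition — it would require the apical membrane to depolarise on
ENaC block while the apical Cl⁻ driving force moves from +1.1 to −9.5 mV,
which would need [Cl⁻]ᵢ ≈ 118 mM — whereas the change reading is coherent
for both conditions and matches the microelectrode literature
(≈ −10 mV apical hyperpolarisation on amiloride in health, ≈ −35 mV in CF).

## Parameters

Free transport parameters (the axis of all inference, in the published
table's units and row order): `P_Na_ap`, `P_Cl_ap`, `P_K_bl` (μm/s),
`rho_NaK`, `rho_NKCC` (10⁻¹⁰ mol cm⁻²), `P_Cl_bl` (μm/s). Fixture columns
`table1_baseline`, `table1_nonCF`, `table1_CF` ship exactly the printed
values.

Fixed configuration: paracellular scale `P_pa` with per-ion selectivity
multipliers (all 1 by default; the cation-selective variant multiplies the
anion branch by 0.5), and osmotic water permeabilities `P_w_ap = P_w_bl =
0.2 cm⁴ mol⁻¹ s⁻¹`. The water permeability is deliberately large enough
that osmotic equilibration is fast relative to ionic relaxation; a 10×
change moves steady-state potentials by < 0.1 mV (tested), so its exact
value is immaterial to every reported quantity.

### Calibration of the fixed constants

The pump and cotransporter sub-models are *reduced* cycle models; their
turnover scales and apparent affinities are effective constants, and the
source supplement that fixed them is not part of the inputs. They were
therefore reconstructed by a one-off calibration, frozen in
`data/kinetics.yaml` / `data/baths.yaml` before any population run:

1. For each candidate configuration (P_pa, affinities, bath Cl⁻/K⁺
   partition), the two turnover scales (v_max, k_t) are root-solved so that
   the fitted non-CF parameter column reproduces the two printed basal
   apical driving forces exactly: V_a − E_Na = −65.8 mV and
   V_a − E_Cl = +1.1 mV.
2. The remaining constants were searched (randomised, then locally refined)
   until both fitted columns (non-CF and CF) place all 18 observables inside
   their published physiological ranges and the post-amiloride apical Cl⁻
   driving force is as close as possible to the printed −9.5 mV.

The frozen configuration achieves all 18 ranges with the post-amiloride
driving force at −10.15 mV (0.65 mV from the printed value; the
reconstruction band for these quantities is ±3 mV). Two notes on the
outcome: the effective v_max and k_t are numerically large because the
calibrated apparent affinities put the carriers far from saturation at the
operating point (the density parameters ρ absorb any rescaling of the
turnover constants); and the loop-current constraint pins P_pa near
0.029 μm/s — the −65.8 mV Na⁺ driving force across P_Na_ap = 0.024 μm/s
implies an absorptive current of tens of μA cm⁻² that must return through
the shunt at a single-digit lumen-negative V_t.

The default bath is a symmetric Krebs-bicarbonate-Ringer-like saline
(Na 140, K 4.52, Cl 115.3, impermeant 30.5 mM; 290.3 mM total), with
bicarbonate/phosphate lumped into the impermeant pool; temperature 310 K;
F = 96 485 C mol⁻¹, R = 8.314 J mol⁻¹ K⁻¹.

## Inference pipeline

**Estimation** (`estimate`): bound-constrained trust-region-reflective least
squares over the six free parameters, residuals weighted by the reciprocal
half-widths of the published physiological ranges (making potentials and
concentrations commensurate); non-physiological parameter sets return a
large finite penalty residual (10³ per slot) so optimisers can back out.
Multi-start (default 10, seeded) inside the box. Because the original
time-course recordings exist only as figures, estimation is validated by
parameter recovery on synthetic data: noise-free recovery is within 5% from
starts perturbed ×(0.5–2); under 1 mV / 2 mM Gaussian noise the channel
permeabilities stay identifiable to ~10–15% while the carrier densities are
softer — the cotransporter density in particular is practically
unidentifiable from steady-state observables, because near its operating
point its flux is set by the concentration disequilibrium rather than the
carrier number.

**Monte Carlo filtering** (`population`): N parameter sets drawn
independently per parameter from U(0, 5 × baseline), all nine observables
computed per set, classification against the non-CF and CF range tables
independently. The full sample is drawn up front from one seeded generator,
so results are independent of evaluation chunking. Integration/root
failures, negative volumes or moles, runaway potentials and the all-zero
degenerate vector are discarded. Paracellular variants re-run the CF-side
evaluation with P_pa halved and/or the junction anion branch halved
(cation-selective); these change the magnitudes but not the direction of
the CF parameter shifts.

**Sensitivity** (`sensitivity`): ordinary least squares of a model output on
the six parameters, each normalised by its baseline value (a coefficient is
then "mV per baseline-multiple"; the alternative normalisation to the
sampled upper bound would rescale all coefficients by exactly 5 and leaves
every reported ratio invariant). Standard errors from the OLS covariance;
rank deficiency raises with the collinear columns named.

**Synthetic data** (`synthetic`): observables from a ground-truth parameter
set plus independent Gaussian noise (σ_potential, σ_concentration), and
filter bounds as symmetric windows around the truth's observables. This
emulates between-culture variability as independent measurement scatter; it
does not emulate correlated biological covariation across observables, so
recovery results bound what the estimator can do under the stated noise, not
under every real-world error structure.

## Problem sizes and numerical choices

* Steady-state tolerances: relaxation rate norm < 10⁻⁹ s⁻¹; root residual
  (scaled) < 10⁻⁹ declared, typically 10⁻¹²–10⁻¹⁴ reached; the two routes
  agree to < 10⁻⁶ relative on every fixture (tested).
* The shared test population uses 10⁵ draws (≈ 1 min); the acceptance
  script defaults to 10⁶ draws — the scale of the original filtering
  experiment — yielding >10³ accepted non-CF sets, so the regression
  coefficients carry standard errors of a few hundredths of a millivolt
  and the knockout tail minimum is resolved.
* The batched Newton solver processes ~10⁴ samples/s/steady-state on one
  core; a 10⁶-draw filter (seven staged solves per sample) runs in ~10 min.
* Bound comparisons are inclusive (closed ranges; measure-zero effect).
* Per-run provenance: every CLI command writes its fully resolved
  configuration (constants, baths, parameters, seeds) beside its outputs.

## Known limitations

* Bicarbonate transport, apical K⁺ channels, pH regulation and
  airway-surface-liquid dynamics are outside the model's scope.
* The pump is voltage-independent; rheogenic-pump voltage dependence would
  slightly reshape the post-amiloride hyperpolarisation.
* The NKCC and pump constants are effective values from the calibration
  described above, not measured microscopic rate constants; only their
  functional form (saturation, stoichiometry, thermodynamic consistency,
  proportionality to density) is mechanistically meaningful.
* The Monte Carlo acceptance *fractions* depend on the exact reconstruction
  of the fixed constants; the direction of the CF parameter shifts and the
  dominant sensitivity structure are robust across every configuration
  explored, the absolute per-10⁶ counts less so.
* In this reconstruction the accepted non-CF population carries a genuine
  (if secondary) coupling between apical Cl⁻ permeability and basal V_t:
  the low-Cl⁻ response window can only be met by NKCC-supplied apical Cl⁻
  secretion, so accepted parameter sets skew towards secretory operating
  points where ∂V_t/∂P_Cl_ap < 0. A configuration in which that coefficient
  is strictly negligible while both fitted columns stay inside every
  published range was not found; the two requirements appear jointly
  infeasible within this model structure (see the junction discussion
  above), and the reported coefficient ratio should be read with that in
  mind.
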