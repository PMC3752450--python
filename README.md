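# nasotrans

Quantitative modelling of ion transport in human nasal epithelium (HNE), and
the inference pipeline built on it. The package addresses a question at the
heart of cystic fibrosis (CF) airway physiology: CF nasal epithelia show a
hyperpolarised basal transepithelial potential (V_t) and a much larger
amiloride response than healthy epithelia — are these changes just the
electrical consequence of losing the CFTR anion channel, or do they require
an additional increase in apical Na⁺ (ENaC) permeability? The model lets the
question be answered quantitatively: loss of apical Cl⁻ permeability alone
hyperpolarises basal V_t by at most a few millivolts, far short of the
~−20 mV seen in patients, so a parallel ENaC increase is required.

It is intended for epithelial physiologists and modellers who want to
simulate nasal potential-difference (PD) measurements, estimate transport
parameters from bioelectric observables, or reproduce the population-level
filtering and sensitivity analyses.

## The model

A single well-stirred cell compartment between two perfused salines, with
six state variables: cell volume `W_i`, intracellular moles of Na⁺, K⁺ and
Cl⁻, and the apical and basolateral membrane potentials
(`V_a = ψ_cell − ψ_lumen`, `V_b = ψ_cell − ψ_serosa`,
`V_t = V_b − V_a`, serosa earthed). Channel and paracellular currents follow
the Goldman–Hodgkin–Katz flux equation

    I = P z² F² V/(RT) · (c_in − c_out e^(−zFV/RT)) / (1 − e^(−zFV/RT)),

the Na⁺/K⁺-ATPase is a saturating 3Na⁺:2K⁺ cycle, NKCC1 an electroneutral
1Na⁺:1K⁺:2Cl⁻ carrier, and water flux is proportional to the osmotic
gradient. Membrane potentials evolve by capacitive charging under
Kirchhoff's law at the lumen and serosa nodes (open circuit). Six free
transport parameters — `P_Na_ap` (ENaC), `P_Cl_ap` (CFTR), `P_K_bl`,
`P_Cl_bl`, `rho_NaK`, `rho_NKCC` — are the axis of all inference; packaged
fixtures carry the published baseline and fitted non-CF/CF values.
See `docs/methods.md` for the full model description and the calibration of
the fixed constants.

## Worked example

```python
from nasotrans import (CL, NA, default_baths, find_steady_state,
                       load_params, reference_state)
from nasotrans.simulate import apply_amiloride, driving_force

baths = default_baths()
params = load_params("table1_nonCF")          # fitted healthy epithelium
basal = find_steady_state(params, baths, reference_state(baths))
print(f"V_t = {basal.V_t:.1f} mV")
print(f"apical Na+ driving force = {driving_force(basal, NA, 'apical', baths):.1f} mV")
print(f"apical Cl- driving force = {driving_force(basal, CL, 'apical', baths):.1f} mV")

amil = basal
for block in (0.75, 0.95, 1.0):               # staged complete ENaC block
    amil = find_steady_state(apply_amiloride(params, block=block), baths, amil.state)
print(f"after amiloride: dV_t = {amil.V_t - basal.V_t:+.1f} mV, "
      f"Cl- driving force = {driving_force(amil, CL, 'apical', baths):.1f} mV")
```

prints

```
V_t = -13.2 mV
apical Na+ driving force = -65.8 mV
apical Cl- driving force = 1.1 mV
after amiloride: dV_t = +6.9 mV, Cl- driving force = -10.1 mV
```

The basal Na⁺ driving force (−65.8 mV) dwarfs the Cl⁻ driving force
(+1.1 mV): basal V_t is ~60× more sensitive to ENaC than to CFTR
permeability, which is why CFTR loss alone cannot hyperpolarise V_t to CF
levels. Only after ENaC block does the Cl⁻ driving force become substantial
(−10.1 mV), making the low-Cl⁻ response a usable readout of CFTR function.

## The analysis pipeline

Numbered drivers under `analysis/` run the study end to end and write their
tables to `results/`:

| script | what it does |
|---|---|
| `01_fitted_columns.py` | steady states and driving forces of the published parameter columns, checked against the physiological ranges |
| `02_parameter_recovery.py` | least-squares recovery of known parameters from synthetic (noise-free and noisy) observables |
| `03_mc_filter.py` | Monte Carlo filtering of U(0, 5×baseline) parameter draws into non-CF and CF populations |
| `04_sensitivity.py` | regression of V_t and the clinical responses on the normalised parameters over the filtered population |
| `05_cftr_knockout.py` | change in basal V_t on pure CFTR loss, across the filtered non-CF population |
| `06_nasal_pd.py` | simulated three-phase clinical nasal-PD recordings for four parameterisations |

The same operations are available as a CLI
(`nasotrans simulate|fit|mc-filter|sensitivity|knockout|synth`); every
command writes its fully resolved configuration beside its outputs.

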