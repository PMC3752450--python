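# Kinetic constants of the carrier sub-models and the fixed (non-inferred)
# transport configuration. These are EFFECTIVE constants of the reduced pump
# and cotransporter cycle models: the turnover scales (v_max, k_t, k_e), the
# apparent affinities and the paracellular permeability were calibrated once,
# by pinning the fitted non-CF parameter column to the published basal apical
# driving forces (-65.8 mV for Na+, +1.1 mV for Cl-) and requiring both
# fitted columns to reproduce every published physiological range (see
# docs/methods.md, "Calibration of the fixed constants"). Do not edit
# piecemeal: the set is self-consistent only as a whole.
pump:
  v_max: 581.371347   # s^-1, maximal cycle rate per pump (effective)
  K_Na: 55.372        # mM, apparent intracellular Na+ affinity
  K_K: 0.330576       # mM, apparent serosal K+ affinity
nkcc:
  k_t: 1957.262245    # s^-1, loaded-carrier translocation (effective)
  k_e: 14303.457188   # s^-1, empty-carrier translocation (effective)
  K_Na: 75.2565       # mM
  K_K: 26.6172        # mM
  K_Cl: 52.1943       # mM, per Cl- site
fixed_transport:
  P_pa: 0.0290921     # um/s, paracellular permeability scale (non-selective)
  pa_substitute: 1.0  # substitute-anion junction permeability relative to Cl-
  P_w: 0.2            # cm^4 mol^-1 s^-1, osmotic water permeability per membrane
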