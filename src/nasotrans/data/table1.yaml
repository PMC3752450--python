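# Published transport-parameter columns: literature baseline values and the
# fitted non-CF / CF estimates. Permeabilities in um/s, densities in
# 1e-10 mol/cm^2.
table1_baseline:
  P_Na_ap: 0.028
  P_Cl_ap: 0.072
  P_K_bl: 0.080
  rho_NaK: 0.400
  rho_NKCC: 0.400
  P_Cl_bl: 0.100
table1_nonCF:
  P_Na_ap: 0.024
  P_Cl_ap: 0.066
  P_K_bl: 0.103
  rho_NaK: 0.127
  rho_NKCC: 0.188
  P_Cl_bl: 0.097
table1_CF:
  P_Na_ap: 0.065
  P_Cl_ap: 0.006
  P_K_bl: 0.400
  rho_NaK: 0.489
  rho_NKCC: 2.000
  P_Cl_bl: 0.144
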