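# Physiological filter bounds (lower, upper) on the nine model observables,
# per condition, from primary-culture measurements. Concentrations in mM,
# potentials in mV. dVa_amil / dVa_lowCl are the changes in apical membrane
# potential after amiloride and after luminal Cl- removal; dVt_* are the
# corresponding transepithelial-potential changes.
nonCF:
  Na_i: [18.0, 43.2]
  Cl_i: [32.5, 84.4]
  V_a: [-38.6, -14.9]
  V_b: [-45.1, -24.2]
  V_t: [-15.5, -2.7]
  dVa_amil: [-14.0, -5.5]
  dVt_amil: [4.7, 10.1]
  dVa_lowCl: [9.2, 15.0]
  dVt_lowCl: [-12.7, -6.1]
CF:
  Na_i: [21.0, 51.3]
  Cl_i: [32.5, 84.4]
  V_a: [-37.7, 6.7]
  V_b: [-59.3, -33.6]
  V_t: [-59.2, -8.2]
  dVa_amil: [-47.4, -29.0]
  dVt_amil: [30.1, 47.1]
  dVa_lowCl: [-5.3, 11.1]
  dVt_lowCl: [-16.5, 9.9]
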