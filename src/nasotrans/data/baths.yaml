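# Perfusate presets (mM). The default is a symmetric Krebs-bicarbonate-
# Ringer-like saline (total osmolarity 290.3 mM); "imp" lumps the anions the
# model does not transport (bicarbonate, phosphate, organic anions) into a
# single impermeant-for-the-cell-membrane pool. The exact partition between
# Cl- and the lumped pool was fixed during the one-off calibration described
# in docs/methods.md.
default:
  lumen: {Na: 140.0, K: 4.52485, Cl: 115.316, imp: 30.45915}
  serosa: {Na: 140.0, K: 4.52485, Cl: 115.316, imp: 30.45915}
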