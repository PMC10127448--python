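# Synthetic defined medium (SDM): glucose and ammonium as sole carbon and
# nitrogen sources, minimal-medium convention for the remaining inorganics.
#
# Exchange-reaction ids follow the yeast-GEM v8.x numbering; adapt the ids if
# your model version differs (apply_medium errors on unknown/non-exchange
# ids, naming them).  Uptake rates in mmol/gDW/h; glucose limited at 10, the
# customary value for aerobic batch simulations, inorganics effectively
# unconstrained.  default_closed shuts every other uptake, which is what
# makes glucose and ammonium the sole C and N sources.
uptake_bounds:
  r_1714: 10     # D-glucose exchange
  r_1654: 1000   # ammonium exchange
  r_1992: 1000   # oxygen exchange
  r_2005: 1000   # phosphate exchange
  r_2060: 1000   # sulphate exchange
  r_2100: 1000   # water exchange
  r_1832: 1000   # H+ exchange
  r_1861: 1000   # iron(2+) exchange
  r_2049: 1000   # sodium exchange
  r_2020: 1000   # potassium exchange
  r_1671: 1000   # chloride exchange
default_closed: true
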