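{
  "NorthAtlantic": {
    "suess_a": 0.0294,
    "suess_r": 0.0231,
    "laws_l": 0.0015
  },
  "_comment": "Reconstructed regional presets for the exponential d13C decline (suess_a, suess_r) plus the linear temperature-mediated term (laws_l); cumulative decline d(t) = -a*(exp(r*(t-1850))-1) - l*(t-1850). Values are reconstructed defaults, not measured constants; edit per region."
}
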