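{
  "out_dir": "scratch/example_run",
  "scenario": "ci_small",
  "models": ["null", "class", "ind", "class+ind"],
  "chains": 3,
  "iterations": 1500,
  "warmup": 1500,
  "n_perm": 999,
  "seed": 1
}
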