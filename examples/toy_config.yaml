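# Toy end-to-end run: ~31 samples x 80 ASVs, completes in well under a minute.
seed: 42
output_dir: results_toy
synthetic:
  sample_scale: 0.33          # 11 / 14 / 6 samples per habitat
  n_asvs: 80
  n_modules: 4
  module_size: 10
  within_module_rho: 0.8
network:
  n_resamples: 1000
spatial:
  mantel_permutations: 499
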