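# Full-pipeline configuration: simulate a study-size cohort and run the
# analysis sequence with the composite stage-site model.
seed: 1
output_dir: out/run1
simulation:
  n: 284
mcmc:
  n_iter: 4000
  n_burnin: 2000
  thin: 2
  n_chains: 2
screening:
  alpha: 0.1
variants: [stage_site_composite]
compare: false
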