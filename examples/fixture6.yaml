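# Small synthetic study: 6 species, 25 adjacency classes.
# Run e.g.:  adjevo simulate --config examples/fixture6.yaml --out-dir out
seed: 1
out_dir: adjevo_out
simulation:
  n_species: 6
  n_classes: 25
  dup_rate: 0.08
  loss_rate: 0.1
  kappa: 1.5
  drop_fraction: 0.1
model:
  kappa: 1.0
fit:
  free: [kappa, root_prob, branch_lengths]
  maxiter: 300
threshold: 0.9
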