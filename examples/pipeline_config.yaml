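# Demo configuration for the end-to-end pipeline:
#   chemevol all --config examples/pipeline_config.yaml --seed 1 --outdir demo_out
# Four simulated chemoreceptor families on the nine-species tree, one
# of which can be given foreground selection via foreground_branches.
seed: 1
outdir: demo_out
n_families: 4
n_codons: 200
dup_rate: 0.3
loss_rate: 0.1
pseudo_rate: 0.1
kappa: 2.0
site_classes:
  - [0.9, 0.2]
  - [0.1, 5.0]
foreground_branches: [Dsuz]
bootstrap_reps: 50
gamma_shape: 1.0
dup_cost: 1.5
loss_cost: 1.0
support_threshold: 0.9
beb_threshold: 0.95
pseudogene_fraction: 0.20
tm_threshold: 1
selection_branches: [Dsuz_1]
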