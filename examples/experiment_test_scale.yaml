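# Desk-scale scheme-comparison experiment for `ecgacgan run --config ...`.
# Keys mirror ecgacgan.experiments.ExperimentConfig.
n_subjects: 5
sessions_per_subject: 3
duration_s: 20.0
fs: 500.0
cycle_len: 256
seed_fixture: 0
seed_gan: 100
seed_ensemble: 200

# paper_faithful: true restores the canonical member hyperparameter grid
# (epochs 500/750, batch 256/512); the desk-scale run below relaxes it.
paper_faithful: false
member_epochs: 50
member_batch: 32
n_members: 6
top_k: 3

gan_epochs: 60
gan_pretrain_epochs: 120
gan_batch_size: 64
gan_cycles_per_class: 100
n_synthetic_per_subject: 8

registration_sessions: [1, 2]
comparison_sessions: [3]
noise:
  baseline_amp: 0.15
  powerline_amp: 0.05
  broadband_sd: 0.02
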