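# Desk-scale privacy/utility comparison: non-private baseline vs two
# differentially private arms at declared budgets. sigma for the eps-arms
# is found by bisecting the moments accountant; q and T here are the
# package's own desk-scale choices.
cohort:
  n_patients: 5000
  seed: 100
arms:
  - {name: nonprivate, sigma: 0.0, lot_size: 256, n_steps: 3000, use_per: true}
  - {name: eps8, target_epsilon: 8.0, lot_size: 256, n_steps: 3000, delta: 1.0e-6, use_per: true}
  - {name: eps2, target_epsilon: 2.0, lot_size: 256, n_steps: 3000, delta: 1.0e-6, use_per: false}
seeds: [0, 1, 2, 3, 4]
train_frac: 0.8
hidden_sizes: [32, 32]
gamma: 0.99
learning_rate: 1.0e-3
target_sync_period: 100
eval_period: 500
phis: [0.7]
max_eval_transitions: 6000
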