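# scaled-down training schedule for desk-scale synthetic cohorts
n_epochs: 200
learning_rate: 1.0e-3
weight_decay: 1.0e-3
dropout_rate: 0.0
n_batch: 41
seed: 0
validation: false
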