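# Desk-scale training profile for `taxoformer train --config`.
# Flags given on the command line take precedence over these values.
scheme: vocab
k: 6
d_model: 32
n_blocks: 1
h: 4
d_ff: 256
reduction: mean
dropout: 0.0
lr: 0.002
batch_size: 64
max_steps: 3000
patience: 500
val_interval: 100
val_fraction: 0.1
threshold: 0.5
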