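# Reference-scale training protocol (GPU-class corpora; far beyond what a
# single CPU core can train — kept for documentation of the full protocol).
scheme: vocab
k: 12
d_model: 64
n_blocks: 1
h: 8
d_ff: 256
reduction: mean
dropout: 0.1
lr: 0.01
batch_size: 2048
max_steps: 300000
patience: 50000
val_interval: 1000
threshold: 0.5
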