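# Methods

## Problem and model

`taxoformer` assigns short metagenomic sequencing reads (100–250 bp) to
taxonomic classes (species and/or genus) with an encoder-only transformer.
A read is tokenized into overlapping canonical k-mers, embedded, summed with
a fixed sinusoidal positional encoding, passed through a stack of masked
multi-head self-attention blocks, reduced to a single vector, and classified
by one linear head or by interconnected multi-level heads.

### Tokenization

Stride-1 k-merization of an L-bp read yields n = L − k + 1 tokens.  Every
k-mer is replaced by its *canonical* form (the lexicographic minimum of the
k-mer and its reverse complement), which makes the token multiset of a read
identical to that of its reverse complement — reads are classified the same
way regardless of sequencing strand.  Four schemes map canonical k-mers to
embedding rows:

- **char** — one token per base (5 symbols); mostly a baseline.
- **vocab** — an explicit vocabulary of all canonical k-mers, enumerated
  combinatorially in lexicographic order (4^k/2 entries for odd k,
  (4^k + 4^{k/2})/2 for even k).  Practical for k ≤ 13.
- **lsh** — Hamming locality-sensitive hashing: a fixed seeded subset of
  m = ⌈0.8 k⌉ positions is extracted from the canonical k-mer and hashed
  with MurmurHash3 (x64-128, low 64 bits) modulo b buckets.  k-mers that
  differ only at non-sampled positions collide by construction, so nearby
  k-mers share embeddings; b (e.g. 2^22–2^23) bounds the table size for
  large k (e.g. k = 15).
- **hash** — hash embeddings: q (default 6) independently seeded hashes
  select q component vectors from a shared pool of b rows; a further hash
  selects a row of importance weights, and the embedding is the
  importance-weighted sum of the components.  This compresses the
  vocabulary while letting training resolve collisions.

All schemes share the special ids PAD=0, UNK=1 (windows containing N),
CLS=2; hashed/vocab ids start at 3.  MurmurHash3 is implemented in-repo
(scalar plus a vectorised batch path for keys ≤ 15 bytes, bit-identical)
because the classifier must hash deterministically across platforms.

### Encoder

Token embeddings S ∈ R^{n×d} are scaled by √d_model and the positional
matrix P is added, with P[p, 2k] = sin(f_k·p), P[p, 2k+1] = cos(f_k·p),
f_k = 10000^{−2k/d_model}, positions p = 1..n.  The first component has
period exactly 2π; wavelengths grow geometrically to 2π·10⁴.

Each encoder block is post-norm:

    Z = MultiHead(E),  N = LN(Z + E),  O = LN(MLP(N) + N)

with a single-hidden-layer ReLU MLP (width d_ff) applied position-wise, and
layer normalisation over the feature dimension (ε = 1e−5, learned gain and
bias).  Attention uses per-head scaled dot products, d_k = d_v = d_model/h,
so the trainable parameter count is exactly invariant in the head count h.
Padding is handled with an additive −∞ bias on masked key columns before
the row softmax, giving masked positions exactly zero attention weight
(a multiplicative mask cannot express this and leaves the softmax
ill-defined).  Dropout, when enabled, is applied to the input encoding, the
attention output, and the MLP output, before the residual additions.

The token dimension is reduced by the masked mean over real positions
(default), by taking the CLS position, or by a learned linear map of the
concatenated sequence (fixed n only).

### Classification heads

A single-level model applies one linear classifier to the reduced vector.
A multi-level model has one MLP head per taxonomic level, ordered coarse →
fine, with interconnections

    ŷ_i = MLP_i(x_b) + T_{i−1} ŷ_{i−1},   T_0 = 0,

so each finer level receives a linear transform of the coarser level's
scores.  Zeroing every T reduces the model exactly to independent heads.

### Initialisation

Projections use He-uniform fan-in initialisation; embedding tables are
N(0, d_model^{−1/2}); layer-norm gain/bias are 1/0.  The output layers of
the classification heads (and the T transforms) are scaled by 0.3 so that
initial logits are near zero and the initial loss sits at ln(m) within a
few percent — large initial logits both distort the first optimisation
steps and make the loss scale depend on the class count.

## Training

Adam with cross-entropy loss.  The reference-scale protocol is lr 0.01 at
batch 2048 with early stopping after 50,000 non-improving steps (validation
loss checked periodically; the best-validation checkpoint is restored, not
the last).  Desk-scale runs use batch 64 and lr 2e−3 — the large reference
rate is matched to the large batch, and transplanting it to batch 64
destabilises training — with patience 500 steps and validation every 100.

Single-level models train unweighted: the read generator balances the
dataset at that level by construction.  Multi-level models always use
per-level class weights w_j ∝ 1/count_j, normalised to mean 1 (so the
weighted loss keeps the scale of the unweighted loss and the learning rate
transfers), because a set balanced at species level is generally imbalanced
at genus level.

Streaming: batches are drawn through a bounded-buffer shuffle
(`stream_batches`), so peak memory is buffer + batch regardless of dataset
size; an exhausted stream restarts (epochs).  Optional flags: sparse
embedding updates (only rows touched in the batch have Adam moments and
values updated — lazy Adam semantics; final loss agrees with dense mode
within tolerance on small tasks).  Mixed precision is not implemented; the
forward/backward pass is float32 throughout (float64 passes through for
analysis use).

## Inference

Paired-end mates are scored separately and their unnormalised scores are
component-wise averaged *before* the softmax; with three or more classes
the opposite order (averaging probabilities) can change the ranking, and
with two classes the orders provably agree.  A read (or pair) is assigned
its argmax class when the softmax confidence reaches the threshold (default
0.5, configurable) and is reported "unclassified" otherwise; multi-level
models threshold each level independently.  One prediction is emitted per
fragment for paired data.

Metrics: precision = correct/classified, recall = correct/total, so
recall ≤ precision whenever anything is classified; with zero classified
reads precision is reported as NaN rather than 0 or 1.  Abundance profiles
are per-class fractions of classified reads; profiles are compared by
Euclidean (L2) distance.

## Synthetic data

The generators emulate the study conditions end to end:

- **Taxonomy** — a uniform-random root genome; each genus ancestor is the
  root with iid substitutions at rate `d_between`; each species genome is
  its genus ancestor with substitutions at `d_within` (substituted bases
  move to one of the 3 alternatives uniformly, so observed differences are
  exactly Binomial).  Defaults for the desk-scale experiment: 3 genera × 3
  species, 20 kb genomes, d_between = 0.15, d_within = 0.03 — within-genus
  divergence comparable to distinct congeneric gut species, at genome
  lengths small enough for CPU training.
- **Balanced read sets** — per-genome coverage C_i = round(L_max/L_i)·f
  (nearest integer, ties to even), so every class contributes ≈ f·L_max
  sequenced bases; f = 3 for training and f = 1 for validation at reference
  scale (one source table states coverage 4 for training; f is therefore a
  required argument, never silently defaulted).  Desk scale uses f = 25
  (≈ 30,000 150 bp reads over nine 20 kb genomes) and f = 2 held out.
- **Reads** — paired-end, insert length ~ Normal(400, 50) truncated to
  [read_len, genome length], mate 2 the reverse complement of the fragment
  end; iid substitution errors (1% default at desk scale).  This is a
  parametric stand-in for an empirical Illumina HiSeq2500 error profile:
  no indels, no quality-dependent error structure, no GC bias.  The
  classifier consumes base identities only, so the training signal it
  exercises is the same; results on these reads say nothing about
  indel robustness or platform-specific artefacts.
- **Mock communities** — abundances A_i = exp(N(μ=1, σ=2)) scaled to a
  total of M reads, R_i = A_i/ΣA · M, with largest-remainder rounding so
  ΣR_i = M exactly (ties broken by index).

What the synthetic data does *not* model: real inter-genome homology
structure (shared operons, mobile elements), contamination and chimeras,
uneven within-genome coverage, and the long-tailed class sizes of real
MAG collections.  Passing the desk-scale recovery therefore demonstrates
the implementation learns and profiles under controlled divergence — not
field performance on real gut metagenomes, which requires reference-scale
corpora and training budgets.

## Desk-scale parameter recovery

The end-to-end experiment (`taxoformer.experiments.run_parameter_recovery`)
trains the Vocab k=6 model (d_model 32, 1 block, 4 heads, d_ff 256, mean
reduction, batch 64, lr 2e−3, ≤ 3000 steps, 10% of the training reads held
out internally for early stopping) on ~30,000 reads and evaluates ~2,400
balanced held-out reads at threshold 0.5: read-level species and genus
recall (for the single-level model the genus call is the predicted species'
parent) and the L2 distance between the inferred and true species profiles.
The multi-level variant trains genus+species heads jointly under Eq.-style
interconnection and mean-1 inverse-count weights.  Runs are deterministic
given a seed; seed 1 is the default experiment seed, and seeds 2 and 3 give
equivalent results (single-level species recall 0.908 / 0.909 / 0.894,
genus recall 0.969 / 0.971 / 0.975, profile L2 0.008 / 0.015 / 0.024 for
seeds 1 / 2 / 3).  A run takes a few minutes on one CPU core.

## Known limitations

- The attention stack is O(n²) in read length; n_max defaults to 256
  tokens, ample for ≤ 250 bp reads at stride 1.
- Byte-pair tokenization is out of scope (it underperforms k-mers for this
  task and needs an external tokenizer-training step).
- The LSH family (seeded position subsampling) and the hash-embedding
  construction are one concrete realisation of the named schemes; both sit
  behind the tokenizer interface so alternates can be swapped.
- No abundance re-estimation (EM) or LCA-style fallback across levels.
- Training is single-threaded NumPy; reference-scale corpora (thousands of
  classes, 10^8 reads) are out of reach — the desk-scale profile is the
  supported regime.
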