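# taxoformer

Transformer-encoder taxonomic classification of short metagenomic
sequencing reads.

Metagenomic profiling asks, for every 100–250 bp read in a shotgun sample,
which species (or genus) it came from, and from those calls, what the
sample's taxonomic composition is.  `taxoformer` answers this with an
encoder-only self-attention model over canonical k-mer tokens — an
alternative to alignment/k-mer-index mappers and to recurrent deep
classifiers — together with everything needed to exercise the method end to
end on simulated data: genome/taxonomy simulators, coverage-balanced read
generation with a paired-end insert model, log-normal mock communities, and
read-level / profile-level evaluation.

It is written for bioinformatics researchers who want a transparent,
CPU-runnable reference implementation of the method: the model, its
training loop and its tokenizers are pure NumPy (with a small reverse-mode
autodiff tape), so every piece is inspectable and testable.

## The model

A read is tokenized into overlapping canonical k-mers (strand-invariant:
a k-mer and its reverse complement share one token id) through one of four
schemes — explicit vocabulary, character-level, LSH bucketing, or hash
embeddings — embedded, scaled by √d_model and summed with the sinusoidal
positional encoding

    PE(p, 2k) = sin(f_k p),  PE(p, 2k+1) = cos(f_k p),  f_k = 10000^(−2k/d_model),

then passed through post-norm encoder blocks

    Z = MultiHead(E),  N = LN(Z + E),  O = LN(MLP(N) + N)

with masked scaled dot-product attention, Attention(Q,K,V) =
softmax(QKᵀ/√d_k + M)V, where the additive mask M puts −∞ on padded key
columns so padding gets exactly zero weight.  The token dimension is
reduced (masked mean, CLS token, or learned concatenation) and classified
by a linear head, or by interconnected multi-level heads

    ŷ_i = MLP_i(x_b) + T_{i−1} ŷ_{i−1},  T_0 = 0,

so genus-level scores inform the species head.  Training is Adam on
(optionally inverse-count-weighted) cross-entropy with early stopping on
validation loss; paired-end mates are averaged score-wise before the
softmax at inference.  See `docs/methods.md` for the full account.

## Worked example

Simulate a small two-genus taxonomy, train a species-level classifier, and
evaluate held-out reads:

```python
from taxoformer import TransformerReadClassifier, simulate_taxonomy, generate_balanced_set
from taxoformer.metrics import precision_recall

tax = simulate_taxonomy(n_genera=2, species_per_genus=2, genome_length=8000,
                        d_between=0.15, d_within=0.03, seed=0)
train, train_manifest = generate_balanced_set(tax, f=20, err_rate=0.01, seed=0)
test, test_manifest = generate_balanced_set(tax, f=2, err_rate=0.01, seed=99,
                                            id_namespace="test")

clf = TransformerReadClassifier(scheme="vocab", k=6, d_model=32, n_blocks=1,
                                h=4, d_ff=256, batch_size=64, lr=1e-3,
                                max_steps=800, patience=400, val_interval=100,
                                random_state=0)
clf.fit([r.sequence for r in train], train_manifest["species_id"])

pred = dict(zip(test_manifest["read_id"], clf.predict([r.sequence for r in test])))
truth = dict(zip(test_manifest["read_id"], test_manifest["species_id"]))
report = precision_recall(pred, truth)
print(f"held-out reads: {report.n_reads}")
print(f"species precision: {report.precision:.3f}")
print(f"species recall:    {report.recall:.3f}")
```

Output (a few minutes on one CPU core):

```
held-out reads: 424
species precision: 0.974
species recall:    0.974
```

The four species differ by ~3% of sites within a genus and ~15% between
genera, with 1% simulated sequencing error; precision equals recall here
because `predict` classifies every read (no confidence threshold).  Use
`clf.classify(reads, threshold=0.5)` for thresholded calls with an
"unclassified" bucket, and `taxoformer.abundance_profile` to turn calls
into per-class fractions.

The estimator follows scikit-learn conventions (`get_params`, `clone`,
fitted attributes `classes_`, `history_`), accepts a 2-D label array
`[genus, species]` to build the interconnected multi-level heads, and
round-trips through `clf.save(dir)` / `TransformerReadClassifier.load(dir)`.

A CLI mirrors the workflow:

```bash
taxoformer simulate-genomes --n-genera 3 --species-per-genus 3 \
    --genome-length 20000 --seed 1 --out genomes.fa --taxonomy-out tax.tsv
taxoformer simulate-reads --genomes genomes.fa --taxonomy tax.tsv -f 3 \
    --err-rate 0.01 --seed 2 --out train.fq --manifest-out train.tsv
taxoformer train --train train.fq --train-labels train.tsv \
    --levels genus,species --seed 3 --out ckpt
taxoformer classify --model ckpt --reads sample_R1.fq.gz --reads2 sample_R2.fq.gz \
    --threshold 0.5 --out pred.tsv --profile profile.tsv
taxoformer evaluate --pred pred.tsv --truth truth.tsv --level species --out metrics.tsv
taxoformer mock-community --taxonomy tax.tsv -m 10000000 --seed 4 --out mock.tsv
taxoformer compare-profiles --a profile.tsv --b mock.tsv
```

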