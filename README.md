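# dhsnet

Classification of DNase I hypersensitive sites (DHSs) from DNA sequence
alone, for fragments of *variable* length (200–800 bp), with a
gated-inception convolutional network ending in a 1-D spatial pyramid
pooling (SPP) head.

DHSs mark nucleosome-depleted, accessible chromatin — the footprints of
enhancers, promoters, silencers and other cis-regulatory DNA. Their
genomic spans vary severalfold, which breaks the fixed-input assumption of
ordinary sequence CNNs: cropping loses signal, padding dilutes it. This
package is for computational genomicists who want a sequence-only DHS
classifier that takes each fragment at its native length, plus the full
surrounding pipeline: corpus construction from a genome FASTA and DHS BED,
length-binned multi-scale training, and standard evaluation statistics.

## The model

A fragment of length n is one-hot encoded as an n × 4 matrix (columns
A, C, G, T). Five inception-style convolution stages — every convolution
gated as `y = conv(x) ⊙ σ(conv_gate(x))` — with four stride-2 max pools
produce a 384-channel feature map of length n/16. The SPP head partitions
each channel into 1, 2 and 4 contiguous parts and averages each part:
1 + 2 + 4 = 7 features per channel, i.e. a fixed 2688-vector for any
input length. Three fully connected layers (836 → 376 → 2, batch-normed,
dropout 0.3) give class probabilities. All activations are LeakyReLU,
`y = x` if `x ≥ 0` else `x/100`. The default configuration has exactly
**3,077,382** trainable parameters.

Training is *multi-scale*: fragments are binned by length (bin width 50,
100 or 200 bp), every fragment is extended on its chromosome to its bin's
upper bound (so each bin is fixed-length and batches cleanly), and each
iteration runs one epoch per bin in ascending length order with a single
shared parameter set — SGD, momentum 0.98, learning rate 0.002 decayed
×0.97 every epoch, mini-batch 128.

Evaluation reports sensitivity, specificity, accuracy, the Matthews
correlation coefficient

    MCC = (Tp·Tn − Fp·Fn) / √((Tn+Fn)(Tn+Fp)(Tp+Fn)(Tp+Fp))

and the ROC AUC.

The network and its training loop are implemented in NumPy with explicit
backward passes (gradient-checked against finite differences); no deep
learning framework is required.

## Worked example

Real corpora come from genome FASTA + DHS BED downloads; everything is
equally runnable on the built-in synthetic fixtures, which plant an exact
8-mer motif in "DHS" intervals whose lengths follow a decreasing
distribution on [200, 800] bp, and draw a length-matched, same-chromosome,
non-overlapping negative for each positive.

```python
from dhsnet import (FixtureSpec, generate_fixture, sample_negatives,
                    build_multiscale_dataset, build_model, TrainConfig,
                    Trainer, score_dataset, evaluate_scores)

genomes, positives, excluded = generate_fixture(FixtureSpec(seed=0))
gmap = {g.chrom_name: g for g in genomes}
negatives = sample_negatives(gmap, positives, excluded, seed=1)
dataset = build_multiscale_dataset(gmap, positives + negatives,
                                   interval_width=100, seed=2)
model = build_model()
Trainer(model, TrainConfig(seed=3)).train(dataset, iterations=4)
scores, labels = score_dataset(model, dataset)
print(evaluate_scores(scores, labels).to_dict())
```

`examples/` contains one narrative script per capability. Running
`python examples/04_train_and_evaluate.py` (300 positives, 6 iterations,
a few minutes on one CPU) prints:

```
train rows per bin: [1308, 213, 9] (targets [400, 600, 800])
iteration 1: per-bin losses [0.928, 0.784, 1.005]
...
iteration 6: per-bin losses [0.357, 0.272, 0.107]
held-out: Sn=0.923 Sp=0.412 ACC=0.633 MCC=0.375 AUC=0.882
```

(Sn/Sp: fraction of held-out positives/negatives recovered at the 0.5
cutoff; MCC balances both errors on [−1, 1]; AUC is the probability a
random held-out positive outscores a random negative — here the ranking
is good while the 0.5 operating point is still conservative.) On the full
default fixture (1,000 positives) multi-scale training reaches held-out
AUC ≥ 0.95 within a handful of iterations, while a label-shuffled control
stays at ≈ 0.5.

A thin CLI wraps the same calls:

```bash
dhsnet make-fixture --seed 0 --out fixture/
dhsnet build-corpus --genome fixture/genome.fa --positives fixture/positives.bed \
    --excluded fixture/excluded.bed --out corpus/
dhsnet train --genome fixture/genome.fa --manifest corpus/manifest.tsv \
    --interval-width 100 --iterations 8 --seed 0 --out model.npz
dhsnet evaluate --checkpoint model.npz --genome fixture/genome.fa \
    --manifest corpus/manifest.tsv --out report.json
```

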