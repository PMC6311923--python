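# Methods

`dhsnet` classifies variable-length DNA fragments (200–800 bp) as DNase I
hypersensitive sites (DHSs) or background. This note documents the model,
the data-construction procedure, the training schedule, the synthetic
corpora the tests run on, and the numerical and design choices that were
genuinely open.

## Problem setting

DHSs are nucleosome-depleted, regulatory-factor-accessible regions; their
genomic footprints vary from a couple hundred to several hundred base
pairs. A fixed-input convolutional classifier must crop or pad fragments,
destroying or diluting sequence information. The model here accepts any
length in a configured range by ending its convolutional stack with a 1-D
spatial pyramid pooling (SPP) head, so a single parameter set serves every
fragment length.

## Model

**Input.** A fragment is one-hot encoded as an n × 4 matrix, column order
A, C, G, T. Ambiguous `N` bases become uniform 0.25 rows, preserving the
row-sum-1 invariant (the real corpora the design targets are essentially
N-free; the policy only matters at assembly gaps).

**Gated convolution.** Every convolution is gated:
`y = conv_lin(x) ⊙ σ(conv_gate(x))`, with two independent kernel/bias
sets per unit (GLU-style). The multiplicative gate lets a unit express
long-range conjunctions of local patterns more readily than a plain
ReLU stack.

**Inception stages.** Five stages of parallel gated-conv branches
concatenated along channels, with stride-2 max pooling after the first
four:

| stage | block | branches | out channels |
|---|---|---|---|
| 1 | A | gated convs, kernels 1/3/5/7 | 32 |
| 2 | A | gated convs, kernels 1/3/5/7 | 48 |
| 3 | B | 1×1, 1×1→3, 1×1→5, pool3→1×1 | 96 |
| 4 | B | 1×1, 1×1→3, 1×1→5, pool3→1×1 | 256 |
| 5 | C | 1×1, 1×1→3, 1×1→3→3, pool3→1×1 | 384 |

Each stage's branches contribute equal channel counts (branch widths
8, 12, 24, 64, 96). Activation throughout is LeakyReLU with divisor 100
(`y = x` for `x ≥ 0`, `x/100` otherwise) — a gentle negative slope chosen
to keep gradients alive through a five-stage stack over a four-letter
alphabet.

**SPP head.** The 384-channel output of stage 5 (length n/16 after four
pools) is partitioned, per channel, into 1, 2 and 4 contiguous parts and
each part averaged, giving 1+2+4 = 7 values per channel — 2688 features —
for *any* input length ≥ 64 bp at the input (4 positions at the head).
Mean pooling is deliberate (image SPP conventionally uses max): averages
of motif-response maps degrade more gracefully when a planted signal sits
anywhere in the fragment. When a level k does not divide the length, part
sizes are ⌈n/k⌉ or ⌊n/k⌋ (never differing by more than 1), larger parts
first.

**Classifier.** Three fully connected layers 2688 → 836 → 376 → 2, each
hidden layer batch-normalized (running-statistics momentum 0.5) and
dropped out at rate 0.3, softmax output, cross-entropy loss.

**Parameter total.** The default widths give exactly **3,077,382**
trainable parameters (convolution kernels and biases for both the linear
and gate paths, FC weights and biases, BN scale and shift). The published
total arbitrated among candidate branch/FC widths: the block structure was
fixed first, then integer widths were searched for an exact match, and the
monotone-channel solution with the lowest mid-stage FLOPs was frozen.
`count_parameters` is the conformance oracle for this choice.

**Dropout placement.** The architecture description could be read as
placing dropout after every layer. Applied to all five conv stages plus
both hidden FC layers, 0.3-rate dropout injects so much noise that the
network fits its training batches without ever becoming a usable
evaluation-mode classifier. This package follows the conventional design
(and the lineage of gated-inception nucleosome models): dropout on the
fully connected layers only. The parameter count is unaffected.

**Batch-norm "parameter 0.5".** Interpreted as the running-statistics
momentum (fraction of the current batch statistic mixed in per step). It
is exposed as `bn_parameter` so other readings can be configured.

## Dataset construction

1. **Length filter:** keep DHS intervals with 200 ≤ length ≤ 800 bp
   (inclusive).
2. **Length-matched negatives:** for each positive, draw uniformly at
   random a same-length window on the same chromosome that overlaps no
   known DHS interval and no previously placed negative (mutual
   disjointness prevents trivial near-duplicates; rejection sampling,
   10,000 attempts before a named error). The negative length multiset
   therefore equals the positive multiset exactly — asserted on every
   build.
3. **Redundancy removal:** greedy, longest-first clustering. A sequence is
   dropped when its ungapped best-offset identity (matches / shorter
   length) to an already-kept sequence reaches the threshold (default
   0.9). Candidate offsets come from shared 12-mers, as in word-filtered
   clustering tools; a pair sharing no 12-mer is treated as dissimilar —
   a heuristic that is exact for the near-duplicates the step exists to
   remove and can, in principle, miss diffusely similar pairs.
4. **Folds:** stratified k-fold (default 5), seeded and deterministic.
   Whether metrics should be pooled or fold-averaged is not fixed by the
   method; the evaluation CLI emits both.

Chromosome eligibility ("euchromosomes only") is the caller's
responsibility via the FASTA/BED they supply; no allow-list is hardcoded.

## Multi-scale training

Fragments are assigned to length bins of width 50, 100 or 200 bp tiling
[200, 800]; a fragment of length L goes to the bin with low < L ≤ high
(length exactly 200 joins the first bin). Every fragment — positive or
negative — is extended on its chromosome to the bin's upper bound by
adding flanking genomic sequence left and right; the split is uniformly
random by default (`centered` and enumerated splits available), clamped
inward at chromosome edges, and always contains the original span.
Varying the split amplifies the corpus: `amplification_factor = m`
produces m distinct evenly spaced splits per fragment.

Training cycles bins in ascending target length, one full shuffled epoch
per bin, all bins updating one shared parameter set (dimensionally
guaranteed by the SPP head). One pass over all bins is an **iteration**.
The optimizer is SGD with classical momentum 0.98, initial learning rate
0.002, multiplied by 0.97 after every per-bin epoch, mini-batch 128.
"Momentum with a decay of 0.98" is read as the momentum coefficient; this
implies an effective step of lr/(1−μ) ≈ 0.1, and a global gradient-norm
clip (default 5.0) is applied as a numerical safeguard — without it the
first iterations oscillate. Runs are deterministic given the config seed
(single-threaded; dropout, shuffling and padding splits all draw from the
run RNG).

## Synthetic fixtures

`FixtureSpec` generates uniform-background chromosomes and plants an exact
8-mer motif (default `TGCACGTA`, 16 bits) at a uniformly random internal
offset of each positive interval. Lengths follow a truncated-geometric
decreasing distribution on [200, 800] (mean excess 100 bp → mean ≈ 300
bp), matching the empirical pattern that shorter accessible sites are more
numerous. Defaults: 2 chromosomes × 600 kb, 1,000 positives — sized so
positives (~300 kb) and their length-matched disjoint negatives (~300 kb)
pack into 1.2 Mb with workable rejection-sampling headroom. Exact-match
planting keeps the separability oracle closed-form: a string-matching
baseline achieves AUC ≥ 0.99 by construction, so the learning target
provably exists independent of the network.

What the fixture does *not* emulate: real k-mer composition, degenerate
(PWM-like) motifs, chromatin context, or DNase-seq signal. Passing the
learning tests shows the pipeline and optimizer can recover a planted
sequence signal at desk scale — not that the model attains its published
accuracy on real corpora, which requires the external downloads and
GPU-scale budgets out of scope here.

## Scaled-down learning demonstration

The held-out learning check trains on the default fixture (1,000
positives + 1,000 negatives, 90/10 split), interval width 100,
amplification ×3 (~5,400 training rows) — amplification mirrors the
method's own remedy for its scarcest corpus. Held-out AUC is evaluated
after each iteration with early stopping at 0.95 and a hard cap of 8
iterations (a single CPU-scale budget; convergence is typically at
iteration 3–4). A label-shuffled control trained for 2 iterations stays at
chance (AUC ≈ 0.5). The multi-scale vs single-scale comparison uses a
300-positive fixture with *two* planted motif copies per positive — a
stronger signal chosen so both arms can learn at this reduced corpus size
on one CPU — and 8 iterations per arm, scoring both arms on the same
native-length test bins; it is reported, not gated, matching its
qualitative role.

## Numerical choices and degenerate inputs

- float32 forward/backward; im2col + BLAS matmul convolutions; the input
  gradient of a convolution is computed as a convolution with
  channel-transposed, kernel-flipped weights. All layers are verified
  against central finite differences in float64 (~1e-9 agreement).
- Max pools use floor division; a 200 bp input retains 12 positions at
  the SPP head (minimum 4 required by level 4).
- Thresholded predictions call score ≥ 0.5 positive (ties positive).
- MCC returns 0 when any denominator factor vanishes; Sn/Sp raise a
  named error when their class is absent rather than returning a silent
  default.
- AUC is the trapezoidal ROC integral over all distinct thresholds
  (equivalently the ties-half rank statistic), computed via
  scikit-learn and cross-checked in tests against exhaustive pairwise
  concordance.
- Empty length bins are skipped with a logged warning; fragments outside
  [200, 800] raise at bin assignment.

## Known limitations

- Forward-strand only by default; no reverse-complement augmentation
  (`reverse_complement` is provided for callers who want it).
- The redundancy filter's word heuristic can miss sub-threshold diffuse
  similarity; piping through an external clustering tool is not built in.
- The Inception-B/C internals follow the block grammar above; the printed
  parameter total, not a layer-by-layer table, fixes the widths.
- CPU-only, single-threaded determinism contract; no GPU kernels or mixed
  precision.
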