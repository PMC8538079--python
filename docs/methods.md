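# Methods

## Problem and pipeline

The package grades digitized prostate biopsy specimens. Tissue regions
carry Gleason patterns GP1–GP5 (GP1 stroma, GP2 benign epithelium,
GP3–GP5 increasingly poorly differentiated carcinoma). The slide-level
diagnosis is the ISUP grade group, derived from the two most frequent
epithelial cancer patterns. The pipeline converts an RGB slide into a
per-pixel GP map via patch classification at three pyramid scales and
majority voting, then applies the deterministic grading rules.

## Preprocessing

Each channel is histogram-equalized with the cdf-anchored mapping
`T(v) = round(255·(cdf(v) − cdf_min)/(n − cdf_min))`, which sends the
lowest occupied bin to 0, the highest to 255, and leaves constant
channels unchanged. A luminance-only variant (equalize luma in YCbCr)
is available behind a flag but off by default. Edge enhancement
convolves each channel with the 3×3 sharpen kernel
`[[0,−1,0],[−1,5,−1],[0,−1,0]]`; the kernel sums to 1, so flat regions
are fixed points and no spurious intensity shift is introduced. Borders
use replicate padding so output size equals input size. Ground-truth
masks are never preprocessed.

Note that per-channel equalization is a *per-slide* monotone remap:
the same tissue class can land at different absolute intensities on
slides with different class mixes. Downstream classifiers therefore
cannot rely on absolute color alone; this is intentional and mirrors
stain/exposure variability in real scanners.

## Patching

Patch sides are 100, 150 and 200 px with stride `floor(scale/4)` (25,
37, 50), giving overlap ≥ 75% at every scale (75.33% at 150, where
exact 75% would need a fractional stride). Origins run row-major from
0 in stride steps; the final origin along each axis is snapped to
`H−N` (resp. `W−N`) so the union of windows covers every pixel.
Windows are half-open `[r, r+N) × [c, c+N)` with 0-based coordinates.
Away from borders each pixel is covered by exactly 16 patches per
scale (4 offsets per axis).

## Training-patch selection

For a patch's ground-truth window: RB = fraction of background (0)
pixels; WL = modal label over non-background pixels, ties broken
toward the smaller label; CV = value at `(N/2, N/2)` (0-based, for
even N). The patch is selected iff `WL == CV` and `RB ≤ 0.3`
(inclusive threshold), and its training label is WL. Background never
wins WL, so a background-centered patch can never be selected. An
all-background window has no WL (reported as 0, never selected).

## Architecture

Four blocks of (3×3 conv, stride 1, no padding → 2×2 max-pool, floor
division → dropout), filters 16/32/64/128, dropout 0.1/0.1/0.3/0.3;
flatten; FC 64 → dropout 0.15 → FC 512 → dropout 0.15 → softmax over 5
classes. The spatial recurrence `side → floor((side−2)/2)` yields
final feature sides 4/7/10 for inputs 100/150/200 and trainable
parameter totals 264,421 / 534,757 / 952,549 (no non-trainable
parameters anywhere). Valid convolutions with floor-division pooling
are the unique standard padding/pooling combination that reproduces
all three totals simultaneously, and are therefore fixed. Activations
are ReLU (conv and FC); the output layer is linear with softmax
applied at the loss/prediction boundary. Convolutional dropout sits
after pooling (parameter-neutral either way). Inputs smaller than
46 px per side are rejected — the four valid-conv+pool blocks would
otherwise leave no spatial extent.

The network is a NumPy layer stack: im2col convolutions via
`sliding_window_view` + `tensordot`, explicit backward passes
(verified by numerical gradient checks in development), inverted
dropout, and float32 NHWC tensors throughout. Weights use He
initialization from a seeded generator; eval-mode inference is fully
deterministic.

## Training

Slides are partitioned into train/validation/test *before* patch
generation; the split is by slide id, so no held-out slide contributes
patches to training. Class balancing keeps all GP2–GP5 patches and
subsamples GP1 (without replacement, seeded) to the median count of
the other four classes; GP1 is never oversampled. The loss is softmax
cross-entropy, optimized with Adam (β₁ 0.9, β₂ 0.999). Early stopping
monitors validation accuracy with patience 5; the best-validation
checkpoint is restored. The random-search harness samples learning
rate log-uniformly in [1e-4, 1e-2], batch size from {32, 64, 128} and
a {0.5×, 1×, 1.5×} multiplier on the convolutional dropout schedule,
and returns the trial with the highest validation accuracy.

Defaults: 10 epochs, batch 32, learning rate 1e-3 — enough for the
small-scale CNN to reach ~0.65–0.75 held-out accuracy on the default
synthetic dataset (20 slides of 320×320 px, ≈1,000 balanced patches at
scale 100) in a few minutes on one CPU.

## Inference and fusion

Each patch gets the argmax label of its softmax (argmax ties resolve
to the smallest label). Per scale, a vote field accumulates one vote
per covering patch per pixel; the pixel label is the modal vote, ties
again toward the smallest label — deterministic and biased, when in
doubt, toward the lower-risk pattern. Cross-scale fusion takes the
majority of the three per-scale maps; when all three disagree the
large-scale map wins, since the 200-px network is the most accurate of
the three. (With three voters this reduces to: small-scale label where
small and medium agree, else large-scale label.) Voting assigns every
covered pixel a label in 1–5; background is not a voting outcome, but
a known background mask can be re-imposed afterwards. A probability-sum
fusion (argmax of summed per-scale class probabilities) is available
but off by default; the hard-vote path is the canonical one.

## Grading

The pattern histogram counts pixels with labels 1–5 (0 ignored). Only
cancer patterns {3,4,5} with at least `min_fraction` (default 1%) of
all tissue pixels qualify; the floor exists because without it a
handful of misclassified pixels could become the secondary pattern and
shift the grade group. Setting `min_fraction=0` restores the strict
two-most-frequent reading. Primary = most frequent qualifier,
secondary = next (equal to primary if only one qualifies; frequency
ties toward the smaller pattern). GS = primary + secondary; the
ordered pair maps GG1–GG5 via the standard table ((3,4)→GG2 vs
(4,3)→GG3). A slide with no qualifying cancer pattern is Benign.
Grading depends only on the histogram, never on pixel arrangement.

## Evaluation metrics

All metrics derive from the confusion matrix (rows true, columns
predicted). Per-class values are one-vs-rest: precision, recall,
F1 = 2PR/(P+R), accuracy (TP+TN)/total and NPV = TN/(TN+FN) — the
per-class accuracy and NPV are one-vs-rest by construction, since
row-wise overall accuracies near 0.9 are impossible in a 6-class
setting otherwise. Aggregates: micro (pooled counts; for single-label
data micro-P = micro-R = micro-F1 = overall accuracy, and weighted
recall also equals accuracy), macro (unweighted mean) and weighted
(support-weighted mean). Ratios of the form 0/0 are reported as 0 with
a `RuntimeWarning`.

## Synthetic data

Each slide is a background frame (margin 20 px, near-white) around a
tissue rectangle partitioned into `n_regions` Voronoi cells (default
5 on a 320×320 slide, so regions are large relative to the 100-px
training patches). Cell classes are drawn from the class-weight vector,
default 60% GP1 / 10% each GP2–GP5 — the strong stromal imbalance that
makes class balancing necessary in practice. Rendering gives each class
a hue-distinct base color (different R/G/B channel *orderings*, not
merely brightness levels, so class identity survives the monotone
per-channel equalization of the preprocessing stage) plus darker
elliptical blobs whose density falls from GP3 to GP5 while their size
grows — a cartoon of declining gland density — and Gaussian pixel noise
(σ = 6). Same seed ⇒ bit-identical slide and mask; per-slide seeds are
spawned from the master seed via `SeedSequence`, which is collision-free
by construction.

What the generator emulates: multi-class regions with per-pixel truth,
GP1-dominated class imbalance, a background margin, and per-class
visual signatures learnable by a small CNN (a linear probe on mean
color of pure windows exceeds 0.9 accuracy). What it does not emulate:
gland morphology, nuclei, stain variation between scanners, tissue
tears or pen marks. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that its training loop can learn
separable texture classes — not that the CNNs reach diagnostic
accuracy on real histology, which requires training on a real
annotated cohort at full scale.

## Problem sizes

Desk-scale defaults keep every check on one CPU in minutes: the
learning-sanity run uses 20 slides of 320² px (≈1,000 balanced
patches, 10 epochs); the oracle-classifier end-to-end check uses 10
slides of 1024² px with 3 Voronoi regions each, so that every slide
contains pixels farther than one large-patch side (200 px) from any
region boundary, where fused reconstruction must be exact; voting is
cross-checked against brute force on 50² fixtures at scale 20.

## Known limitations

- The CNN stack is CPU-bound NumPy; it is meant for desk-scale
  experiments, not multi-million-patch training runs.
- Within-scale vote ties and WL ties resolve to the smallest label — a
  deterministic but conservative (risk-lowering) convention.
- The grading module implements primary/secondary rules only; tertiary
  patterns, percent-pattern-4 reporting and intraductal carcinoma are
  out of scope.
- Stain normalization and cross-scanner color standardization are not
  implemented; inputs are assumed comparable to the training domain.
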