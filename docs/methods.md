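# Methods

## Pipeline model and assumptions

The package treats tumor identification in Ki67-stained tissue as binary
tile classification lifted to pixel resolution by window averaging. The
core assumptions are:

- **Class-pure training tiles.** A 64×64 tile drawn completely inside an
  annotated region carries that region's label; tiles straddling a region
  boundary are never sampled. The sampling grid is anchored at the image
  origin with stride = tile size by default, so training tiles are
  disjoint; both anchor and stride are configurable.
- **Frozen features suffice.** The transfer-learning premise: a backbone
  trained elsewhere yields features under which tumor and non-tumor tiles
  are linearly separable, so only a softmax head needs fitting. The
  backbone is an injected contract (`embed(tile) -> R^d`, deterministic,
  fixed d); any network satisfying it plugs in.
- **Window-average smoothing.** A pixel's class probability is the mean of
  the probabilities of every 64×64 window covering it (step 8 → up to 64
  windows per pixel). Accumulation covers the full window footprint — the
  literal reading of per-tile accumulation "in the tile's corresponding
  area" — which smooths boundaries at the scale of the window.

## Numeric primitives

Cross-correlation (valid region), ReLU, max pooling, the dense layer,
softmax (max-shifted for overflow safety), label smoothing and SGD with
momentum are implemented directly and are each verified against
independent brute-force oracles in the test suite. Two deliberate,
documented readings:

- The cross-entropy averages over the **M classes**, not the batch, i.e.
  L = −(1/M) Σ_j ȳ_j log y_j; the batch loss is the mean of per-sample
  losses. This nonstandard 1/M normalization is kept exactly as specified
  by the recipe this package implements; it only rescales gradients.
- Exact probability ties at the 0.5 threshold go to tumor (`tumor_wins`),
  erring toward sensitivity, which is the clinically conservative side.
  With a two-class head the averaged maps are complementary, so the two
  masks always partition the covered field.

## Training recipes

Head training (default, `head_only`): learning rate 0.01, momentum 0.9,
mini-batch 100, 3000 mini-batch steps, 10% seeded validation split, label
smoothing ε = 0.1. The transfer recipe states no learning-rate schedule,
so both exponential decays default to 1.0 (constant); per-epoch decay
factors are available in `TrainingConfig` for the fine-tuning baseline
(`full_finetune`: lr 1e-4 and momentum 0.9, both decayed ×0.9 per epoch,
batch 128, 10 epochs — the batch size filled with a conventional value
where the recipe text omits it). ε is the estimated fraction of mislabeled
tiles; 0.1 is a deliberately conservative default for pathologist-drawn
region boundaries and is config-exposed. "3000 iterations" is read as
3000 mini-batch steps. One epoch is one pass over the shuffled training
split.

The head z-scores incoming features with mean/scale frozen from its
training split (stored in the model file, applied identically at
inference). This is the head's input normalization: backbone feature
channels can differ in scale by orders of magnitude, and a first-order
method with a single learning rate needs comparably scaled inputs to
converge within the fixed step budget. The head itself is initialized at
zero — the problem is convex, so the start point carries no information
and removing it makes training exactly seed-reproducible.

Auxiliary-classifier note: when a backbone exposes auxiliary feature taps,
auxiliary heads would train with the same recipe but only the principal
head drives inference; the built-in backbone has no auxiliary taps, so
this path is not exercised.

## Tile pruning

Outlier elimination runs per class: pairwise Euclidean distances on raw
flattened 8-bit RGB (no normalization — the simplest faithful reading),
classical Torgerson MDS (double-centered −D²/2, top-k eigenpairs, negative
eigenvalues clipped), then a robust radius cut: discard points whose
distance to the component-wise median exceeds median + 3 × 1.4826·MAD.
The target dimensionality (2), the cut constant k = 3 and a 10% removal
cap are design choices where the procedure is otherwise unspecified; the
cap guarantees pruning can never hollow out a class. Above 2,000 tiles
per class the distance matrix is computed on a seeded uniform subsample
(pairwise distances are quadratic in n) and only subsampled tiles can be
discarded.

## Synthetic data: what it emulates, what it does not

`generate_slide` renders rectangular annotated regions on a pale tissue
background: tumor regions as dense jittered-grid fields of larger nuclei
(radius 5 px), non-tumor regions as sparse scatters of smaller nuclei
(radius 3 px), each nucleus brown (DAB-like, base RGB 165/105/60) with the
class's positive fraction (0.4 tumor, 0.15 non-tumor — a plausible
moderately proliferative profile) or blue (hematoxylin-like, 70/80/150).
Annotated tumor area exceeds non-tumor area 14:1 by default, matching the
annotation imbalance the pipeline is designed around; with default
geometry this yields a tile imbalance near 40:1, the same order as the
~14:1 tile imbalance of real annotation sets. Gaussian intensity noise
(sd 8) is truncated at 2.5 sd so that the generator's own brown/blue rule
(R > B + 45) is provably exact: no background or blue pixel can cross it.
Evaluation fields (`generate_hpf`) are 448×448 px, 80% tumor — emulating
the roughly 4:1 tumor:non-tumor pixel imbalance of real test fields.

Reader disagreement is simulated as contiguous ~900-px blobs flipped near
class boundaries (not i.i.d. pixel noise), because real reader differences
concentrate on small ambiguous segments. Per-class flip rates (1.5% tumor,
6% non-tumor) were calibrated once so that two simulated readers' per-class
union agreements land near the reported levels for this task (~96% tumor,
~84% non-tumor).

What the synthetic data does **not** contain: real chromatin texture,
nucleus overlap, stain variation between slides, tissue folds, or
non-rectangular region geometry. Passing tests therefore demonstrate that
the pipeline machinery is correct and that the recipe recovers a signal it
is designed for — not that the classifier would reach the same accuracy on
clinical slides.

## Evaluation semantics

- **C1** (AND): pixels where the readers agree enter the ground truth;
  disagreement pixels are excluded from every count, so C1 and C2 tables
  do not share a total.
- **C2** (OR): "union" is directional for a two-class labelling. Both
  variants exist; the default, reported in every output, is the
  tumor-favouring union (a pixel either reader called tumor is tumor).
- Metrics with zero denominators are reported as undefined, never 0.
  Display percentages round half-up to one decimal; stored values keep
  full precision.
- Class balancing subsamples the majority ground-truth class uniformly
  without replacement down to the minority count (seeded, pooled over the
  evaluation set). An `upsample` mode (minority resampled with replacement
  up to the majority count) is provided because published balanced tables
  sometimes show totals exceeding the raw pixel count, implying
  upsampling.
- ROC: tumor predicted where the averaged map ≥ t; AUC by trapezoid with
  equal-FPR points ordered by TPR.

## Problem sizes

Default synthetic runs use three 1280×1280 slides (two tumor regions,
three non-tumor regions each), a 448×448 HPF, and the full 3000-iteration
head recipe; a complete end-to-end run (generation → training → 2,401
window classifications → scoring) takes well under a minute on one CPU
core. These sizes were chosen as the smallest at which every stage —
including the 14:1 imbalance and the minority class's guaranteed tile
yield (each 135-px non-tumor region necessarily contains at least one
grid-aligned 64×64 square) — operates non-degenerately.

## Known limitations

- The TinyBackbone's random frozen kernels are a capacity floor, not a
  substitute for learned features; on real tissue a pretrained backbone
  satisfying the contract should be injected.
- Whole-slide pyramid formats are out of scope; plain rasters stand in,
  and the pipeline is resolution-agnostic given microns-per-pixel
  metadata (default 0.2437 µm/px, stored as a linear, not areal,
  resolution).
- Region placement is rectangle-based; polygon rasterization itself is
  general (even-odd pixel-center rule, later annotations overwriting
  earlier on overlap).
- Ki67-index computation (brown vs blue positivity calling within tumor
  regions) is deliberately out of scope; the pipeline stops at the
  tumor / non-tumor partition.
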