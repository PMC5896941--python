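# ki67seg

Tumor / non-tumor region identification in Ki67-stained histology images
via transfer-learned tile classification.

## The problem

The Ki67 proliferation index — the fraction of tumor cells staining
Ki67-positive — drives WHO grading of pancreatic neuroendocrine tumors
(NETs). But the Ki67 stain is not tumor-specific: dividing lymphocytes and
stromal cells also stain brown (DAB), and the hematoxylin counterstain
marks non-dividing nuclei of both kinds blue. Before the index can be
counted, tumor regions must be separated from non-tumor tissue. This
package implements a pipeline that learns that separation from pathologist
region annotations and paints tumor / non-tumor probability maps with
decision-boundary overlays onto high-power fields (HPFs), plus the full
evaluation machinery for scoring those maps against two readers' consensus.

It is aimed at digital-pathology researchers who want a small, fully
testable, dependency-light reference implementation of this kind of
pipeline — every stage runs on synthetic data with exactly known ground
truth, so no slide archive is needed.

## The method

1. **Tile sampling.** Annotated regions are grid-sampled (point-counting
   stereology: a lattice of 64×64 squares anchored at the image origin)
   into class-pure tiles; a tile is kept only if every pixel lies inside a
   region of its class. Per class, pairwise Euclidean distances between
   flattened RGB tiles are embedded by classical (Torgerson)
   multidimensional scaling and outliers beyond a robust median + 3·MAD
   radius are discarded (capped at 10%).
2. **Transfer-learned classifier.** A pretrained network acts purely as a
   feature extractor; only a softmax head is trained:

   y_j = f(Σ_i w_ij x_i + b_j),   p_k = e^{z_k} / Σ_j e^{z_j}

   on label-smoothed targets (ε/k and 1 − ε(k−1)/k) with the cross-entropy
   L = −(1/M) Σ_j ȳ_j log y_j, minimized by mini-batch SGD with momentum
   (lr 0.01, momentum 0.9, batch 100, 3000 iterations, 10% validation
   split). The backbone is an injected contract; the built-in
   `TinyBackbone` (two conv-ReLU-maxpool blocks built from the package's
   own cross-correlation/ReLU/pooling primitives, plus global average
   pooling) serves desk-scale runs, and a `full_finetune` mode
   backpropagates into its kernels as the fine-tune-everything baseline.
3. **Segmentation.** A 64×64 window slides over the HPF with step 8; each
   window's class probabilities are accumulated over its footprint in two
   maps while a third map counts passes per pixel. Averaged maps are
   thresholded at 0.5 into binary masks; subtracting each mask's disk-r2
   morphological erosion yields thin decision boundaries, overlaid in red
   (tumor) and green (non-tumor).
4. **Consensus evaluation.** Two readers' corrected masks combine into
   ground truth as C1 (intersection — disagreement pixels excluded) or C2
   (union); predictions are scored with pixel-count confusion matrices
   (sensitivity, specificity, PPV, NPV, overall accuracy), optionally on a
   class-balanced resample, plus ROC curves over the averaged tumor map.
5. **Leave-one-slide-out.** One model per fold; the model used to segment
   any HPF from slide S is the fold that excluded S.

A synthetic-data module generates Ki67-like slides (dense large brown/blue
nuclei in tumor regions, sparse small nuclei elsewhere, ~14:1 tumor :
non-tumor annotated area) with exact ground truth, and simulates reader
disagreement as boundary-localized blob edits.

## Worked example

```sh
ki67seg demo --seed 0 --out demo-run
```

generates a three-slide synthetic cohort, trains the three
leave-one-slide-out heads, segments one 448×448 HPF with the fold model
that never saw its slide, simulates two readers, and prints:

```
{
  "seed": 0,
  "n_tiles": {"tumor": 400, "non_tumor": 11},
  "mean_held_out_tile_accuracy": 1.0,
  "tumor_iou": 0.9852501494917282
}
table              sens%   spec%    ppv%    npv%  overall%
C1_unbalanced       98.7    99.4    99.9    94.6      98.8
C1_balanced         98.7    99.4    99.4    98.7      99.0
C2_unbalanced       95.7    99.4    99.9    83.4      96.4
C2_balanced         95.8    99.4    99.4    95.9      97.6
```

`n_tiles` is the post-pruning tile census (the annotated-area imbalance
makes tumor tiles dominate); `mean_held_out_tile_accuracy` averages each
fold's accuracy on tiles of its held-out slide; `tumor_iou` compares the
thresholded tumor mask with the generator's ground truth; the table rows
score the same mask against the two consensus readings, raw and after
majority-class subsampling. The output directory receives the overlay PNG,
probability-map TIFFs, reader masks, ROC CSV/PNG, per-fold metrics and a
JSON summary embedding the seed and config hash.

The same stages are available as `ki67seg synth | tiles | train | loocv |
segment | evaluate`, and as plain library calls (`ki67seg.pipeline`,
`ki67seg.segmentation`, ...).

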