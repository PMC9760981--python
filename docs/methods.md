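# Methods

`meibseg` implements an automated meibography analysis pipeline: semantic
segmentation of infrared eyelid images into background / eyelid / meibomian
gland (MG), quantification of gland atrophy, and a cross-device evaluation
protocol that measures how a model trained on one acquisition device degrades
on another, with and without histogram-based preprocessing.  Because clinical
meibography sets are not freely available, every stage is exercised on
synthetic phantoms whose geometry, labels and atrophy level are known exactly.

## Synthetic phantoms

A phantom is an elliptical-band eyelid on a dark background, filled with
near-vertical bright stripes standing in for the glands.  All stripes share a
sinusoidal lateral drift ("tortuosity"), which keeps them parallel — the way
healthy glands present — and preserves inter-gland spacing, so gland coverage
of the eyelid is controlled by a single parameter (`gland_width_frac`,
default 0.98: healthy glands tile the lid almost completely, separated by
thin eyelid gaps).

Atrophy is modeled as *distal truncation*: each stripe loses the fraction of
its pixels nearest the lid margin, and truncated pixels revert to the eyelid
label — mirroring clinical gland dropout, where the distal ends disappear
first and bare eyelid shows through.  The truncation fraction is solved
against the realized baseline coverage so that the mask's loss rate,
1 − gland area / eyelid area, equals the requested `atrophy_frac` up to pixel
rounding (at requested rates below the baseline loss of ≈0.02–0.03 — the
thin inter-gland gaps — the baseline is the floor).

Device styles are purely photometric: a monotone 256-entry tone curve,
brightness offset, contrast gain about mid-gray, radial vignette, and
additive Gaussian noise, applied to a fixed rendering (background 35, eyelid
110, glands 185, plus smooth illumination texture).  The two stock styles
("deviceA": bright/high-contrast, "deviceB": dark/compressed/vignetted) give
an average-histogram L1 gap of ≈1.6 on a [0, 2] scale — a strong, systematic
intensity-domain shift.  Styles never touch the mask, so identical geometry
under two styles is a controlled domain-shift pair.

What the phantoms do **not** model: eyelashes, specular reflections,
illumination failures, everted-lid perspective distortion, annotation noise,
or gland-level morphology beyond parallel stripes (no branching, no local
dropout holes).  Results on phantoms therefore demonstrate that the pipeline
is correctly wired and can learn and measure what it claims to measure — not
that any particular accuracy carries over to clinical images.

Reproducibility: each dataset item's seed is a SHA-256 hash of the master
seed and the item counter, so collections are reproducible and independent of
generation order; all seeds stay below 2³¹.

## Preprocessing

**Histogram specification (HS).**  The reference population's per-image
256-bin histograms are normalized and averaged into a template.  An image is
remapped through the LUT `v → min{t : templateCDF(t) ≥ imageCDF(v)}` — the
standard discrete CDF-inversion construction; the LUT is monotone and is
returned explicitly.  A 1e-12 slack in the inversion keeps self-specification
(matching an image to its own histogram) an identity up to quantization.  The
agreement between the output's empirical CDF and the template CDF is bounded
by the coarser of the two histograms' largest single-bin masses; this is the
bound the tests assert.

**CLAHE.**  Tiles of `tile_size` (default 64 px, following the neighborhood
block size conventional in meibography work) are equalized with their
histograms clipped at `clip_limit` × the mean bin height (default 2.0; the
limit is a free choice, as no standard value exists for meibography).
Clipped excess is redistributed uniformly in one pass.  Per-pixel outputs
bilinearly interpolate between the four surrounding tile LUTs; border pixels
clamp to the nearest tile.  A single unclipped tile reduces exactly to global
histogram equalization (`round(255·CDF)`), which is the oracle used in tests.
A constant image is returned unchanged (single-bin equalization is
ill-defined).  Color input is collapsed with luma weights; 16-bit input is
range-rescaled to 8-bit.

## Augmentation

Training images are expanded exactly 12-fold using five transform families:
gamma (0.7, 1.3, 1.6), rotation (−10°, +10°, 180°), Gaussian blur (σ 1, 2),
additive Gaussian noise (σ 5, 10), and flips (horizontal, vertical) — twelve
single-transform variants, with originals kept separately.  Single-transform
variants were chosen over compositions to make the 12× factor auditable; a
recipe that does not total 12 raises a configuration error, since the factor
is a protocol contract.  Geometric transforms are applied to image and mask
together (mask nearest-neighbor, borders filled with background 0);
photometric transforms touch only the image.  The 180° rotation is an exact
index flip so it commutes exactly with label counting.

## Segmentation network

A U-Net-style encoder–decoder, implemented on a small in-house numpy
autograd engine (reverse-mode, with 2-D convolution, max-pooling, bilinear
upsampling, batch norm and channel concatenation as primitives; every
gradient is finite-difference-checked in the test suite).

* **Encoder** — the 34-layer residual design without its classifier: 7×7/2
  stem (BN, ReLU), 3×3/2 max-pool, then four stages of basic residual blocks
  (3, 4, 6, 3; channels 64/128/256/512 at `width_scale` 1), total stride 32.
* **Bottleneck (MSP)** — parallel 3×3 convolutions with dilation rates 1, 2,
  3 (effective receptive fields 3×3, 5×5, 7×7), each ReLU-activated, fused by
  a 1×1 convolution with ReLU.
* **Decoder** — five ×2 bilinear upsampling steps; after each, the matching
  encoder feature map is concatenated (stages 3, 2, 1 and the stem) and two
  conv-BN-ReLU blocks applied; a final 1×1 convolution produces the 3 class
  channels at input resolution.  A per-step ×4 upsampling variant is exposed
  (`decoder_upsample=4`; skips are then attached only where resolutions
  match) but is not the default, because ×4 steps cannot meet the ×2-per-stage
  encoder skips.

Weights are He-initialized from a seeded generator; no pretraining.
`width_scale` multiplies every channel count: 1.0 is the full-capacity
description, 0.25 (≈2.0 M parameters) is the desk-scale setting used in the
tests, where a forward+backward step at 64×64 takes well under a second on
one CPU.  Prediction resizes the input bilinearly to `input_size`, takes the
per-pixel argmax of the three scores, and resizes the label map back with
nearest-neighbor interpolation.

## Training

Loss is multi-class soft Dice: per class c, 1 − (2|y_c ∩ y'_c| + s) /
(|y_c| + |y'_c| + s), averaged over the 3 classes (background included —
the simplest faithful multi-class extension of the single-mask definition),
with smoothing s = 1e-6 so a class absent from both prediction and truth
contributes zero loss.  An L1 penalty on convolution kernels (weight 1e-6 by
default; biases and normalization parameters excluded) discourages
overfitting; it enters the optimizer as a subgradient term.

Optimizer: Adam with β₁ = 0.9, β₂ = 0.999, initial learning rate 3e-4
decayed by ×0.8 every 5 epochs (closed form 3e-4·0.8^⌊e/5⌋, asserted against
the recorded history), batch size 32 and 50 epochs as protocol defaults.
Desk-scale runs pass smaller batch/epoch settings explicitly.  The checkpoint
with the best validation mean DSC (MG and eyelid regions averaged) is
returned, a defensible default where the selection rule is otherwise
unspecified.

Desk-scale study conditions, fixed in advance of any measurement: the
synthetic recovery run trains a `width_scale` 0.25 network on 60 internal-
style phantoms for 20 epochs at 96×96 (96 keeps a gland stripe ≥4 px after
resizing and is divisible by the ×32 encoder stride); the single-image
overfit oracle uses 200 steps at 64×64 with Adam's conventional 1e-3 rate.

## Evaluation

* **Region metrics** — DSC, recall, precision per region (eyelid = label 1
  as annotated, MG = label 2; an eyelid = 1∪2 reading is available as a
  flag).  DSC equals the harmonic mean of precision and recall, checked as
  an identity on random masks.  Images whose truth region is empty make
  recall undefined; they are flagged and excluded from mean ± SD aggregates,
  with the exclusion count reported.
* **MG loss rate** — 1 − #label-2 / #(label-1 ∪ label-2), clamped to [0, 1].
  The union denominator is forced by the rate's [0, 1] range: glands lie
  within the eyelid, and a label-1-only denominator could exceed 1.
* **Meiboscore** — grade 0 iff the rate is exactly 0, then one grade per
  third: (0, 1/3] → 1, (1/3, 2/3] → 2, (2/3, 1] → 3.  Right-closed
  boundaries mirror the clinical "no loss / ≤1/3 / 1/3–2/3 / >2/3" scheme.
* **RMSE** — √mean((predicted − true)²) over a test set's loss-rate pairs.
* **Group comparison** — two-sided Mann–Whitney U.  When the number of group
  assignments C(n+m, n) is ≤ 200 000 the p-value is exact: all assignments
  of the pooled midranks are enumerated and p = min(1, 2·min(P(U ≤ u),
  P(U ≥ u))); otherwise scipy's tie-corrected normal approximation is used.
  Significance threshold p < 0.01.  The samples being compared are treated
  as independent groups (the test itself is unpaired).
* **Domain-gap diagnostic** — images are downscaled to 32×32, flattened,
  embedded in 2-D with t-SNE (PCA initialization, fixed seed, perplexity
  min(30, (n−1)/3)), and the two-device separation is scored with the
  silhouette coefficient: ≈0 when the populations mix, approaching 1 when
  they form separate clusters.

## Cross-device experiment

`run_experiment` generates internal-style train/val/test pools and an
external-style test pool, trains two models — one on raw phantoms, one on
CLAHE-preprocessed phantoms — and scores up to six conditions: internal,
internal+CLAHE, external, external+HS, external+CLAHE, external+HS+CLAHE.
The HS template is built from the internal-style pool (the internal device
plays the guide-image role).  Non-CLAHE conditions are scored by the
raw-trained model and CLAHE conditions by the CLAHE-trained model; the
pairing is configurable because the alternative (scoring everything with the
raw model) is also defensible.  Outputs: per-image metric CSV, per-condition
mean ± SD summary, loss-rate CSV with meiboscores, per-condition RMSE,
pairwise Mann–Whitney comparisons, the average-histogram gap, the t-SNE
separation, and a JSON report recording config, seed and package version.

## Numerical notes and limitations

* float32 weights/activations; Dice-loss softmax uses a detached max-shift
  (exact, since softmax is shift-invariant).
* Batch norm uses batch statistics in training and running averages
  (momentum 0.1) in evaluation; small desk-scale batches make the running
  estimates noisier than large-batch training would.
* CLAHE redistributes clipped excess in a single pass, so bins may end
  marginally above the clip threshold — the standard one-pass variant.
* The Mann–Whitney exact path's two-sided p doubles the smaller tail
  (capped at 1), the convention matched by the brute-force oracle; other
  two-sided definitions exist.
* Training on 1 CPU at `width_scale` 1 and 256×256 is possible but slow;
  all shipped configurations use reduced width and input size, and report
  what those settings achieve on phantoms only.
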