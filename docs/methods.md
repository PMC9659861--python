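# Methods

## The problem

Thymoma typing assigns a whole-slide image (WSI) of a thymic epithelial
tumour to one of eight WHO classes — A, AB, B1, B1+B2, B2, B2+B3, B3, and
thymic carcinoma (TC). Pathologists do this by combining observations made at
several magnifications: architectural context (fibrous septa, perivascular
spaces, medullary differentiated areas) is read at low power, while cellular
detail (epithelial-cell morphology, lymphocyte density, erythrocytes, tumour
fields) needs high power. `mcvit` implements a two-stage pipeline that
mirrors this workflow:

1. **CAST** (cross attentive scale-aware transformer) classifies
   co-registered patch triplets — the same tissue field at 10x (64x64),
   20x (128x128) and 40x (256x256) — into ten pathological-information
   classes, fusing the three scales at every block.
2. **WT** (WSI transformer) encodes a slide as a matrix of m patch rows
   (768-d multi-scale embedding plus one normalised patch-label scalar,
   width 769) and predicts the thymoma type.

## Stage one: CAST

Each branch is a three-stage hierarchical transformer over token grids.
The stems split the 40x / 20x / 10x images into 8x8 / 4x4 / 2x2 patches so
all branches start from the same 32x32 grid with 128 channels; 2x2 patch
merging after stages 1 and 2 gives 16x16x256 and 8x8x512 grids. Per stage the
head counts are (2, 4, 8) and MLP expansion ratios (8, 4, 4), two blocks per
stage.

* **GGB** (global-guided branch, 10x) uses classical pre-norm blocks:
  `x + MSA(LN(x))` then `x + MLP(LN(x))` with GELU.
* **LGB** (local-guided branch, 40x) uses paired window-attention blocks:
  W-MSA on non-overlapping 8x8 windows with a learned relative position bias
  (one scalar per head per relative offset), then the shifted variant
  (cyclic shift by half a window, additive -1e9 masking of pairs that wrapped
  around opposite edges). When the window covers the whole grid — stage 3 at
  the default sizes — the shift is degenerate and disabled.
* **FAB** (feature aggregation branch, 20x) runs the CAS block:
  `C' = SRA(LN(CAM(A, B, C))) + C` then `C = MLP(LN(C')) + C'`, where A, B, C
  are the previous block's outputs from GGB, LGB and FAB. SRA computes keys
  and values from a patch-merged copy of the grid (reduction ratios 8, 4, 2
  per stage, keeping at least a 4x4 key grid); queries stay at full
  resolution.

**CAM** (cross-correlation attention module) builds per-scale spatial
attention from channel inner products. With the three branch features stacked
as G of shape (3, c, h, w): a shared 1x1 convolution gives f1; the fusion
feature C is the correlation target f2; the attention map is
`Att[s, x, y] = sigmoid( sum_ch f1[s, ch, x, y] * f2[ch, x, y] )` — a
per-position (3 x c) @ (c x 1) product, the only reading that produces a
(3, h, w) map. The un-convolved slices of G are reweighted by their maps,
concatenated (3c channels) and re-aggregated by a 3x3 convolution back to c
channels. The inner product is not pre-scaled; with many high-variance
channels the sigmoid can saturate, which the pre-LN placement upstream keeps
in check. A nested-loop oracle (`cam_oracle`) recomputes the same contract
without batched linear algebra and is the module's equivalence check.

Attention scores are scaled by `1/sqrt(head_dim)` (the convention of the
block families CAST builds on); a flag selects a literal `1/head_dim` for
comparison. The classifier head is a global average pool over FAB's stage-3
grid followed by a fully connected layer with softmax over the ten classes.
The slide-stage embedding pools each branch's stage-3 grid (512-d), projects
each to 256-d and concatenates to 768; disabled branches contribute zeros, so
ablations keep the interface width.

Design choices made where the architecture description left room:

* Stages 2–3 use 2x2 patch merging (the printed per-stage grid halving
  requires it).
* The CAM inputs at block i are the outputs of block i-1 (stem outputs for
  the first block).
* The 768-d embedding is composed per branch (GAP 512 -> linear 256, x3).
  This preserves scale provenance and zero-fills cleanly under ablation.
* The embedding is taken pre-classifier-FC.
* Window size 8 (divides all default grids), shift 4.
* Branch toggles reproduce the single- and two-branch ablation variants;
  `use_cam=False` replaces the CAS fusion input with the branch's own feature.

## Stage two: WT

The feature matrix is built by sampling m patches per slide uniformly
(without replacement when enough are available) and appending the patch label
divided by 9 to each embedding row. Width 769 is not divisible by the 12
attention heads, so a 769 -> 768 linear input projection precedes the blocks;
769 is the interface width, the blocks run at the projected width. Learned
absolute position encodings are added (their value on randomly ordered rows
is questionable, so a flag disables them; permutation invariance of the
disabled mode is a tested property), followed by three stages of two
classical blocks (12 heads, MLP ratio 4), a token-wise global average pool
and an 8-way head. At inference the label priors come from CAST predictions;
a teacher-forcing flag substitutes ground truth for controlled experiments.
Embeddings narrower than 768 (reduced-width models) are zero-padded so the
slide-stage interface is width 769 everywhere.

## Training

Both stages minimise multi-class cross-entropy (K = 10 / T = 8) with Adam
(beta1 = 0.9, beta2 = 0.999). The full-scale profile is 160 epochs, batch 64
at learning rate 2e-3 for the patch stage and batch 8 at 1e-3 for the slide
stage; no weight decay, augmentation, warm-up or schedule (a cosine schedule
is available but off by default). Tests and the worked examples run a desk
profile: stage dims (16, 32, 64) on 16/32/64-px triplets, 480 training
patches, at most 30 epochs (the patch stage typically converges in 3–5);
the slide stage uses model width 64, 4 heads, m = 64 tokens, 384 training
slides. Loops are deterministic given their seed; the best-validation
parameters are retained, and checkpoints round-trip bitwise.

The networks are implemented on a small reverse-mode autodiff core written
for this package (float64 NumPy arrays; matmul, reshape/transpose/slicing,
padding, cyclic rolls, softmax/sigmoid/GELU/logsumexp). Analytic gradients
are verified against central finite differences down to 1e-4 relative error
through a full transformer block.

## Synthetic data generator

Real slides for this task are not publicly deposited, so the generator
produces data with exactly the statistical structure the architecture
assumes, and nothing more.

* **Co-registration.** One 40x scene is rendered and the 20x / 10x views are
  its exact 2x2 and 4x4 area averages (same field of view). Area averaging
  conserves mean intensity to 1e-6, a tested invariant.
* **Ten classes from two signal families.** Coarse layout classes carry
  low-frequency structure that survives downsampling: faint diagonal bands
  (fibrous septa), a faint ring (perivascular space), large bright blobs
  (medullary areas). Fine-texture classes live on a 4-px block lattice
  aligned with the 4x4 averaging: spot-density/size grades for the four
  epithelial classes, red or dark specks for erythrocyte/lymphocyte, a dense
  dark field for tumour.
* **A pair separable only at low power.** Fibrous septa and perivascular
  space share one mid-tone base and one clutter distribution — strong ±
  speckle placed as balanced pairs inside each aligned 4x4 block, so every
  block sums to zero and the 10x view erases the clutter exactly — and differ
  only in faint zero-mean coarse structure. At 40x the structure is buried
  in clutter (a fixed-budget logistic regression on raw pixels sits near
  chance); at 10x it is clean and the same classifier separates the pair
  essentially perfectly. The tested invariant asks for at least a
  15-percentage-point gap.
* **A pair separable only at high power.** The B2 and B3 epithelial classes
  place the same amount of ink per 4x4 block (four scattered 1-px spots vs
  one 2x2 spot), so their 10x block means are identical by construction and
  only the 40x texture distinguishes them (same 15-pp-gap check, reversed).
* **Slide bags.** A slide's type selects a row of an 8x10 row-stochastic
  composition matrix encoding the qualitative class-type associations
  (type A concentrated on spindle cells and tumour; B1 on B1 epithelium,
  lymphocytes and medullary areas; TC on tumour; mixed types are averages of
  their component rows). The per-slide composition is Dirichlet-distributed
  around that row with concentration 500 — slides of a type are consistent
  but not identical; at much lower concentrations adjacent mixed types
  overlap and even an oracle classifier on exact compositions cannot separate
  the eight types, defeating the generator's purpose. Patch labels are i.i.d.
  draws from the composition; the default budget is 3,000 patches per slide
  (configurable; tests render 8–64-px scenes and desk-scale counts).
* **Embedding stand-in.** `synthetic_patch_embeddings` emulates trained
  patch-classifier embeddings (signal 1.0 on the label coordinate, Gaussian
  noise 0.1 elsewhere) so the slide stage can be exercised and tested without
  first training a patch model; the CLI path (`train-cast` -> `embed` ->
  `train-wt`) uses real CAST embeddings.

What the generator does **not** emulate: H&E stain variation and
deconvolution, scanner artifacts and defocus, tissue-boundary/background
patches, pyramidal file formats, spatial correlation between neighbouring
patches of one slide, and annotation noise. Passing tests therefore
demonstrate that the architecture, fusion module, losses and training loops
are implemented correctly and that the pipeline learns the designed
multi-scale structure — not that the published accuracy on real slides is
reproduced. The published headline numbers (patch Top-1 0.939, slide Top-1
0.951) come from a private 323-WSI dataset and are out of reach at desk
scale by design.

## Evaluation statistics

Macro recall/precision/F1; Top-1 accuracy (confusion-matrix trace over
total); MAcc defined as the mean of per-class one-vs-rest accuracies (the
term is used ambiguously in the field, so the definition is fixed here);
one-vs-rest ROC/AUC with midrank tie handling (tested against the
Mann-Whitney identity `AUC = U / (n_pos * n_neg)`); Wilson score intervals
for sensitivity/specificity; and two-sided McNemar tests on discordant
counts, using the continuity-corrected statistic
`max(|b - c| - 1, 0)^2 / (b + c)` — clamped so b = c yields statistic 0 with
p = 1 — with the asymptotic chi-square(1) upper tail. The clamped form is the
only one consistent with a tied row printing statistic 0.000 and
significance 1.00000. Undefined cases (b + c = 0) are flagged rather than
given a number. Reference sensitivity/specificity interval methods for the
original study are not recoverable (per-class n unpublished), so confidence
intervals are reported but not validated against printed ones.

## Numerical choices and degenerate inputs

* float64 throughout; attention softmax is max-shifted; cross-entropy clamps
  probabilities at 1e-12; the training loss uses the logsumexp form.
* Argmax tie-breaks take the lowest index (both stages).
* Non-finite attention inputs are rejected; window sizes, reduction ratios
  and patch sizes must divide their grids, with errors naming the fix.
* A class never predicted contributes precision 0; a class absent from the
  truth set has no AUC and is reported as missing.
* PNG patches are 8-bit: pixel round trips are exact to 1/255. All manifest
  and prediction files are plain CSV with fixed, validated columns; split
  assignment is slide-level and leakage (a slide in two splits) is rejected
  at read time.

## Known limitations

* CPU-only and desk-scale: the full-size configuration (62M parameters) runs
  forward in seconds but is not practical to train in this implementation;
  the desk profile is the supported training regime.
* No dropout/augmentation/regularisation beyond early stopping on
  validation accuracy, matching the stated training recipe.
* The CAM sigmoid is unscaled; very wide unnormalised inputs can saturate it.
* Synthetic realism limits are listed above; conclusions about real WSIs
  require real data.
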