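# Methods

## Problem setting

Enhancers are distal cis-regulatory elements, typically 50–1500 bp long.
Reporter assays such as STARR-seq give direct but coarse activity readouts:
peaks mark *regions* containing an enhancer without resolving its
boundaries. `encore` treats enhancer discovery as weakly supervised object
detection in one dimension: a classifier decides whether a 4 kb window
contains an enhancer, and a class-activation-mapping stage localises the
evidence inside positive windows at 10 bp resolution.

## Input representation

All coordinates are BED-convention (0-based, half-open). A window of 4000 bp
is represented as a 5 × 400 matrix: five assay rows × 400 bins of 10 bp,
each entry the arithmetic mean of base-resolution signal in the bin.
Uncovered bases read as 0 (coverage semantics), so matrices are always
finite. A base at position *p* belongs to bin ⌊(p − start)/10⌋; the midpoint
of [s, e) is ⌊(s + e)/2⌋. Chromatin accessibility occupies the middle row so
that full-height convolution kernels always see it flanked by histone
marks; the histone row order is configurable and carries no meaning beyond
bookkeeping. No cross-assay normalisation is applied — signals are used as
given, and the classifier is expected to learn scale differences.

Sliding-window scans use 4 kb windows at a 500 bp stride; windows that
would extend past a chromosome end are dropped rather than clipped, keeping
the matrix shape invariant.

## Training labels

Positives are STARR-seq peaks that overlap (≥1 shared base) at least one
chromatin-accessibility peak *and* at least one peak of an active histone
enhancer mark. Each positive is extended to 4 kb around its midpoint,
shifting minimally inward at chromosome boundaries so no positive is lost.
Negatives are 4 kb windows drawn uniformly (seeded, without replacement of
start positions) from the background — the genome minus all positive
windows and minus every supplied peak set — at 10 per positive. The 1:10
ratio is exact by construction.

## Classifier

Architecture (defaults; all sizes configurable):

| stage | layers | output |
|---|---|---|
| input | 5 × 400 matrix, 1 channel | 1 × 5 × 400 |
| 2D stage | conv1: 32 filters, 5 × 10, same padding; max-pool 1 × 4; conv2: 32 filters, 5 × 10, valid in height | 32 × 1 × 100 |
| 1D stage | conv3…conv7: 32 filters, 1 × 4, same padding | 32 × 1 × 100 |
| head | max-pool 1 × 4 → flatten → dense 64 → dropout 0.3 → dense 1 → sigmoid | P(enhancer) |

Squeeze-and-excitation blocks (reduction 4) sit between consecutive
convolutional layers: each global-average-pools the channels, passes the
descriptor through a two-layer bottleneck, and rescales the block input by
the sigmoid gate — a learned control on how much of each feature map is
passed on. ReLU follows every convolution; the first convolution keeps
same padding so its activation retains the five assay rows (this is what
makes a 5 × 400 feature-wise attribution map possible), and the second
removes height padding, collapsing to one dimension over the genome
(5 − 5 + 1 = 1).

Design notes on the open choices:

* **Pooling placement.** With "two convolution–pooling sets" as the outer
  structure, the first pool is applied directly after conv1 and the second
  after conv7. Pooling before the ReLU is exact (max and an increasing
  elementwise map commute) and pooling before conv2 cuts the dominant GEMM
  cost ~4×; both pools are width-only, so the assay axis is never pooled.
* **Filter counts** default to 32 per layer; **dropout** 0.3 after the
  first dense layer; **dense width** 64. None of these is critical on the
  synthetic data; they are exposed as estimator parameters.
* **Loss** is binary cross-entropy on the logit (numerically stable form),
  with inverse-frequency class weights `w_c = N/(2·N_c)` so each class
  contributes equal total weight despite the 1:10 imbalance.
* **Optimisation**: Adam, learning rate 5·10⁻⁵, batch 64, up to 100 epochs
  (reduced in the synthetic experiments), seeded stratified 80–20
  train/validation split, early stopping when validation loss fails to
  improve for 10 epochs, best weights restored. Validation loss is
  unweighted (the conventional behaviour when class weights apply to
  training only).
* **Determinism**: a single seed drives weight init, the split, epoch
  shuffling and dropout; with fixed BLAS threading, training histories and
  refined BED outputs are bit-reproducible.

The network is implemented directly on numpy (im2col GEMM convolutions with
hand-written backward passes). This is deliberate: Grad-CAM needs exact
gradients of the logit with respect to arbitrary intermediate activations,
and the test suite verifies every parameter and activation gradient against
central finite differences on float64 models. The first convolution is
fused with its max-pool and specialised for the single-channel, full-height
input (a shared width-im2col with row-shifted kernels), which is
mathematically identical to the generic layer and ~3× faster.

## Grad-CAM refinement

For a window with a positive call, each filter *k* of a chosen
convolutional layer gets the importance
`a_k = (1/Z) Σᵢⱼ ∂y/∂A^k_{ij}` — the global-average-pooled gradient of the
positive-class score with respect to its activation map (Z = number of
spatial positions). The map `ReLU(Σ_k a_k A^k)` is then linearly
interpolated to the 400-bin input resolution, aligning the centre of each
(pooled) column with the bins it covers. Gradients are taken on the
pre-sigmoid logit by default (the standard choice; a flag switches to the
post-sigmoid probability, which rescales but does not re-rank bins within
a window).

* **Position-wise score** (length 400): map from the last 1D layer
  (`conv7`), importance of each 10 bp bin.
* **Feature-wise score** (5 × 400): map from the first layer (`conv1`),
  importance of assay × bin; a helper averages these maps over many
  positive windows to give per-assay importance profiles.

Annotation condensation over a genome scan:

1. score all sliding windows; windows with probability strictly > 0.5 are
   positive; merging overlapping/book-ended positive windows gives the
   **original** annotation;
2. compute position-wise maps for every positive window and pool **all**
   their bins into one global mean — the cutoff (filtering therefore only
   happens after the whole scan is processed);
3. per window, keep bins strictly above the cutoff; on the genomic 10 bp
   grid, a bin is kept if *any* covering window keeps it (union rule —
   overlap reconciliation is not otherwise defined);
4. merge adjacent kept bins into the **refined** annotation; each refined
   interval carries the mean Grad-CAM score of its bins (averaged over
   covering windows).

Refined intervals are, by construction, inside the original footprint, on
the 10 bp grid, sorted and non-overlapping; raising the cutoff can only
shrink them.

## Synthetic genomes

The simulator plants non-overlapping enhancer *cores* (lengths uniform in
50–1500 bp) on chromosomes of 500 kb (count auto-sized), then builds five
co-registered base-resolution tracks emulating the canonical active-
enhancer signal architecture:

* **background**: exponentiated Gaussian noise (σ = 0.5 by default)
  smoothed with a 50 bp moving average — non-negative, autocorrelated,
  coverage-like, mean ≈ 1; σ = 0 gives a flat background of 1;
* **accessibility**: background + a Gaussian bump of amplitude 4 centred on
  each core, σ = core length / 4 (truncated at 4σ) — the nucleosome-
  depleted region;
* **histone marks**: background × a multiplicative trough over the core
  (depth 0.6, σ = core length / 2) + two flanking Gaussian peaks of
  amplitude 3 (± a per-mark gain in [0.7, 1.3]) centred 100 bp outside the
  core edges with σ = 60 bp — the +1/−1 nucleosomes carrying the marks,
  hugging the accessible core. An early draft placed these flank peaks
  300 bp out with σ = 120 bp; that detaches the histone signal from the
  core, and since the flanks are genuinely informative of enhancer
  presence, Grad-CAM then (correctly) highlights core *and* flanks. The
  nucleosome-adjacent geometry is both the more realistic rendering and the
  one under which "recover approximately the core" is the right target for
  refinement.

Labelled datasets centre a 4 kb window on each core with a uniform offset
(default ±500 bp; ±800 bp in the shifted-enhancer experiments) and sample
background negatives at 1:10. Ground truth (core intervals, window
placements) is returned for evaluation.

What the simulator does **not** emulate: read-level sampling noise
(fragments, duplicates, mappability), inter-assay scale differences,
promoter or CpG-island signal look-alikes, overlapping or clustered
enhancers, and cell-type mixtures. Passing tests on these genomes
demonstrate that the pipeline's machinery — training, scanning, gradient
attribution, condensation — behaves correctly and localises planted
signal; they do not certify real-data accuracy, which depends on
label quality and signal processing upstream.

## Evaluation

auROC is computed as the Mann–Whitney statistic (ties count ½) and auPRC by
step-wise precision–recall integration (both via scikit-learn; the test
suite checks them against brute-force pair/threshold enumeration).
Cross-validation supports plain k-fold and grouped leave-one-cell-type-out /
leave-one-chromosome-out schemes in which no group ever spans train and
validation; one model is trained per fold. Boundary recovery scores each
ground-truth core by the Jaccard index between the core and the union of
refined intervals overlapping it (unmatched cores score 0); coverage ratio
is total refined bases over total original bases.

## Problem sizes and observed behaviour

The standard synthetic benchmark uses 1,000 positives (11,000 windows);
the classifier converges well before 10 epochs at the default learning
rate, and held-out auROC is essentially 1 at noise σ = 0.5. Boundary
recovery is evaluated at 100 planted cores with ±800 bp window offsets and
σ = 0.1 noise: median per-core Jaccard is ≈ 0.55 and is insensitive to
background noise between σ = 0 and σ = 0.5 — the limiting factors are the
receptive field of the last convolutional layer (~1 kb) and the 40 bp
native resolution of its maps, not the noise. Refined coverage is ~20 % of
the original footprint under these conditions.

## Known limitations

* Localisation resolution is bounded by the last conv layer's receptive
  field and pooled map resolution; very short cores (≲150 bp) are
  systematically over-covered relative to their length.
* The global mean cutoff couples refinement across the whole scan: adding
  windows with weak maps lowers the cutoff and widens refinement elsewhere.
* Tracks are held densely in memory per chromosome (float32); a
  whole-human-genome scan needs ~12 GB for five tracks, so chromosome-wise
  streaming is advisable there.
* The classifier consumes signal as given; if assays are on wildly
  different scales across cell types, transfer requires matched
  processing upstream.
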