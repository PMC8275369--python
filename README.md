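# encore

**Enhancer classification and core-boundary refinement from epigenetic
signal tracks.**

`encore` is a two-stage toolkit for cell-type-specific enhancer discovery
aimed at computational genomicists who have genome-wide signal tracks for
chromatin accessibility (ATAC-seq or DNase-seq) and four active histone
marks (H3K27ac, H3K4me3, H3K4me1, H3K9ac), plus — for training — enhancer
activity peaks from a massively parallel reporter assay such as STARR-seq.

1. **Binary classification.** Each 4 kb genomic window is summarised as a
   5 × 400 matrix *X* of mean signal per 10 bp bin (five assays × 400 bins,
   accessibility in the middle row). A convolutional network scores
   `P(enhancer) = σ(f(X))`, where `f` stacks seven convolutional layers —
   a 2D stage whose 5 × 10 kernels span all five assays and collapse the
   assay axis, then a 1D stage with 1 × 4 kernels along the genome —
   with squeeze-and-excitation channel gates between layers, max-pooling,
   and two dense layers. Windows with `P > 0.5` are enhancer-positive.
   Training uses STARR-seq-supported positives against a 10× background
   sample, Adam (lr 5·10⁻⁵), class weights `w_c = N / (2 N_c)`, a seeded
   stratified 80–20 split, and early stopping on validation loss.

2. **Weakly supervised boundary detection.** For each positive window,
   gradient-weighted class activation mapping (Grad-CAM) scores every
   10 bp bin: each filter's activation map `A^k` in a chosen layer is
   weighted by the global-average-pooled gradient
   `a_k = (1/Z) Σᵢⱼ ∂y/∂A^k_{ij}` of the positive-class logit, and the map
   `L = ReLU(Σ_k a_k A^k)` is interpolated to input resolution. The map
   from the last 1D layer is a per-bin *position-wise* score; the map from
   the first layer (which still spans the assay rows) is a 5 × 400
   *feature-wise* score. Bins scoring above the global mean over all
   positive windows are merged into *refined* core-enhancer intervals at
   10 bp resolution — typically ~20 % of the footprint of the merged
   positive windows (the *original* annotation).

The network and its backward pass are implemented directly on numpy (the
Grad-CAM stage needs exact gradients of the logit with respect to
intermediate activations); gradients are verified against finite-difference
oracles in the test suite. A synthetic-genome module generates five
co-registered tracks with planted enhancer cores — a unimodal accessibility
peak over the core, peak–trough–peak histone profiles — so the entire
pipeline is testable without external data.

## Worked example

```python
import encore

# a synthetic genome: 5 tracks, 100 planted enhancer cores (50-1500 bp)
cfg = encore.SimConfig(n_positive=100, neg_ratio=10, noise_scale=0.1,
                       center_offset=800, seed=11)
dataset, truth = encore.simulate_dataset(cfg)
tracks, _ = encore.simulate_tracks(cfg)

clf = encore.EnhancerClassifier(max_epochs=14, random_state=11)
clf.fit(dataset.X, dataset.y)

result = encore.scan(clf, tracks, truth.chrom_sizes)   # 4 kb / 500 bp windows
original, refined = encore.condense(result, clf, tracks)

df = encore.boundary_recovery(refined.intervals, truth.intervals)
print(len(result.windows), int(result.positive_mask.sum()))
print(len(original), len(refined.intervals))
print(round(df.attrs["medians"]["jaccard"], 3),
      round(encore.coverage_ratio(refined.intervals, original), 3))
```

Output (one CPU, ~2 minutes):

```
1986 878
28 100
0.524 0.213
```

1,986 sliding windows were scanned and 878 called positive. Because the
positive windows of nearby enhancers overlap, merging them yields only 28
original elements — coarse blocks that bridge several enhancers. Grad-CAM
condenses these into 100 refined core elements (one per planted enhancer)
covering 21 % of the original footprint, with a median per-enhancer
Jaccard of 0.52 against the planted cores: refinement both shrinks the
annotation and splits merged calls, recovering enhancers that sit far from
any window centre.

The same pipeline is scriptable from a shell:

```bash
encore simulate --n-positive 100 --noise 0.1 --seed 11 --out-dir sim/
encore train --data sim/dataset.npz --model-out model.npz --epochs 14 --seed 11
encore scan --model model.npz --tracks sim/H3K4me3.bedgraph \
    sim/H3K9ac.bedgraph sim/accessibility.bedgraph sim/H3K27ac.bedgraph \
    sim/H3K4me1.bedgraph --chrom-sizes sim/chrom.sizes --out-prefix out/npc
encore eval --pred out/npc.windows.tsv --truth sim/truth.bed \
    --refined out/npc.refined.bed --original out/npc.original.bed \
    --report out/report.json
```

Real data enters the same way: peaks as BED, signal as bedGraph or bigWig,
and `encore.call_positive_regions` / `encore.sample_negatives` to build the
training labels from STARR-seq, accessibility and histone peak sets.

## Documentation

`docs/methods.md` describes the model, the training configuration, the
Grad-CAM refinement procedure, what the synthetic genomes do and do not
emulate, and the numerical design choices.
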