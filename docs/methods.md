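# Methods

This note documents the models, procedures and design choices behind
`nodulenet`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, with which
defaults, and what the synthetic experiments do and do not demonstrate.

## Problem setting

Pulmonary nodules — focal lung lesions of roughly 3–30 mm on CT — are the
main imaging precursor of lung cancer. Two tasks matter clinically:
delineating the nodule voxel-by-voxel (segmentation) and deciding whether
it is benign or malignant (classification). `nodulenet` implements a
single 3-D network that performs both jointly over a shared encoder, so
that boundary-level detail and lesion-level semantics inform each other.

## Network

The model is a U-shaped encoder–decoder over 64³ lesion-centered patches
(values in [0, 1] after HU normalization).

**Encoder.** A 3-D adaptation of an 18-layer residual network: a 7³
stride-2 stem with group normalization and ReLU, a 2³ stride-2 max-pool,
then four stages of two basic residual blocks with default widths
(64, 128, 256, 512) producing feature maps at 1/4, 1/8, 1/16 and 1/32 of
the input resolution.

**Decoder.** Three fusion stages, deepest first. Each stage:

1. trilinearly upsamples the deeper map ×2 and reduces channels with a 3³
   convolution;
2. gates the encoder skip through **global semantic attention (GSA)**;
3. fuses by channel concatenation + 3³ convolution;
4. refines with the **multi-scale convolution block (MSConv)**;
5. applies **dual spatial attention (DSA)** — in the two deepest stages
   only.

A head of two (upsample ×2 + conv) steps restores full resolution and a
1³ convolution emits 2-channel segmentation logits.

**Classification branch.** Three streams — encoder stages 3 and 4, and
the early-fusion decoder map (the third fusion, at 1/4 scale, taken after
the fusion convolution and before MSConv) — each pass their own
**channel attention (CA)**, are globally average-pooled, concatenated and
mapped by one hidden fully connected layer to 2 logits (benign /
malignant). The early-fusion tap is the highest-resolution fused map, so
the branch sees both deep semantics and fused boundary-level detail.

### MSConv

Given X with C_in channels, four grouped convolutional branches run in
parallel — kernel sizes 1³, 3³, 5³ and a residual 3³ branch — and their
outputs are summed element-wise:

    Y = Conv_res^(g)(X) + Σ_{k∈{1,3,5}} Conv_k^(g)(X).

All branches share the adaptive group number g, the largest integer with
g ≤ min(⌊C_in/2⌋, C_out) and g | C_out (`group_number`). Inside the
network C_in always equals C_out, where this rule alone suffices; for
arbitrary channel pairs a realizable grouped convolution also needs
g | C_in, so `MSConvSpec.groups` additionally walks down to the largest g
dividing both. The branches use literal kernel sizes with dilation 1; a
`dilation` option provides the alternative multi-branch-dilated reading
(same kernels, dilated receptive fields). "Same" padding (0/1/2 for
k=1/3/5) makes the element-wise sum well-defined.

### Attention blocks

*GSA* controls skip-connection quality. Two parallel bottleneck
projections (1³ conv to C/2 with group-norm + ReLU, 1³ conv back to C,
compression ratio 2) yield two response maps; each passes a sigmoid and
is reduced to a channel descriptor — global *average* pooling for the
first, global *max* pooling for the second. The input is reweighted
channel-wise by both descriptors (multiplicative gating, matching the
"reweight" reading rather than an additive one), then refined by a 3³
conv + group-norm + ReLU. The bottleneck-and-expand shape is the minimal
instantiation that keeps the stated compression ratio while producing
C-dimensional descriptors able to reweight the input.

*DSA* builds two one-channel spatial maps by channel-wise average and max
pooling, convolves each with a 7³ kernel (default; odd, "same" padding),
applies a sigmoid, and sums the two rescaled copies of the input. The
average branch stabilizes the nodule core; the max branch sharpens
boundaries. The sum is the symmetric combination of the two cues.

*CA* is a squeeze-excite gate: global average pool → bottleneck
C/reduction (default reduction 4, floored at 1) with ReLU → expansion →
sigmoid channel weights in (0,1)^C.

### Ablation switches

`NetworkConfig.active_blocks ⊆ {CA, GSA, DSA, MSConv}` wires the ablation
family: the empty set is the plain multi-task baseline, and the
progressive variants (+CA, +CA+GSA, +CA+GSA+DSA, full) only add the named
blocks. `with_classification=False` yields the single-task residual-U-Net
topology. Capacity is strictly monotone along this ladder
(regression-tested), and all variants run the full smoke chain.

## Loss

L_total = L_seg + L_cls with unit task weights; L_seg = L_CE + L_Dice.
L_CE is the voxel-mean cross-entropy over the two classes; L_Dice is the
soft Dice loss on the nodule channel with smoothing constant ε = 1e-5;
L_cls is the batch-mean two-class cross-entropy. CE terms floor
probabilities at 1e-12 before the log (the losses are undefined at p = 0;
the floor only matters for saturated predictions). CE and Dice are
computed per sample and averaged over the batch, matching the per-case
evaluation convention. No dynamic task weighting is applied.

## Preprocessing and augmentation

Volumes are resampled to 1 mm isotropic spacing (output shape per axis =
round(shape·spacing/target); image trilinear, mask nearest-neighbor so it
stays binary), clipped to [-1000, 400] HU and mapped linearly to [0, 1],
and cut into 64³ patches centered on the lesion. Conventions the source
protocol leaves open, fixed here for bit-reproducibility:

* even-size centering — the center voxel lands at index 32;
* out-of-volume padding with 0.0 (= −1000 HU after normalization, i.e. air);
* nearest-neighbor interpolation for masks everywhere.

Four augmentations, each applied with a configured probability under an
explicit per-call seed: axis-aligned 90° rotations (free-angle rotation
would require an interpolation convention the protocol does not fix),
axis flips, elastic deformation (a uniform random field smoothed with a
Gaussian of σ = 6 voxels, scaled to a peak displacement `elastic_alpha`,
shared between image and mask; image trilinear, mask nearest), and
Gaussian intensity noise on the image only (σ = 0.02 on the unit scale),
re-clipped to [0, 1]. Geometric transforms act identically on image and
mask; labels never change.

## Training protocol

SGD with learning rate 0.01 (constant — no schedule), momentum 0.9,
weight decay 1e-4, batch size 4, 200 epochs. Model selection keeps both
the last checkpoint and the best by validation Dice + accuracy. Weights
are Kaiming-initialized from the configuration seed; all shuffling and
augmentation randomness derives from that seed, so a training run is a
pure function of (data, config) on CPU.

## Numerical substrate

The network runs on a small numpy-based neural-network engine inside the
package (`nodulenet.nn`): reverse-mode autograd tensors; grouped/strided/
dilated 3-D convolution implemented as a loop over kernel offsets with
batched BLAS matmuls (exact forward and backward, no im2col copies);
2³ max-pooling; trilinear ×2 upsampling as three dense 1-D interpolation
matrices (half-pixel convention, so its adjoint is exact); group
normalization (batch-independent, hence deterministic at any batch size);
and SGD with momentum. Every operator's backward is exact and is verified
against central finite differences at 1e-5–1e-3 relative tolerance in the
test suite. Float32 is used for parameters and activations; float64 for
oracle comparisons.

## Synthetic phantoms

The phantom generator replaces external CT cohorts so the entire pipeline
trains and evaluates hermetically. Each case is a 72³ volume at 1 mm
isotropic spacing: parenchyma background at −800 HU, additive Gaussian
noise (σ = 40 HU), 2–5 straight cylindrical vessel-like tubes (radius 1–2
voxels) of near-nodule intensity passing close to — but never labeled
into — the nodule, and one star-shaped nodule r(θ,φ) = r0·(1 + a·s(θ,φ)),
where s is a zero-mean, |s| ≤ 1 smooth angular field built from
`spike_count` von-Mises-like bumps. Class-conditional defaults: benign
r0 ∈ [1.5, 6] mm, a ∈ [0, 0.1], intensity ∈ [−100, 0] HU; malignant
r0 ∈ [5, 15] mm, a ∈ [0.15, 0.4], 6–14 spikes, intensity ∈ [0, 100] HU.
These spans cover the 3–30 mm diameter range of screening-relevant
nodules and typical lung-window contrast, and give the malignant class
the classic morphology signal (larger, spiculated, denser). The radius
ranges deliberately overlap at 5–6 mm so size alone is not sufficient —
a classifier must also use spiculation or intensity there. A
foreground-volume threshold alone reaches >80% but not 100% accuracy
(property-tested).

What the phantoms do **not** emulate: lobar anatomy, airways, pleura,
part-solid/ground-glass texture, respiratory or reconstruction artifacts,
scanner heterogeneity, and multi-nodule scans. Passing the synthetic
experiments therefore demonstrates that the architecture, losses and
pipeline are implemented correctly and can learn genuine morphological
signal — not that the model reaches clinical-grade performance on real
CT.

## Evaluation

Seven metrics: Dice 2|A∩B|/(|A|+|B|) and mean IoU (foreground
TP/(TP+FP+FN), averaged over cases — the reading consistent with the
per-case identity IoU = DICE/(2−DICE)) for segmentation; accuracy,
sensitivity, specificity, precision and F1 from the case-level confusion
table (probability threshold 0.5) for classification. Segmentation
predictions are binarized by argmax over the 2-channel softmax. Ratios
with zero denominators are reported as absent, never as 0; Dice of two
empty masks is defined as 1.0 (degenerate phantoms can produce it).
Reports aggregate per-case values as mean ± sample standard deviation
(ddof = 1; a single case reports 0.00) in percent with two decimals,
optionally stratified by a grouping column such as an acquisition center.

## Desk-scale experiments

Three reference experiments (`nodulenet.experiments`) define the
package's CPU-scale study conditions; the acceptance script and test
suite run exactly these:

* **Overfit probe** — 8 fixed phantom patches, no augmentation, reduced
  widths (8, 16, 32, 64), 32³ patches, at most 150 SGD steps with early
  stopping once training Dice ≥ 0.8 and training accuracy is 1.0.
  Verifies capacity and end-to-end gradient flow.
* **Generalization** — a 40-phantom cohort, seeded 8:1:1
  train/val/test split, 700 steps with augmentation, best-validation
  checkpoint, scored on the held-out cases. Elastic deformation is
  enabled here (p = 0.5, peak displacement 3 voxels) deliberately: it
  perturbs apparent nodule volume, which discourages the network from
  collapsing onto a pure size shortcut and pushes it toward the
  spiculation/intensity cues that disambiguate the 5–6 mm overlap zone.
* **Reproducibility** — the full phantom → train → predict → evaluate
  chain run twice with one seed must produce byte-identical metric CSVs;
  everything downstream of the seed is deterministic on CPU.

The reduced problem sizes (widths, 32³ patches, step caps) are the
package's chosen desk-scale conditions: each experiment completes in
minutes on one CPU core while exercising every component at full fidelity.

## Known limitations

* The full-width (64–512 channel) configuration is practical for forward
  passes and short fine-tuning on CPU, not for 200-epoch training; the
  protocol's full training schedule assumes accelerator hardware.
* Single nodule per case; one center per manifest row.
* NIfTI only; DICOM ingestion is out of scope.
* No ROC/AUC or surface-distance metrics; the seven-metric panel is the
  fixed reporting surface.
* Free-angle rotation and GradNorm-style dynamic loss balancing are
  intentionally not implemented.
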