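# Methods

## Problem

Multi-class segmentation of abdominal slices into background, muscle,
subcutaneous adipose tissue (SAT) and visceral adipose tissue (VAT), in the
common situation where most training labels are *weak* — produced by an
imperfect automated segmenter — and only a small set is *strong* (trusted).
The goal is not only to train a segmenter but to **improve the weak label
maps themselves**, so they can be reused downstream.

The two dominant weak-label failure modes modeled here:

1. whole muscle connected components are missed (small, isolated components
   far more often than the main muscle wall);
2. the innermost strip of the subcutaneous band is mislabeled as visceral
   fat.

## Model

A dual-branch convolutional network with one shared encoder and two
architecturally identical decoders:

* **Encoder** — a 3×3 stem, then `depth` stages of (residual block →
  stride-2 downsampling convolution, channel doubling), then a bottleneck
  residual block. Every convolution except the 1×1 output heads is followed
  by instance normalization (per-sample, per-channel, no running
  statistics) and ReLU.
* **Decoders** — mirror-image upsampling paths: `depth` stages of bilinear
  2× upsampling (nearest-neighbour 2× followed by a fixed separable
  [¼, ½, ¼] smoothing, with exact adjoint in the backward pass) and a 3×3
  normalized convolution halving the channels, a 3×3 refinement
  convolution, and a 1×1 per-pixel class head with channel softmax.
  Skip connections from matching-resolution encoder activations are
  available as an option (`build_model(..., skips=True)`) and are **off by
  default**, so by default every feature a decoder sees passes through the
  encoder bottleneck.
* The **strong decoder** is supervised by trusted labels, the **weak
  decoder** by weak labels. Both decoders are built from the same
  hyperparameters with independently seeded weights.

The network runs on a small in-package reverse-mode automatic
differentiation engine over numpy arrays (`labelrefine.nn`): channel-last
layout, convolution as one matmul per kernel tap, and an Adam optimizer
that skips frozen parameters. No deep-learning framework is required.

## Training

Two phases, fully seeded and single-threaded deterministic:

1. **Self-supervised warm-up** (`pretrain`): encoder and both decoders are
   trained on the weak labels alone with the generalized Dice loss, giving
   the shared encoder a usable representation without any strong labels.
2. **Encoder-frozen fine-tuning** (`finetune`): the encoder is frozen
   (checksum-asserted bit-identical after every epoch; since it is then a
   fixed function, its features are computed once per sample and cached)
   and the decoders are trained jointly with three terms:
   * supervised generalized Dice — strong labels → strong decoder, weak
     labels → weak decoder;
   * cross-decoder consistency — symmetric mean squared difference between
     the two decoders' probability maps on weak inputs;
   * confidence — mean per-pixel Shannon entropy of the strong branch,
     normalized by ln C.

   Default weights are (1, 0.1, 0.1); the consistency and confidence
   weights ramp linearly from 0 over the first 10 fine-tune epochs. Every
   `replace_interval` epochs each weak label map is **replaced** by the
   strong decoder's argmax prediction (lowest index wins ties), so the weak
   set improves as training proceeds. Strong samples are never modified,
   and refined labels always keep weak provenance.

### Loss definitions

Generalized Dice loss per sample:
`L = 1 − 2 (Σ_c w_c Σ_i p_ci g_ci) / (Σ_c w_c Σ_i (p_ci + g_ci))` with
`w_c = 1 / (Σ_i g_ci)²`; classes absent from the target get weight 0, which
keeps the loss finite. Batches average per-sample losses. The trainer uses
analytic gradients for all three terms; these are verified against central
finite differences in the test suite.

## Synthetic data

Real abdominal CT with body-composition annotations is not publicly
redistributable, so the pipeline is exercised on seeded geometric phantoms
(`generate_phantom`): a concentric "abdomen" — background / thick SAT band
/ muscle ring / VAT interior — plus 3–4 isolated muscle patches inside the
interior (the analogue of pelvis muscle). The image is a per-class mean
intensity (0.05 / 0.60 / 0.25 / 0.38) plus a smooth two-mode cosine bias
field (±0.04) and Gaussian noise (σ = 0.03), clipped to [0, 1]. Geometry is
randomized per seed; generation fails loudly if any foreground class falls
outside 1–60 % of pixels.

`corrupt_labels` produces weak labels from truth with three seeded,
composable operators, applied in order: (1) deletion of a fraction of
muscle connected components, drawn without replacement with weights biased
toward small components and nested across fractions (monotone:
a larger fraction deletes a superset); (2) relabeling of the innermost
`sat_to_vat_band` pixels of the SAT band as VAT; (3) optional per-class
morphological boundary jitter. The generator and corruption defaults are
fixed study conditions, calibrated a priori so that initial weak-label DSC
lands near the mid-70s (muscle), high-80s (SAT) and low-70s (VAT).

**Scope**: phantoms are 2-D, single-channel, 4-class, ≥ 32×32 (and
divisible by 2^depth for the network). They exercise the *structure* of the
label-refinement problem, not the intensity statistics of real CT.

## Evaluation

Per class: IoU, DSC and relative volume difference (RVD), in percent, with
explicit empty-class conventions (both empty → 100/100/0; truth empty but
prediction not → 0/0/undefined, the undefined RVD excluded from
aggregation). Sets are aggregated per-slice as mean ± sample SD (ddof = 1).
The identity DSC = 2·IoU/(1+IoU) holds exactly; both metrics and the
generalized Dice loss are tested against brute-force counting oracles at
1e-9.

## Numerical choices

* Network parameters default to float32 (CPU speed); losses and their
  gradients are computed in float64. Gradient correctness is verified with
  a float64 build of the full network.
* All randomness flows through `numpy.random.default_rng` with explicitly
  derived seeds (`SeedSequence([seed, phase])`); identical seeds give
  bit-identical histories and label revisions in single-threaded runs.
* At import, the package raises glibc's mmap/trim thresholds (best-effort,
  via `mallopt`) so the allocator recycles the multi-megabyte temporaries
  training allocates each step instead of returning them to the kernel;
  this is purely a performance measure and does not change numerics.

## Limitations

* Phantoms are geometric stand-ins; no claim is made about accuracy on real
  CT, and the corruption model covers only the two failure modes above.
* The default (skip-free) decoder reconstructs boundaries from the encoder
  bottleneck and plateaus around 98–99 % DSC on this data even with ample
  width; runs that must preserve near-perfect labels (e.g. the identity
  robustness check) use the skip-enabled variant.
* 2-D slices only; no 3-D context, no DICOM, no multi-channel inputs.
* The iterative replacement schedule trusts the strong decoder after a
  10-epoch ramp; with extremely few or unrepresentative strong samples the
  pseudo-labels can still drift.
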