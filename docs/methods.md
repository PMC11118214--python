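# Methods

This note records what the package models, the defaults that matter, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Model

The architecture couples a small trainable agent segmentation network with
a frozen promptable foundation pair (image encoder + mask decoder).  For an
input image `I` (3×S×S, integers 0–255 normalised to [0,1] at model entry):

1. **Dual-path encoding.** The frozen encoder produces an embedding
   `f_SAM` of shape `sam_dim × S/16 × S/16`; the agent encoder produces
   `f_Agent` of shape `agent_dim × S/8 × S/8`.  Agent variants: a
   ResNet-50-shaped trunk with the last two stages dilated (output stride
   8) for the `fcn` variant, the same trunk plus an atrous pyramid (rates
   6/12/18) for `deeplab`, and a 4-block strided conv net (`tiny`) for
   CPU-scale training.  All normalisation is group/layer based, never batch
   based, so forward passes are independent of batch composition and
   bit-reproducible.
2. **Fusion (confusion module).** `f_SAM` is mapped by a 3×3 conv to
   `agent_dim` channels, bilinearly resized to the agent grid, concatenated
   with `f_Agent`, and squeezed back to `agent_dim` by a 1×1 conv.
3. **Agent decoding.** Two convolutions reduce the fused feature to
   `n_classes+1` channels (background is channel 0), followed by bilinear
   upsampling to S×S and a channel softmax.
4. **Prompt generation.** Both prompt paths share the layout: average
   pooling (factor 2), seven FACM blocks (first three stride 2, then four
   stride 1; only the first runs with stochastic augmentation ON), and a
   final 1×1 conv — a total spatial reduction of 1/16.  The sparse path
   consumes the agent's predicted mask and emits one `prompt_dim` token per
   class channel (spatial mean, then reshape); the dense path consumes the
   fused feature and keeps the spatial grid of the embedding.  The dense
   path compresses channels with a 1×1 conv *before* the bilinear resize to
   full resolution; because a 1×1 conv is a per-pixel linear map and
   bilinear resampling mixes pixels linearly, the two operations commute
   exactly, and compressing first avoids materialising an
   `agent_dim × S × S` tensor at full scale.
5. **Frozen decoding and mask fusion.** The frozen decoder adds the dense
   prompt to the embedding, runs two two-way cross-attention blocks between
   sparse tokens and image tokens, upscales by two transposed convolutions,
   and classifies each pixel with per-token linear heads (a hypernetwork),
   ending in a channel softmax.  The final prediction is the per-pixel,
   per-channel convex combination
   `Mask_pred = (1−α)·Mask_SAM + α·Mask_agent`, applied to probability
   maps (post-softmax) so the convex-combination semantics is literal and
   rows still sum to 1.
6. **Loss.** `L_all = L_Agent + L_pred`, both soft Dice
   (`1 − mean_channels (2Σpg+ε)/(Σp+Σg+ε)`, ε = 1e-6) against the same
   annotation.  Gradients flow through the frozen decoder into the prompt
   paths; frozen parameters are never updated (verified by checksum).

### FACM

A FACM block is a 3×3 convolution `c` plus a stochastic linear suppression
applied only during training when its status is ON: with probability
`p_zero` (default 0.05) the output is `0·c`; otherwise with probability
`p_activate − p_zero` (default 0.5 − 0.05) it is `α·c + β` with
`α ~ U(0.25, 1.0)` (mean 0.625) and `β ~ U(−10, 10)`; otherwise `c`.  OFF —
and ON at inference — is exactly the bare convolution.  The printed
formulation of the module admits a reading in which both states add a
second copy of the convolution; that would make the OFF state twice a
single conv, contradicting the accompanying description of OFF as
"a standard 3×3 convolutional block", so this implementation uses the
single-conv reading.  Note that `β` is an absolute offset: at mini scale,
where feature maps are O(1), the default range perturbs features much more
strongly (relative to signal) than at full scale, and the measured mini-
scale effect of FACM on final Dice is correspondingly neutral-to-slightly
negative; the defaults are nevertheless kept, and every range/probability
is exposed in `FacmConfig`.

## Scale profiles

| quantity | full | mini |
|---|---|---|
| input side S | 256 | 64 |
| foundation embedding | 256 × 16 × 16 | 16 × 4 × 4 |
| agent feature | 2048 × 32 × 32 | 32 × 8 × 8 |
| prompt dim | 256 | 16 |
| prompt-path hidden width | 64 | 16 |

The full profile reproduces the printed architecture dimensions (ViT-b
shape: 16×16 patchify, 12 transformer layers of width 768 with 12 heads,
neck to 256 channels; ResNet-50-shaped agent trunk before global pooling).
The prompt-path hidden width is not fixed by the architecture description;
the defaults above were chosen once for CPU feasibility.  The final sparse
1×1 conv emits `(n_classes+1) × prompt_dim` channels; a token per class
plus background keeps the token count independent of image resolution.

## Training protocol

Defaults follow the reference protocol: the few-shot training set is
replicated to 512 augmented draws (random central rotations of ±10°,
bilinear for images, nearest-neighbour for masks, background fill);
50 epochs, batch size 8, AdamW (weight decay 0.01) at 1e-4 decaying to
1e-5 from epoch 26; Dice loss; best epoch selected by validation mean
foreground Dice.  The fusion weight default is α = 0.25 (the strong
setting in the fusion-weight sweep; 0.1/0.3/0.5 are common alternatives
and exposed as a sweep command).  Mini-scale tests and the packaged
demo shrink the *budget* (replicate 8–32, epochs 2–8, batch 4, lr 1e-3),
never the protocol structure; the sizes used are stated in each
experiment's configuration.

## Surrogate foundation pair

Real pre-trained checkpoints are an optional external adapter (documented,
unimplemented I/O).  The shipped surrogate gives the frozen pair genuine
prompt-decoding skill at toy scale: it is pre-trained for a configurable
number of steps (200 in the packaged experiments) on auto-generated
phantoms using *oracle prompts* rendered from ground-truth masks — sparse
tokens from fixed random projections of per-class area/centroid statistics,
dense prompts from the pooled one-hot mask — and then frozen.  Three
choices make this short pre-training converge reliably rather than
occasionally collapsing to the background class:

- batch size 8 at learning rate 3e-3 (gradient noise small enough to
  escape the all-background basin within 200 steps);
- in 30 % of steps the oracle prompts are perturbed with unit Gaussian
  noise, mirroring how promptable segmenters are trained with imperfect
  prompts, so decoding degrades gracefully under the initially
  off-distribution learned prompts;
- the decoder's residual branches (attention output projections, MLP
  second layers) are zero-initialised, making each two-way block the
  identity at initialisation and preserving the class identity carried by
  the prompt tokens at the start of training.

## Synthetic phantoms

The generator emulates the *topology and class statistics* of the two
target domains, not their imaging physics.  Cardiac: two confocal rotated
ellipses (blood pool = class 1 inside; the ring between them = class 2)
plus a disjoint atrial-wall ellipse (class 3), grayscale template with
multiplicative Rayleigh-like speckle normalised to unit mean.  Fundus: a
bright optic disc (class 1) with a strictly nested cup (class 2), radial
vignette, additive Gaussian noise, warm colour cast.  Jitter defaults
(position ±2 % of the side, scale ±8 %, rotation ±10°) were chosen once as
moderate anatomical variability.  Every phantom is a pure function of
(spec, seed, index).  Consequences for interpretation: passing tests show
the pipeline's mechanics (fusion, prompting, frozen decoding, few-shot
advantage) under controlled geometry; they do not show robustness to real
speckle statistics, shadowing, probe variation, or pathology.

## Evaluation

Dice `2|P∩G|/(|P|+|G|)` (both-empty = 1); Hausdorff distance between
boundary pixel sets (mask minus its erosion) under the Euclidean metric,
reported in pixels; exactly one empty side yields the image diagonal and a
degeneracy flag (tables stay total); sensitivity/specificity at the argmax
label (ties break to the lowest class index); AUC/AUPR by rank integration
of the class-probability channel; classes absent from the ground truth
yield missing values excluded from means; background is excluded from
foreground-mean rows.  Method comparisons use a paired two-sided t-test on
per-image differences (the same test images score both methods), with
significance marks at 0.05/0.01/0.001 and explicit handling of the two
degenerate cases (all differences zero → p = 1; constant nonzero
difference → flagged, p → 0).

## Numerical choices

- All tensors float32; the autodiff core is single-threaded numpy, so runs
  are bit-reproducible on a fixed machine.
- Convolution by im2col + matmul; bilinear resampling as two 1-D
  interpolation matrices (the adjoint is exactly their transpose);
  transposed conv as zero-stuffing + flipped-kernel conv.
- Every stochastic draw (phantom, augmentation, FACM, batch order,
  initialisation) is a pure function of an explicit integer seed tuple.
- Degenerate inputs: empty manifests, out-of-range few-shot sizes, MD
  without FE, and channel-count violations raise immediately; non-finite
  training losses abort with a diagnostic rather than continuing.

## Known limitations

- The surrogate foundation pair is a toy: conclusions about real
  pre-trained checkpoints require the external adapter and real weights.
- The full-scale profile is exercised forward-only in tests; training at
  256 px on CPU is possible but slow.
- FACM's absolute β range interacts with feature scale (above); at mini
  scale its measured contribution is within noise.
- Hausdorff distances are in pixels; no physical spacing is applied.
- The mask decoder emits a joint (n+1)-channel map; a per-token mask
  formulation (one binary mask per prompt) is a plausible alternative
  reading of the architecture and was not implemented.
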