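# Methods

## Problem and model

Peripheral-blood smears photographed under a microscope present two coupled
nuisances for leukocyte segmentation: the illumination across the field of
view is uneven, and the leukocytes — the darker, more saturated minority
population after Wright staining — sit among far more numerous pale cells
(erythrocytes, debris) of similar geometry. `wbcseg` implements a two-stage
pipeline: an adaptive retinex correction that removes the illumination
nuisance and sharpens the colour separation between leukocytes and
distractors, followed by an encoder-decoder network that classifies every
pixel.

### Retinex core

Retinex theory models the observed image as S(x, y) = R(x, y) · L(x, y),
reflectance times illumination. In the log domain, s = r + l, and the
reflectance is recovered by subtracting a Gaussian-surround estimate of the
illumination:

    r_σ = log(S + ε) − log(G_σ ∗ S + ε)

Single-scale retinex (SSR) uses one σ; multi-scale retinex (MSR) averages
several (default σ ∈ {15, 80, 250} px with equal weights, the classic
choice; small scales compress dynamic range and flatten illumination, large
scales preserve colour fidelity). MSRCR adds a colour-recovery gain per
channel i,

    c_i = α · log(β · S_i / Σ_i S_i),

with the conventional α = 46, β = 125, to undo the greying that channel-wise
MSR causes.

Numerical choices: logarithms are offset by ε (default 1.0 on the byte
scale, i.e. 1/255 internally) so black pixels stay finite; convolution uses
reflective padding to avoid dark halos at borders; Gaussian supports are
truncated at 4σ; display stretch is linear min–max (a constant plane maps to
mid-grey 128 — any choice is arbitrary, this one is symmetric); a
percentile-clip stretch is available as an option. The exponential-transform
output variant is not implemented.

### Adaptive correction

The constant β treats every region alike, which pulls leukocytes and
distractors toward a common tone. The adaptive correction works in HSV space
(all components scaled to [0, 1]) and makes β local: each of the H and S
planes is tiled into k×k blocks (default k = 32; boundary blocks are
truncated, never padded, so their statistics come only from real pixels),
and each block gets

    C_M = (I_max − I_min)/(I_max + I_min)        (Michelson contrast, in [0, 1])
    β_block = γ · exp(C_M)                        (in [γ, γ·e])

with γ = 125 so that a zero-contrast block reduces exactly to the classic
constant-β recovery. An all-black block (I_max + I_min = 0) gets C_M = 0 by
convention, matching that constant limit. H is treated as a linear plane —
no circular statistics; the synthetic fixtures keep hues away from the wrap
at 0, where a linear treatment of a circular quantity would misbehave.
Per-block β is piecewise constant by default (the literal block procedure);
an optional flag bilinearly interpolates β between block centres to suppress
blocking artifacts.

The corrected component is the gain times the *exponentiated* reflectance:

    component′ = c(x, y) · exp(MSR(component))

The gain could equally multiply the log-domain MSR output; both readings are
consistent with a product formulation, and the choice is genuinely open. We
apply it at the output-transform stage (where the reflectance has been
mapped back to a linear intensity ratio) because the multiplicative form
preserves the saturation ordering between leukocytes and paler cells — in
the log domain the large negative background reflectance values dominate
the subsequent min–max normalisation and compress exactly the contrast the
correction is meant to amplify.

The V component receives illumination removal only — no colour-recovery
gain — via single-scale retinex at the *smallest* surround scale. That end
of the scale tradeoff tracks the illumination field most closely, which is
what background evenness requires; the larger scales act nearly globally on
desk-scale images and would pass most of a gradient through. (Min–max
normalisation alone cannot reduce background variance: it is an affine map
with slope ≥ 1 on unit-interval data, so some illumination estimate must be
divided out of V for the "uniformly bright backdrop" behaviour to be
possible at all.)

Each component is min–max normalised to [0, 1] independently, the image is
converted back to RGB, and each channel is stretched to the display range.
The denominator Σ_i S_i of the gain is the sum of the three HSV planes of
the uncorrected image.

### Segmentation network

A U-shaped fully convolutional network: a VGG-style encoder produces five
feature layers at successively halved resolution (channel widths
base·{1, 2, 4, 8, 8}); the decoder doubles resolution with nearest-neighbour
upsampling, concatenates the matching encoder layer, and applies two 3×3
convolutions; a 1×1 convolution yields per-pixel class scores. The reference
configuration takes 512×512×3 input; the test-scale preset uses 128×128 and
8 base filters. Input sides must be divisible by 2^(levels−1).

The implementation is pure NumPy — im2col convolutions with explicit
backpropagation — which keeps the package self-contained and every run
bit-reproducible from a seed. Training uses per-pixel cross-entropy (an
optional soft-Dice term is available via `dice_weight`), Adam at an initial
learning rate of 1e-4 (the schedule default; the desk-scale experiments
below use 1e-3 because a from-scratch network at their size converges
within their epoch budget at that rate), batch size 2, and a freeze/thaw
schedule: encoder parameters are held fixed for the first `freeze_epochs`
epochs (50 + 50 by default, mirroring transfer-learning practice with a
pretrained backbone), then released. When training from random
initialisation, freezing is counterproductive, so the desk-scale runs set
`freeze_epochs = 0`. Weights use He initialisation from a seeded generator;
two builds with the same seed are bit-identical.

### Metrics

With X the predicted pixel set, Y the ground truth and k the number of
classes: Dice = 2|X∩Y|/(|X|+|Y|) on the foreground; per-class
IoU = |X∩Y|/|X∪Y|, averaged over the classes present in the ground truth
(k = 2 here) for MIoU; MPA is the per-class recall averaged over classes;
accuracy-at-IoU is the fraction of images whose foreground IoU strictly
exceeds the threshold (default 0.8). Two empty foregrounds count as perfect
agreement (Dice = IoU = 1), so background-only tiles are not spurious
failures. The per-image IoU for the accuracy metric is computed on the
foreground class of the whole image, not per connected component.

### Counting

Predictions are binarised (probability > 0.5, or nonzero label), connected
domains are extracted (8-connectivity by default — leukocyte blobs are
compact, and 8-connectivity avoids splitting thin diagonal bridges;
4-connectivity is available), numbered 1..count with background 0, and an
optional minimum-area filter removes speckle. Touching or overlapping cells
merge into a single component; counting adherent cells is out of scope.

## Synthetic smears

The generator emulates the image structure the method relies on, not the
appearance of any particular stain or camera:

* bright low-saturation background (V ∈ [0.84, 0.92], S ∈ [0.04, 0.10]);
* many pale distractor ellipses (S ∈ [0.15, 0.30], orange-red hue kept away
  from the hue wrap at 0);
* a few darker, strongly saturated leukocytes (S ∈ [0.55, 0.75],
  V ∈ [0.48, 0.62]) drawn as a cytoplasm ellipse with a darker, more
  saturated nucleus;
* a smooth multiplicative illumination field — linear gradient with random
  per-image direction (amplitude a gives a brightest/darkest background
  ratio of (1+a)/(1−a); default 0.25) or radial vignette — plus optional
  stray light (`flare`) proportional to the local illumination deficit,
  which desaturates the dim side the way misaligned illumination does on a
  real microscope (default 0);
* additive Gaussian sensor noise (default sd 0.01).

Mean saturation obeys leukocytes > distractors > background, and leukocyte
value lies strictly below background value — the separability the adaptive
correction exploits; both orderings are enforced as config invariants.
Shapes are smoothed ellipses (Gaussian-blurred stencils, σ 0.8 px);
leukocytes are placed by rejection sampling with at least a one-pixel gap
between them, so the ground-truth mask and the component count are exact.
The mask marks exactly the placed leukocyte stencils. Everything is
deterministic given the seed.

What the generator does **not** model: staining chemistry and its
variability, leukocyte subtypes, adherent or overlapping leukocyte
clusters, focus gradients, chromatic aberration, and real sensor noise
statistics. Passing tests on these fixtures therefore demonstrate that the
algorithms behave as designed under the stated colour/illumination
structure — not that the trained test-scale network transfers to real
micrographs.

## Desk-scale experiment sizes

All validation runs on one CPU with seeded inputs; problem sizes are chosen
so the whole suite is a coffee-break affair:

* End-to-end learning: test-scale preset (128×128, 8 base filters), 40
  training + 40 held-out smears at default generator settings, 18 epochs,
  batch 2, learning rate 1e-3. Reaches mean held-out Dice well above the
  0.8 bar; both loss curves decrease (final-5 mean below first-5 mean).
* Preprocessing benefit: five replicate dataset pairs at 64×64 (20 train /
  12 test), strong gradient (amplitude 0.6) with stray light 0.35 and noise
  0.02, 12 epochs; the corrected pipeline must beat the raw pipeline's MIoU
  in at least four of five replicates. The stray-light term is what makes
  the comparison informative: a purely multiplicative field leaves H and S
  untouched and hands the raw network an illumination-invariant cue no real
  camera provides.
* Background flattening: 20 gradient-illuminated fixtures (amplitude 0.45);
  corrected background V-variance must drop below the raw variance in at
  least 95% of them. Typical variance ratios are ≈ 0.1.

## Known limitations

* The H plane is treated linearly; hues straddling the 0/1 wrap would need
  circular statistics.
* The NumPy network is CPU-sized; the reference 512×512/64-filter
  configuration is expressible but slow, and no pretrained encoder weights
  ship with the package (the freeze schedule is therefore mainly useful
  when such weights are loaded externally).
* Adherent leukocytes count as one component.
* Per-image min–max normalisation inside the correction ties the output
  scale to image extrema; extreme outlier pixels (dead pixels, dust) would
  compress the usable range.
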