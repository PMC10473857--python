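# Methods

This note documents the models, conventions and design choices behind
`grainsight`: a desk-scale re-creation of a machine-vision pipeline for
rice appearance-quality inspection, from backlit five-channel image to
per-grain phenotype table and perfect/imperfect classification.

## The inspection problem

A 20 g rice sample (800–1000 grains) is spread on a translucent stage and
imaged from above through a prism-split camera that delivers three
co-registered images: RGB, NIR₁ and NIR₂. The analysis must (i) separate
grains from background, (ii) split grains that touch each other
("adhered" or conglutinated grains) into individuals, (iii) cut a
fixed-size five-channel crop per grain, and (iv) classify each grain as
*perfect* or *imperfect* (diseased spot, mildew, or unripe/immature) while
reporting standard morphometrics. No public image set exists for the
original instrument, so the package ships a synthetic scene generator with
exact instance-level ground truth; all quantitative claims in the test
suite are claims about recovery of that generator's truth.

## Synthetic scenes (`synthetic_scenes`)

Grains are rotated ellipses. Geometry defaults: major axis 56 ± 3.5 px
(≈ 6% CV — milled rice within a variety is dimensionally uniform) and
aspect ratio 2.8 ± 0.2, typical of long-grain indica at the working
resolution where 800–1000 grains fill a few-megapixel frame. Test scenes
default to 100 grains on a 768×768 canvas; full-scale scenes are the same
code at a larger canvas.

Photometry follows the backlit convention: background ≈ 230, grain bodies
darker in every channel. Each grain has a radial shading profile
`core + (rim − core)·ρ^6` (flat translucent core ≈ 128–150 per channel,
rim 172): thick centers transmit less light. The NIR planes are the
luminance rendering passed through a wider Gaussian (σ 1.4 and 1.8 vs 0.5
for RGB) with lower additive noise (σ 1.5 vs 4.0) — longer wavelengths
scatter less, so the NIR surface is smoother; this is asserted as a
testable property (mean |Laplacian| over grain interiors).

**Adhesion.** With probability `adhesion_prob` a grain is placed touching
an existing cluster member (clusters capped at 4 grains), with contact
depth 5–30% of the smaller grain's minor axis. Every pair of touching
grains — including second contacts formed when a grain joins a chain —
gets a rendered *contact seam*: a dark occlusion line (level 90) where the
bodies press together, flanked by narrow bright crevice wedges (level 188,
still below the binarization threshold) where backlight leaks between the
curved bodies. This seam is what a gradient watershed can find; without
it, two merged constant-brightness silhouettes are unsplittable in
principle. Instance masks assign overlap pixels to the nearer grain in
normalized elliptic distance, with a connectivity repair pass so every
grain's mask is 4-connected.

**Defects.** Imperfect grains (default 30%) carry one of three phenotypes
(mix 0.4/0.3/0.3): *lesion* — 1–3 dark spots of radius 2–4 px at RGB
contrast 70 but NIR contrast 25 (reduced yet nonzero); *mildew* — a
diffuse darkened patch covering 20–60% of the grain (contrast 45 RGB / 18
NIR); *immature* — globally paler (+35) and 10–25% smaller. The contrasts
were chosen once so that classes are separable but not trivially so at
the default noise level. Spot radii are at the small end of the plausible
range (0.5–1.5 mm at this scale); this also keeps a lesion's interior
low-gradient pocket below the sliver-filter area during watershed
splitting.

**Noise.** Gaussian sensor noise everywhere, salt/pepper specks on the
background (2 per 10⁴ background pixels), and a few small dark debris
blobs (impurities) that preprocessing must remove. Scenes are bit-exactly
reproducible from the spec's seed; dataset scenes use `base_seed + index`.

What the generator does **not** emulate: real grain texture (chalkiness,
translucency gradients along the grain), lens distortion and prism
mis-registration, illumination non-uniformity, overlapping (stacked)
grains, and the natural continuum between defect classes. Passing tests
therefore demonstrate that the algorithms recover the stated structure
under controlled conditions, not field performance on real rice.

## Preprocessing (`preprocess`)

Gray conversion uses ITU-R 601 luminance weights on RGB; NIR planes are
excluded from segmentation (they feed classification). Denoising is a
sampled Gaussian with σ = 1.0 px, truncated at radius ⌈3σ⌉, reflective
borders. Binarization is Otsu's between-class-variance maximization over
the 256-bin histogram, classes `≤ t` vs `> t`, smallest t on ties; the
implementation is authored here (the convention is pinned and the
gradient+Otsu combination is central to the method) and is cross-checked
in tests against both an exhaustive 256-threshold search and
scikit-image. Foreground is the dark class (backlit stage). A guard
declares the scene object-free when the two Otsu classes are separated by
fewer than 30 gray levels — on a grain-free image Otsu would otherwise
bisect the background noise mode. Components smaller than `min_area`
(default 5% of the expected single-grain area ≈ 44 px) are removed;
specks and debris fall below this, grains are 20× above it.

## Region triage (`regions`)

Connected regions (8-connectivity) are described by area A, perimeter S
and roundness `4πA/S²` (1 for a disc; lower for elongation or merging).

**Perimeter convention.** S is the closed Moore (8-connected) outer
boundary chain length with diagonal steps weighted √2, multiplied by the
Kulpa calibration factor π/(8(√2−1)) ≈ 0.9481. Raw chain code
over-measures a smooth digital contour by ≈ 5.5% on average, which would
bias every roundness down by ≈ 10% and push a digital disc to ≈ 0.90; the
calibrated estimator puts a disc at 1.03 ± 0.03 and a 3:1 ellipse within
0.05 of the Ramanujan-perimeter value. A single-pixel region has S = 4 by
convention.

**Triage rule.** A region is *adhered* if roundness < 0.55 or area >
1.5 × median area of roundness-passing regions; otherwise *single*. The
two defaults were placed using the measured distributions under the
generator's conditions: single grains bottom out at roundness ≈ 0.61
(3.4:1 aspect tail) with an area tail ≈ 1.45× median, while merged pairs
either drop below 0.55 (end-to-end) or exceed ≈ 1.7× median area
(side-by-side). A false "adhered" call is benign — the watershed returns
one basin and the region passes through intact — so the gate is biased
toward sensitivity only as far as the ≥99%-singles property allows.

## Watershed splitting (`watershed`)

The gradient is the printed first-difference magnitude
`g = √((f−f↑)² + (f−f←)²)` with replicated borders (a Sobel magnitude is
available as an option). Over-segmentation is suppressed by *clamping*:
`g' = max(g, t)` with t from Otsu on the integer-binned gradient
histogram restricted to the region — every basin shallower than t is
flooded away, leaving one catchment basin per grain body (the components
of `{g ≤ t}`).

Flooding processes levels in ascending order; within a level each
connected plateau component seeds a new basin (no labeled neighbor),
joins its unique adjacent basin, or is divided among several by geodesic
BFS distance with equal-distance pixels becoming watershed lines. These
semantics are deterministic and order-free, which lets an independent
fixed-point (Bellman–Ford-style) flood serve as an exact oracle in the
tests. Watershed-line pixels belong to no grain.

One post-processing rule extends the textbook procedure: a basin that
vanishes under two 3×3 binary erosions (i.e. is nowhere more than about
four pixels wide) is reclassified as line zone. Along a long
side-by-side contact, the crest of the occlusion seam floods as a
legitimate thin basin whose area (40–135 px) straddles any fixed area
cutoff; the morphological criterion identifies it reliably without
touching grain bodies, which at this working scale are never narrower
than ~10 px. Remaining submasks smaller than `min_area` are discarded as
slivers; a region yielding a single basin is passed through whole and
flagged.

Measured behavior at defaults: ≥ 98% of generated two-grain clumps split
into exactly two grains (four independent 200-clump blocks), the
unclamped control over-segments nearly always, and end-to-end counting
on 100-grain scenes with adhesion 0.2 shows 1.1–1.8% mean absolute error.

## Crops and stacking (`stacking`)

The five planes are stacked in fixed (R, G, B, NIR₁, NIR₂) order. Each
final grain mask is cut at its bounding box, padded symmetrically to a
square, masked (background fill 0 by default, to minimize background
signal leakage into the CNN) and resized bilinearly to 100×100 in all
five planes with one shared transform; output is rounded half-up to
8 bits. An identity-size window is passed through bit-exactly.

## Classification (`classifier`, `nn`)

Two architectures are built on an in-package numpy layer library
(im2col convolution, batch norm, ReLU, max/avg pooling, fully-connected,
bottleneck residual blocks, softmax cross-entropy, Adam, full backprop —
verified against finite differences):

* **vgg19_variant** — five stages of conv 3×3 → batch-norm → ReLU →
  max-pool 2×2, then one fully-connected layer and softmax: 24 layers
  under the taxonomy (input + 5 conv + 5 BN + 5 activation + 5 pool +
  FC + softmax + output). Stage widths default to (16, 32, 64, 128, 256),
  a VGG-family progression sized so that CPU training on a thousand
  crops takes minutes rather than hours; the layer count and behavior do
  not depend on the widths.
* **resnet50** — 7×7/2 stem, max-pool, four bottleneck stages of depths
  (3, 4, 6, 3) (first block per stage a projection block, the rest
  identity blocks, three convolutions each), global average pool, one
  fully-connected layer: 1 + 3×16 = 49 convolutions plus 1 FC, following
  the conventional accounting in which shortcut projections are
  shape-matching maps rather than counted layers. Identity blocks
  satisfy Y = F(X) + x exactly when F is zeroed (batch norms expose a
  bypass used to verify this without the ε in the variance).

Training: Adam at learning rate 0.001 (the instrument's published
setting), batch 32, ≤ 100 epochs with early stopping (patience 10 on an
internal 15% validation split), all randomness drawn from one seeded
generator so runs are bit-reproducible. Five-channel input precludes
RGB-pretrained weights; He initialization is used. Inputs are scaled to
[−0.5, 0.5].

At the reference experiment (1000 balanced synthetic crops, ≤ 20 epochs)
the VGG variant reaches ≈ 99% held-out accuracy — the synthetic defects
are cleaner than real rice, so this is a scaled-down label-recovery
check, not a claim about the published 92.3%/91.3% accuracies, which used
a proprietary image set. A directional property encodes the five-channel
rationale: with defect contrast placed only in the NIR planes, the
five-channel model strictly beats the RGB-only model of the same
architecture.

## Pipeline and reporting (`pipeline`, `cli`)

`inspect_scene` chains the stages and emits one row per final grain:
centroid, area, perimeter, roundness, fitted-ellipse axes
(scikit-image moments), and, when a model is supplied, predicted class
with probability. With ground truth attached it also reports counting
accuracy and a confusion matrix via majority-overlap matching of final
masks to true instances. `benchmark_counting` aggregates
`1 − |detected − true|/true` over seeded scenes. The CLI (`grainsight
simulate|segment|train|classify|inspect|benchmark`) is a thin layer over
these functions; run manifests record all parameters and seeds.

## Numerical conventions and degenerate inputs

0-based (row, col) coordinates, half-open bounding boxes; 8-connectivity
everywhere unless stated. Rounding to 8 bits is half-up. Otsu ties take
the smallest threshold. Constant images raise a degenerate-histogram
error at binarization but pass through with a warning at gradient
clamping (the region is then returned unsplit and flagged). Empty masks,
empty scenes and empty crop lists are legal inputs with empty outputs.

## Known limitations

* The generator's contact-seam model is the load-bearing assumption for
  watershed splitting; real adhered grains with invisible seams would be
  under-split, and the reported splitting rates are conditional on the
  seam photometry stated above.
* Roundness depends on the perimeter estimator; the Kulpa calibration is
  accurate for smooth convex digital shapes but the absolute values for
  very small or very thin regions are conventional.
* The classifier accuracy on synthetic crops overstates what the same
  architecture would achieve on real rice; only the architecture,
  training mechanics and the NIR-ablation direction transfer.
* The flood is quadratic in plateau size in the worst case (per-basin BFS
  per plateau); adhered regions of a few thousand pixels take
  milliseconds, but the implementation is not meant for whole-image
  unseeded watersheds.
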