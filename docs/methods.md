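# Methods

`lesionsal` computes instance-level, quantitative saliency maps for
volumetric semantic segmentation, together with the evaluation machinery
needed to validate them (lesion-instance extraction, example
classification, peak-value statistics, sanity checks, and a contextual-
information probe). This note records the models, the parameter choices and
their rationale, the numerical decisions, and what the synthetic test bed
does and does not establish.

## Setting and notation

A multi-channel volume `x[v]` lives on the full rectangular voxel grid
`Γ ⊂ Z^D` (D = 3 by default; D = 2 is supported so oracle tests stay
cheap). A segmentation model maps `x` to per-voxel logits `y[v]` with the
same spatial dimensions; the foreground probability is the two-class
Softmax of the logit (the background logit fixed at zero, i.e. the
logistic function). Binarizing the probability map at `t = 0.3` (strictly
greater) and taking connected components under 18-connectivity, discarding
components smaller than 5 mm³, yields lesion instances; each instance's
voxel set `Ω ⊂ Γ` is the unit of explanation.

Instances are classified against ground truth by overlap alone: a
predicted instance with at least one voxel on the ground-truth mask is a
true positive, otherwise a false positive; a ground-truth instance
untouched by the full predicted mask is a false negative. No one-to-one
assignment is attempted — a single prediction overlapping two ground-truth
lesions is one TP. True-negative examples are ten spheres of 93 mm³
(radius ≈ 2.81 mm) per volume, rejection-sampled inside the brain mask so
that they intersect neither the ground-truth nor the predicted mask;
spheres may overlap each other. The discrete sphere is the set of voxels
whose centre lies within the target radius; its realized voxel volume is
recorded rather than forced to exactly 93 mm³.

## Gradient saliency

For one instance `Ω`, the per-voxel gradients `D_{v'} = ∂y[v']/∂x[v]` of
every source voxel `v' ∈ Ω` are combined into one map per input channel.
Two aggregations are provided:

* **mean** — `M[v] = (1/(N|Ω|)) Σ_n Σ_{v'∈Ω} ∂y(x_n)[v']/∂x_n[v]`. Its
  in-lesion magnitude scales like `1/|Ω|`, so values are not comparable
  across lesions of different sizes.
* **signed maximum** — per noise repetition `n`, each map voxel keeps the
  candidate of largest absolute value with its sign,
  `D^n_{argmax_{v'}|D^n_{v'}|}`, and the `N` kept maps are averaged. The
  selection happens inside the sum over `n` (argmax per repetition). Ties
  go to the smallest `v'` in scan order. On the per-voxel linear reference
  model the in-lesion value equals the model weight exactly for any `|Ω|`,
  which is the point of the rule.

SmoothGrad adds independent `N(0, σ)` noise per repetition, channel and
voxel, with defaults `N = 50`, `σ = 0.05` on the z-scored intensity scale.
`N = 1, σ = 0` reduces bit-exactly to vanilla gradients. All randomness is
driven by an explicit seed.

Because input gradients vanish beyond a model's receptive field,
computation is restricted to the bounding box of `Ω` grown by the model's
analytically derived receptive-field radius (48 voxels when a model
reports none) and re-embedded at the original offset; equality with the
full-volume computation is asserted in tests for the reference models.
The brute-force path — one backward pass per source voxel — is the
reference; the batched implementation must match it within 1e-5.

A band filter discards gradient values strictly inside an open interval
(default (−0.1, 0.1)) to focus analyses on voxels with higher attention;
boundary values are kept, the open-interval reading being the literal one
and the boundary having no practical weight.

## Grad-CAM++

Class-level maps use the scalar aggregate `y' = Σ_{v: y[v] > t} y[v]`
(thresholded on logits) and one weight per activation map:
`ω^k = Σ_v α^k[v]·Relu(∂y'/∂A^k[v])`, `M = Relu(Σ_k ω^k A^k)`. The
instance-level adaptation takes `y' = Σ_{v∈Ω} y[v]` (signed, no
threshold) and drops the spatial summation, keeping a weight per element:
`ω^k[v] = α^k[v]·Relu(∂y'/∂A^k[v])` — this is what prevents other
instances' activations from surfacing. Heatmaps from coarser layers are
upsampled linearly to the input grid (identity at equal resolution;
linear interpolation of a non-negative map stays non-negative).

The coefficients are
`α^k[v] = d2 / (2·d2 + (Σ_{v'} A^k[v'])·d3)` with `d2`, `d3` the diagonal
second and third derivatives of `y'` with respect to `A^k[v]`. Two
readings of the third-derivative term exist; the default multiplies the
*global* activation sum by the local third derivative (the literal form,
matching the original classification derivation), and a `third_term="local"`
variant using only `A^k[v]` is exposed and compared in tests. Where the
denominator's magnitude falls below `ε = 1e-8` the coefficient is set to
zero; at such points the first derivative is degenerate too, and this is
the guard reference implementations use.

Three derivative routes are available and recorded in metadata:

* `exact` (default) — closed-form nested differentiation. For layers whose
  downstream path is affine or piecewise affine — in particular the last
  activation layer of a ReLU-family segmentation head — the diagonal
  higher-order derivatives vanish (almost everywhere), the guard fires and
  the heatmap is the documented degenerate zero map.
* `power` — the classical closed form obtained by passing the score
  through an exponential before differentiating a piecewise-affine
  network: `d2 = g²`, `d3 = g³` with `g = ∂y'/∂A`. One backward pass; the
  practical route for trained networks, and the one the pipeline and the
  benchmark use.
* `finite_difference` — central differences on individual activation
  elements (step 1e-3); O(#elements) evaluations, intended for oracle
  checks on small layers, where it must agree with the exact route within
  1e-3 relative.

## Experiments

**Peak statistics.** Each example contributes the maximum and the minimum
of its saliency map (per channel, over the computed crop). Per-category
medians carry percentile-bootstrap 95% CIs (1000 resamples, seeded). All
available category pairs are compared with two-sided Mann-Whitney U tests:
exact enumeration of all group assignments (ties handled by the ½-count U)
when both groups have ≤ 8 members, tie-corrected normal approximation
otherwise. Analyses default to channel 1 (the hyperintense-lesion analog),
configurable.

**Sanity checks.** A probe domain in lesion-free tissue is processed
exactly like a lesion (it must not intersect the ground-truth or predicted
masks), and its peaks are compared against the lesion range. Lesion
transplantation copies the intensities of an instance — optionally with a
surrounding shell obtained by face-connected dilation, one step per mm —
onto a translated footprint; every voxel outside the destination footprint
is bit-identical to the original.

**Context probe.** Starting from the input masked to `Ω` (all other
voxels set to 0, the z-scored tissue mean), the visible region grows by
morphological dilation with the face-connected unit element (one step
≈ 1 mm axially at 1 mm spacing; the 26-connected element is available by
flag), 35 iterations by default. Per iteration the mean Softmax score in
`Ω` and a detection flag (any in-`Ω` score strictly above `t = 0.3`) are
recorded. Dilation does not respect the brain mask by default (the mask is
a configurable option). Once the dilated mask covers the grid the input
equals the original volume, so the scores are constant from there on and
are filled without re-running the model. For the probe cohort, lesions
with physical volume in the closed interval [90, 120] mm³ are preferred
(near-average size).

## Reference models

All models are implemented in numpy with explicit backpropagation, and
expose the same contract: forward to logits, input gradients of weighted
logit sums (batched over many scalar functionals in one sweep), named
activation layers with the downstream map to the logits, and an
analytically derived receptive-field radius.

* `AnalyticLinearModel` — `y[v] = Σ_c w_c x_c[v] + b`; radius 0, every
  derivative known in closed form. The oracle for aggregation rules and
  for "no context" behaviour.
* `FixedConvModel` — one fixed odd-sized kernel on one channel; radius =
  kernel Chebyshev radius, so gradient support is testable exactly.
* `TinyCNN` — a two-resolution encoder–decoder
  (conv3 → act → avgpool2 → conv3 → act → nearest-up2 → concat-skip →
  conv3 → act → 1×1 conv), about 9k parameters, LeakyReLU activations
  (slope 0.01). LeakyReLU is the choice common in segmentation U-Nets and
  keeps rarely-active channels trainable: with hard ReLU, small trained
  instances can end up encoding lesions purely by *suppression* of
  background-tuned channels, all positively-weighted head channels dead —
  a representation on which rectified-gradient CAM methods are blind.
  The receptive-field radius (5 voxels for 3³ kernels) is derived by
  propagating index intervals through the layer hyperparameters, over all
  pooling parities.

Training uses per-voxel binary cross-entropy with logits (configurable
positive-class weight, default 1.0) and Adam (lr 6e-3), 20 epochs over 24
phantoms of 32³ voxels, all seeded. This configuration was selected for
segmentation quality of the stand-in — mean Dice ≈ 0.90 against phantom
ground truth with predicted/true volume ratio ≈ 1.07, i.e. a
boundary-accurate, converged model — since every downstream experiment
presumes a model that segments well. Losses are required to be finite;
`epochs = 0` returns the initialised model with a warning.

## Synthetic phantoms

Phantoms emulate the statistical structure the method assumes of
preprocessed two-channel MR volumes: blob lesions hyperintense in channel
1 (+3 raw contrast) and hypointense in channel 2 (−2) against unit-variance
Gaussian tissue noise inside an ellipsoidal brain support (semi-axes 0.42
of the grid), constant air far below tissue outside it, and per-channel
z-scoring computed over the brain mask only. Lesion blobs have a one-voxel
cosine-tapered edge to avoid gradient artifacts at hard boundaries; radii
are drawn from 1.5–4.0 mm (1.5–3.0 mm in the 32³ fast configuration), so
every ground-truth component survives the 5 mm³ filter. Lesions are placed
fully inside the brain, pairwise non-overlapping; explicit centres and
radii can be given for controlled setups (e.g. two lesions separated
beyond the receptive-field diameter). Everything is reproducible from the
configuration seed.

The phantoms are *not* realistic MRI: no anatomy, bias fields, partial
volume, spatially correlated noise or scanner variability. Two consequences
matter for interpreting results. First, because the background is
independent unit-variance noise, suppressing false positives is the
statistically hard sub-task for the model — closer to the inverse of the
clinical situation, where lesion evidence is subtle and background is
smooth. Peak-value comparisons on phantoms therefore probe the *machinery*
(maps are computed, aggregated and compared correctly): the TP and TN
peak distributions separate strongly, but which group sits higher depends
on the training seed, and no clinical claim about the ordering should be
read into either outcome. Second, the
lesion intensity profile extends about two voxels past the ground-truth
core (the taper), so "perilesional tissue" in the sign-structure analysis
is measured at Euclidean distance 2–5 voxels from the instance, outside
the blob's own intensity footprint.

## Benchmark problem sizes

The standing seeded benchmark trains on 24 phantoms of 32³ voxels,
evaluates on 10 held-out phantoms, uses 4 noise repetitions per saliency
map and caps maps at 40 per example category (30 for the 93 mm³ control
spheres, which are the most expensive domains); these sizes keep the full
benchmark around seven minutes on one CPU core while leaving ≥ 30 examples
per compared group. The method defaults (N = 50, σ = 0.05, t = 0.3,
18-connectivity, 5 mm³, ten 93 mm³ spheres, 35 dilations, [90, 120] mm³)
are unchanged; the benchmark only reduces repetition counts and example
budgets.

## Numerical choices and degenerate inputs

* Binarization and detection use strict inequality (`p > t`, score `> t`).
* Tie-breaks (signed-max candidates, centre-of-mass fallback, instance
  labels) follow scan order for bit-reproducibility.
* The centre-of-mass domain rounds the mean index to the grid and falls
  back to the nearest member voxel when the rounded mean lies outside `Ω`.
* Empty domains raise immediately (`EmptyDomainError`); an empty logit
  selection in the class aggregate returns 0 with a warning.
* Sphere sampling retries up to 10 000 times per sphere and reports how
  many spheres were placed when it gives up.
* Volumes with odd spatial sizes are zero-padded internally to even sizes
  by the two-resolution model and cropped back; gradients are exact with
  respect to the unpadded input.
* Double precision throughout; gradient implementations are verified
  against finite differences and, for the aggregation paths, against
  brute-force per-voxel backward passes at 1e-5 absolute.

## Known limitations

* Class-level Grad-CAM++ on the tiny model concentrates most of its mass
  at high-activation regions near the brain/air boundary; lesions carry a
  small fraction of total mass (they are present, which is the contrast
  with the instance-level map, whose off-target mass is exactly zero for
  far-apart lesions). Wide clinical networks with many, more selective
  feature channels behave more favourably.
* The sign-structure statistics (positive in-lesion, negative
  perilesional medians) are properties of a particular trained model and
  phantom family; their magnitudes here are small and seed-dependent even
  though the signs are stable in the shipped configuration.
* The exact higher-order derivative route is informative only for smooth
  functionals; on piecewise-affine networks it correctly yields the
  degenerate zero heatmap, and the power route is the operative one.
* Whole-brain clinical volumes, sliding-window inference, and clinical
  performance metrics are out of scope.
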