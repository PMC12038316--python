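# Methods

This note documents the model implemented by `scenenet`, the parameter
choices that matter, what the synthetic stimuli do and do not emulate, and
the numerical decisions a user should know about.

## Model overview

The network is a three-layer feedforward competitive hierarchy over a
V1-like front end, with two scene-specific mechanisms in the top layer:
gain modulation by gaze direction and a recurrent continuous attractor.
The intent is to show how world-referenced ("allocentric") scene
representations and spatial view cells can emerge from visual feature
combinations alone, without error backpropagation or supervision.

| stage | size | afferents/neuron | radius | sparseness target |
|---|---|---|---|---|
| V1 (Gabor) | 256×256×32 | — | — | — |
| Layer 1 | 32×32 | 54 | 1.0 | 0.10 |
| Layer 2 | 32×32 | 40 | 1.7 | 0.12 |
| Layer 3 | 32×32 | 40 | 1.7 | 0.08 |

The natural-scene demonstration configuration instead uses sparseness
0.3 / 0.4 / 0.4 with lateral inhibition disabled.

## V1 front end

Even-symmetric (cosine-phase) Gabor kernels at wavelengths {4, 8, 16, 32}
px, orientations {0°, 45°, 90°, 135°}, Gaussian envelope σ = 0.5·λ, aspect
ratio 1, truncated at 3σ. Each kernel is mean-subtracted to exact DC
balance and L2-normalised. The image is mean-subtracted and filtered with
reflective borders; each linear response is split into half-rectified
positive and negative channels, so one of each sign pair carries the
response and the stack is everywhere non-negative. Contrast (standard
deviation) normalisation is deliberately not applied: an alternative
front-end that equalised band gains against a 1/f reference spectrum was
evaluated and rejected, because it lets generic fine-edge energy dominate
the drive and markedly degrades the allocation of distinct populations to
distinct patches.

## Connectivity

Afferents are drawn from a radially symmetric Gaussian probability kernel
centred on the topologically aligned source position (proportional scaling
of cell centres). The layer's radius parameter is calibrated so the kernel
places 67 % of its probability mass within one radius: for a 2-D radial
Gaussian, P(r ≤ R) = 1 − exp(−R²/2σ²) = 0.67 gives σ = R/1.489. The kernel
is truncated at 4σ and at the layer edge (no wraparound) and renormalised.

Two distinct statements follow and both are tested:

- sampling the kernel itself (i.i.d. draws) puts ≈67 % of connections
  within one radius — this is the calibration the radius expresses;
- the realised afferent lists are drawn *without replacement* (a neuron
  never receives duplicate synapses from one source). At Layer-2/3 scale
  (40 afferents, radius 1.7 ≈ 9 grid cells within one radius) the
  de-duplication necessarily spreads the realised lists wider than the
  kernel, so the 67 % figure characterises the kernel, not the realised
  in-radius fraction. If the truncated support cannot supply the requested
  afferents, the kernel scale is widened by 1.5× iteratively (logged).

V1 afferents to Layer 1 are sampled spatially with the radius scaled to
pixel units (×8), and allocated across frequency bands proportionally to
band frequency (geometric ratio 2 per octave: 29/14/7/4 of 54 afferents,
high to low, by largest-remainder rounding), with orientation and sign
uniform within a band.

## Competition

Per presentation: activation (inner product over the afferent list) →
optional Mexican-hat lateral inhibition → threshold setting. The
difference-of-Gaussians filter uses σ = 0.2 (centre) and 1.5 (surround) in
neuron units, both Gaussians normalised to equal mass so the filter sums
to zero; half-width ⌈4·surround⌉; reflective borders.

Threshold setting solves for the scalar θ with y = max(0, h − θ) whose
population sparseness a = (Σy/n)²/(Σy²/n) matches the layer target, by
bisection on [min(h, 0), max(h)] (the lower end includes 0 so an
already-satisfying map keeps θ = 0), tolerance 1e−3 on a, at most 60
iterations, keeping the best (and among ties the smallest) θ visited. A
constant activation map is degenerate: all-zero rates are returned with a
logged warning. Sparseness of the returned rates is scale-invariant and
equals the active fraction for binary rates.

## Learning

- Layer 1: associative rule δw_j = α·y·x_j.
- Layers 2–3: trace rule δw_j = α·ȳ·x_j with ȳ τ = (1−η)y τ + η ȳ τ−1.
  η = 0 makes the two rules bit-identical (shared code path). The trace is
  reset at each patch change so features of different patches are never
  associated across the presentation boundary.
- After every update the neuron's weight vector is renormalised to unit
  Euclidean norm (required for stable competitive learning); silent
  neurons are left bit-identical.

**Learning rate.** α = 1.0 by default. With the schedule used (7 epochs ×
4 update presentations per patch) smaller rates leave the weights close to
their random initialisation — at α = 0.1 the Layer-1 populations recruited
by two different glyph patches still overlap by ≈52 % versus ≈63 % before
any training, while the per-neuron tuning is already saturating. At
α = 1.0 a winner's weight vector essentially converges to its input
pattern within an epoch (fast competitive learning) and the allocation
becomes stimulus-driven (overlap ≈0.37–0.49 across seeds). Results do
depend on this choice; it is exposed in the configuration.

**Schedule.** An epoch visits every (patch, gaze) pair once in a seeded
random permutation. Each visit presents the patch 5 times to let the trace
build up (weights frozen) and then 4 times with synaptic updates. Layers
are trained sequentially — Layer 1 for all epochs, then Layer 2, then
Layer 3 — so upper layers always see stationary inputs; a simultaneous
mode is available behind the `training.sequential` flag. The buildup
presentations are run for Layer 1 too (inert under the associative rule)
to keep the schedule uniform. An optional fixation-jitter augmentation
(±4 px shifts, 3 transforms per visit, default off) exercises the trace
rule's purpose of binding nearby fixations of the same patch.

## Gaze gain modulation and the scene attractor

The gaze direction is quantised to four quadrants tiling the 32×32 scene
frame, nominally ±35° azimuth/elevation at quadrant centres (one fixation
patch ≡ 70° of visual angle, whole scene ±70°). Remapping is implemented
as downsample-and-place: 2×2 block averaging (conserving total drive up to
the factor 4) into the quadrant's 16×16 block. A multiplicative gain-field
formulation would be an equivalent alternative; the shift operator is what
the demonstrations require.

Recurrent Layer-3 weights update as δw_ij = α·y_i·y_j·k(d_ij) with
k(d) = exp(−d²/2σ_d²), σ_d = 4 neuron units. The distance factor must be
*decreasing* — nearby co-active neurons bind more strongly — which is what
makes the attractor continuous. Rates enter this rule normalised to peak 1
and the learning rate is 0.01, so that the cumulative increments over a
training run stay below the per-synapse ceiling of 1.0; a saturated weight
matrix would flatten the distance structure that the rule exists to
create. W is kept symmetric, non-negative, zero-diagonal.

Recall and bump dynamics iterate r ← set_sparseness(W·r [+ cue − β·a]).
The recurrent drive W·r is divisively normalised to peak 1 each step
(global divisive inhibition); without it the threshold-linear iteration
has no intrinsic scale and rates grow without bound. Adaptation follows
a ← λ·a + (1−λ)·r with the subtractive current β·a; λ = 0.9, β = 1.0 by
default. β = 0 reduces exactly to non-adapting recall. Adaptation is a
diagnostic device only: a settled bump (see `settle`, which relaxes the
cue-free dynamics to a fixed point, tolerance 1e−9, up to 500 steps) stays
put at β = 0 and travels semi-continuously at β = 1, demonstrating that
the weights implement a continuous attractor. Convergence of the cue-free
relaxation can take a few hundred iterations depending on seed.

## Receptive-field mapping

A probe (default 32×32 px) is cut from the image, presented at its true
position on a zero background, and stepped in 2-px increments, giving a
113×113 lattice for 256-px images. The forward pass during probing is
identical to training (same inhibition and sparseness settings, threshold
re-solved per probe). Because a probe is zero outside a small square, its
Gabor responses vanish beyond one kernel half-width; the mapper filters
each probe on a small window with cached kernel FFTs, which is numerically
identical to the naive full-image pass (verified to ~1e−16 in the test
suite) and orders of magnitude faster (~9 ms per probe). RF size is
reported as the equivalent circular diameter of the area above half the
peak, in pixels and in degrees (70°/256 px).

## Synthetic stimuli

Glyph patches: a fixed embedded 5×7 bitmap font (no system font
rasterisation, hence bit-identical output everywhere), upscaled ×6 by
nearest neighbour, on a 3×3 cell lattice spanning the central 75 % of the
field; the lower-right glyph is offset by (3, 3) px so the topology of the
learned maps can be traced through the layers. Strokes are white on black
by default (polarity configurable through the rendering call). Natural-like
patches are seeded isotropic noise with a 1/f amplitude spectrum, rescaled
to [0, 1]; exponent 0 gives white noise. These share natural images'
second-order statistics but have no objects, occlusions, shading or phase
structure — passing tests therefore demonstrate the mechanisms
(competitive allocation, remapping, attractor formation), not performance
on real photographs. Any user-supplied 256×256 grayscale image is accepted
equivalently.

## Determinism and problem sizes

All randomness derives from one integer seed through named substreams
(connectivity per layer, weight initialisation, schedule, stimuli), so
identical configuration + seed gives bit-identical models. The worked
demonstrations use the full architecture above with two fixation patches
per scene and 7 training epochs (seconds to train); full 113×113
receptive-field maps take a few minutes per neuron on one core, and the
examples use coarser probe steps where only the qualitative picture is
needed.

## Known limitations

- Gaze is quantised to four quadrants; continuous gaze angles and
  overlapping fixation patches are not implemented.
- No recall of scenes from partial hippocampal cues via backprojections,
  no top-down attention, no multi-scene capacity experiments.
- Competition is algorithmic (threshold setting), not an explicit
  inhibitory population; no spiking dynamics.
- The fixation-jitter augmentation is minimal (integer shifts) and off by
  default; trace-rule invariance is exercised but not studied
  parametrically.
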