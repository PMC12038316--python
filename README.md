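# scenenet

A simulator of how the primate brain may build **spatial view cells** —
hippocampal-system neurons that fire when a particular location in a viewed
scene is looked at — from a purely feedforward, biologically plausible
visual hierarchy. The package is aimed at computational neuroscientists who
want a tested, reproducible implementation of scene-coding by competitive
learning, gaze gain modulation, and a whole-scene continuous attractor.

## The model

Three 32×32 layers of threshold-linear neurons sit on a Gabor-filter V1
front end (256×256×32 channels: 4 spatial frequencies × 4 orientations ×
2 signs). Each neuron receives a fixed number of afferents (54/40/40 for
Layers 1–3) from a Gaussian-profile neighbourhood of the previous layer
whose radius (1 / 1.7 / 1.7 neuron units) contains ≈67 % of the connection
probability.

**Competition.** Activations are inner products `h_i = Σ_j w_ij x_j`;
after optional Mexican-hat lateral inhibition (difference of Gaussians,
radii 0.2/1.5), rates are `y_i = max(0, h_i − θ)` with the single threshold
θ set so the population sparseness

    a = (Σ_i y_i / n)² / (Σ_i y_i² / n)

hits the layer's target (0.1 / 0.12 / 0.08; for binary rates `a` is the
active fraction).

**Learning.** Feedforward weights follow the associative rule
`δw_j = α y x_j` (Layer 1) or its short-term-memory-trace variant
`δw_j = α ȳ τ x_j` with `ȳ τ = (1−η) y τ + η ȳ τ−1` (Layers 2–3; η = 0
reduces it exactly to the associative rule), with weight vectors
renormalised to unit length.

**Scene building.** A gaze-direction signal (quadrant UL/UR/LL/LR of a
±70° scene) gain-modulates the Layer-2 fixation-patch representation:
halved in size and placed at its world position in the 32×32 Layer-3
scene frame. Recurrent Layer-3 weights grow between co-active neurons with
a strength that decays with their distance in the scene
(`δw_ij = α y_i y_j e^{−d²/2σ_d²}`), forming a continuous attractor that
stitches the fixation patches into one scene. Firing-rate adaptation can be
switched on purely as a diagnostic: it makes the activity bump travel
semi-continuously across the map, which is the attractor's signature.

## Worked example

```bash
python examples/03_train_glyph_scene.py
```

trains the network for 7 epochs on two alphanumeric fixation patches
(digits fixated under gaze UL, letters under UR) and prints:

```
layer1: sparseness 0.101 (target 0.1), active 141 vs 142 neurons, population overlap 0.45
layer2: sparseness 0.119 (target 0.12), active 155 vs 150 neurons, population overlap 0.05
layer3: sparseness 0.080 (target 0.08), active 107 vs 99 neurons, population overlap 0.00
layer3 digits support in UL quadrant: 0.98
layer3 letters support in UR quadrant: 1.00
```

Each layer's measured sparseness sits on its target; the two patches are
encoded by largely different neuron populations (overlap well below half);
and the gaze gain modulation places each patch's Layer-3 representation in
its own quadrant of the whole-scene frame. The other examples cover
stimulus generation, V1 encoding, receptive-field mapping (printing the
half-max field diameter in pixels and degrees), and the adaptation-driven
moving bump.

A thin CLI exposes the same operations:

```bash
scenenet gen-stimuli --out stimuli/ --seed 0
scenenet train --scene glyphs --seed 0 --out model/
scenenet map-rf --model model/ --image stimuli/patch1_digits.png \
        --layer 3 --neuron 4,4 --gaze UL --out rf_map
scenenet demo-bump --model model/ --steps 200 --out bump/
```

## Layout

- `src/scenenet/stimuli.py` — glyph-grid and 1/f natural-like fixation patches, image I/O
- `src/scenenet/gabor.py` — V1 Gabor bank and encoding
- `src/scenenet/topology.py` — Gaussian-profile afferent sampling, per-frequency allocation
- `src/scenenet/competitive.py` — activation, lateral inhibition, sparseness, learning rules
- `src/scenenet/scene.py` — gaze remapping, continuous attractor, bump dynamics
- `src/scenenet/training.py` — schedules, sequential layer training, inference, archives
- `src/scenenet/analysis.py` — receptive-field probe mapping, selectivity, exports
- `src/scenenet/config.py`, `cli.py` — configuration schema, seeds, CLI
- `docs/methods.md` — the model, parameter choices and limitations in detail
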