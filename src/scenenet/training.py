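"""Training orchestration: the full stimulus/gaze schedule over epochs,
sequential layer-wise competitive learning, and the inference pass.

A training epoch presents each (fixation patch, gaze) pair of the scene in
a seeded random permutation.  Each patch visit consists of buildup
presentations that let the short-term memory trace charge without weight
changes, followed by update presentations with synaptic updates: the
associative rule in Layer 1, the trace rule (which reduces to the
associative rule at eta = 0) in Layers 2-3, and additionally the
distance-weighted recurrent update of the scene attractor in Layer 3.
Layers are trained sequentially (each layer is fully trained before the
next one sees its output), so upper layers always learn from stationary
inputs; a simultaneous mode is available behind a flag.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import competitive as comp
from .config import RunConfig, make_config, substream
from .gabor import GaborBank, V1Stack, build_gabor_bank, encode
from .scene import GazeDirection, RecurrentWeights, remap_by_gaze
from .stimuli import GrayImage, SceneSpec
from .topology import (
    ConnectivityMap,
    LayerConfig,
    build_layer_connectivity,
    build_v1_connectivity,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainingSchedule:
    """Presentation schedule for one training run."""

    n_epochs: int = 7
    n_update_presentations: int = 4
    n_buildup_presentations: int = 5
    sequential: bool = True
    jitter_enabled: bool = False
    jitter_amplitude_px: int = 4
    jitter_n_transforms: int = 3

    def __post_init__(self) -> None:
        if min(self.n_epochs, self.n_update_presentations,
               self.n_buildup_presentations) < 1:
            raise ValueError("schedule counts must be >= 1")

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "TrainingSchedule":
        t = cfg["training"]
        return cls(
            n_epochs=t["n_epochs"],
            n_update_presentations=t["n_update_presentations"],
            n_buildup_presentations=t["n_buildup_presentations"],
            sequential=t["sequential"],
            jitter_enabled=t["jitter"]["enabled"],
            jitter_amplitude_px=t["jitter"]["amplitude_px"],
            jitter_n_transforms=t["jitter"]["n_transforms"],
        )


@dataclass
class Model:
    """The three-layer network plus its V1 front end and scene attractor."""

    config: RunConfig
    bank: GaborBank
    layer_cfgs: tuple[LayerConfig, LayerConfig, LayerConfig]
    conn_v1_l1: ConnectivityMap
    conn_l1_l2: ConnectivityMap
    conn_l2_l3: ConnectivityMap
    recurrent: RecurrentWeights
    log: list[dict] = field(default_factory=list)
    _v1_cache: dict[bytes, V1Stack] = field(default_factory=dict, repr=False)

    def encode(self, img: GrayImage) -> V1Stack:
        key = hashlib.sha1(img.pixels.tobytes()).digest()
        if key not in self._v1_cache:
            if len(self._v1_cache) > 16:
                self._v1_cache.clear()
            self._v1_cache[key] = encode(img, self.bank)
        return self._v1_cache[key]


def build_model(config: RunConfig | None = None) -> Model:
    """Initialise a model with seeded topological connectivity."""
    cfg = config or make_config({})
    g = cfg["gabor"]
    bank = build_gabor_bank(
        n_freq=g["n_freq"], n_orient=g["n_orient"],
        base_wavelength=g["base_wavelength"],
        octave_spacing=g["octave_spacing"], sigma_factor=g["sigma_factor"],
    )
    l1, l2, l3 = (cfg.layer_config(i) for i in (1, 2, 3))
    v1_shape = (256, 256, bank.n_channels)
    conn1 = build_v1_connectivity(
        v1_shape, l1, substream(cfg.seed, "connectivity-l1"),
        n_freq=g["n_freq"], n_orient=g["n_orient"], freq_ratio=g["freq_ratio"],
    )
    conn2 = build_layer_connectivity(l1.dims, l2, substream(cfg.seed, "connectivity-l2"))
    conn3 = build_layer_connectivity(l2.dims, l3, substream(cfg.seed, "connectivity-l3"))
    att = cfg["attractor"]
    rec = RecurrentWeights.zeros(l3.dims, sigma_d=att["sigma_d"], w_max=att["w_max"])
    return Model(cfg, bank, (l1, l2, l3), conn1, conn2, conn3, rec)


def _layer_forward(x_in: np.ndarray, conn: ConnectivityMap, lcfg: LayerConfig
                   ) -> np.ndarray:
    h = comp.activate(x_in, conn)
    if lcfg.inhibition_enabled:
        h = comp.lateral_inhibit(
            h, lcfg.inhibition_center_radius, lcfg.inhibition_surround_radius
        )
    y, _ = comp.set_sparseness(h, lcfg.sparseness)
    return y


def present(
    model: Model, img: GrayImage, gaze: GazeDirection | str, v1: V1Stack | None = None
) -> dict[str, np.ndarray]:
    """Pure feedforward inference pass; no weights are changed.

    Returns the rate maps {"layer1", "layer2", "layer3"} (each 32x32,
    non-negative, at the layer's sparseness target) plus the gain-modulated
    scene-frame input "layer3_input".
    """
    stack = v1 if v1 is not None else model.encode(img)
    l1cfg, l2cfg, l3cfg = model.layer_cfgs
    y1 = _layer_forward(stack.responses, model.conn_v1_l1, l1cfg)
    y2 = _layer_forward(y1, model.conn_l1_l2, l2cfg)
    x3 = remap_by_gaze(y2, gaze)
    y3 = _layer_forward(x3, model.conn_l2_l3, l3cfg)
    return {"layer1": y1, "layer2": y2, "layer3": y3, "layer3_input": x3}


def _jitter_image(img: GrayImage, shift: tuple[int, int]) -> GrayImage:
    out = np.zeros_like(img.pixels)
    dr, dc = shift
    h, w = img.pixels.shape
    src = img.pixels[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
    out[max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)] = src
    return GrayImage(out, label=f"{img.label}+shift{shift}")


def _train_one_layer(
    model: Model,
    layer: int,
    scene: SceneSpec,
    schedule: TrainingSchedule,
    rng: np.random.Generator,
    attractor_alpha: float,
) -> None:
    """Train a single layer for the full run of epochs, lower layers frozen."""
    lcfg = model.layer_cfgs[layer - 1]
    conn = (model.conn_v1_l1, model.conn_l1_l2, model.conn_l2_l3)[layer - 1]
    items = scene.items()

    def layer_input(patch: GrayImage, quadrant: str) -> np.ndarray:
        if layer == 1:
            return model.encode(patch).responses
        out = present(model, patch, quadrant)
        return out["layer1"] if layer == 2 else out["layer3_input"]

    # lower layers are frozen during this stage, so the layer input per
    # (patch, gaze) is stationary and can be computed once per epoch set
    cache: dict[str, np.ndarray] = {}
    for epoch in range(schedule.n_epochs):
        for k in rng.permutation(len(items)):
            quadrant, patch = items[k]
            trace = np.zeros(lcfg.dims)
            if schedule.jitter_enabled:
                shifts = [
                    (
                        int(rng.integers(-schedule.jitter_amplitude_px,
                                         schedule.jitter_amplitude_px + 1)),
                        int(rng.integers(-schedule.jitter_amplitude_px,
                                         schedule.jitter_amplitude_px + 1)),
                    )
                    for _ in range(schedule.jitter_n_transforms)
                ]
                inputs = [layer_input(_jitter_image(patch, s), quadrant)
                          for s in shifts]
            else:
                if quadrant not in cache:
                    cache[quadrant] = layer_input(patch, quadrant)
                inputs = [cache[quadrant]]
            n_total = schedule.n_buildup_presentations + schedule.n_update_presentations
            for p in range(n_total):
                x_in = inputs[p % len(inputs)]
                h = comp.activate(x_in, conn)
                if lcfg.inhibition_enabled:
                    h = comp.lateral_inhibit(
                        h, lcfg.inhibition_center_radius,
                        lcfg.inhibition_surround_radius,
                    )
                y, _ = comp.set_sparseness(h, lcfg.sparseness)
                trace = comp.trace_step(trace, y, lcfg.trace_eta)
                if p < schedule.n_buildup_presentations:
                    continue
                if layer == 1:
                    comp.hebb_update(conn, x_in, y, lcfg.alpha)
                else:
                    comp.trace_update(conn, x_in, trace, lcfg.alpha)
                if layer == 3:
                    from .scene import ca_update

                    # rates enter the recurrent rule on a 0-1 scale so the
                    # cumulative increments stay below the weight ceiling
                    # and the distance-weighted structure is not saturated
                    peak = y.max()
                    ca_update(model.recurrent, y / peak if peak > 0 else y,
                              attractor_alpha)
            model.log.append({
                "layer": layer, "epoch": epoch, "patch": patch.label,
                "gaze": quadrant, "mean_rate": float(y.mean()),
                "sparseness": comp.sparseness(y),
            })


def train(
    model: Model,
    scene: SceneSpec,
    schedule: TrainingSchedule | None = None,
    rng: np.random.Generator | int | None = None,
) -> Model:
    """Train the model on a whole scene.

    ``rng`` may be a Generator, an int seed, or None (the model config's
    schedule substream).  Training is deterministic given (model seed,
    schedule, rng seed).
    """
    if not scene.patches:
        raise ValueError("scene has no patches")
    schedule = schedule or TrainingSchedule.from_config(model.config)
    if rng is None:
        rng = substream(model.config.seed, "schedule")
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    att_alpha = model.config["attractor"]["alpha"]
    if schedule.sequential:
        for layer in (1, 2, 3):
            _train_one_layer(model, layer, scene, schedule, rng, att_alpha)
    else:
        # simultaneous mode: every layer updated in each epoch
        one = TrainingSchedule(
            1, schedule.n_update_presentations, schedule.n_buildup_presentations,
            True, schedule.jitter_enabled, schedule.jitter_amplitude_px,
            schedule.jitter_n_transforms,
        )
        for _ in range(schedule.n_epochs):
            for layer in (1, 2, 3):
                _train_one_layer(model, layer, scene, one, rng, att_alpha)
    return model


def save_model(model: Model, out_dir: str | Path) -> None:
    """Write a model archive: config snapshot, weight arrays, training log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.config.save(out / "config.yaml")
    np.savez_compressed(
        out / "weights.npz",
        v1_l1_indices=model.conn_v1_l1.indices,
        v1_l1_weights=model.conn_v1_l1.weights,
        l1_l2_indices=model.conn_l1_l2.indices,
        l1_l2_weights=model.conn_l1_l2.weights,
        l2_l3_indices=model.conn_l2_l3.indices,
        l2_l3_weights=model.conn_l2_l3.weights,
        recurrent=model.recurrent.W,
    )
    (out / "log.json").write_text(json.dumps(model.log, indent=1))


def load_model(in_dir: str | Path) -> Model:
    """Rebuild a model from an archive written by :func:`save_model`."""
    from .config import load_config

    src = Path(in_dir)
    cfg = load_config(src / "config.yaml")
    model = build_model(cfg)
    with np.load(src / "weights.npz") as z:
        model.conn_v1_l1.indices[:] = z["v1_l1_indices"]
        model.conn_v1_l1.weights[:] = z["v1_l1_weights"]
        model.conn_l1_l2.indices[:] = z["l1_l2_indices"]
        model.conn_l1_l2.weights[:] = z["l1_l2_weights"]
        model.conn_l2_l3.indices[:] = z["l2_l3_indices"]
        model.conn_l2_l3.weights[:] = z["l2_l3_weights"]
        model.recurrent.W[:] = z["recurrent"]
    log_path = src / "log.json"
    if log_path.exists():
        model.log = json.loads(log_path.read_text())
    return model
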