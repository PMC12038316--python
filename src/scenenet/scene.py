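"""Top-layer scene machinery: gaze-direction gain modulation and the
whole-scene continuous attractor.

Gain modulation places the fixation-patch representation from the middle
layer into the quadrant of the 32x32 whole-scene frame selected by the
current gaze direction (the patch is halved in size so four patches tile
the frame).  Recurrent associative weights between co-active scene-layer
neurons, scaled by a decreasing function of their distance, then form a
continuous attractor that stitches the scene together: nearby features end
up more strongly linked than distant ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .competitive import set_sparseness
from .topology import distance_matrix

SCENE_DIMS = (32, 32)
QUADRANT_OFFSETS = {"UL": (0, 0), "UR": (0, 16), "LL": (16, 0), "LR": (16, 16)}
# nominal world angle (azimuth, elevation) of each quadrant centre; the
# whole scene spans +-70 degrees of visual space
QUADRANT_ANGLES_DEG = {
    "UL": (-35.0, 35.0),
    "UR": (35.0, 35.0),
    "LL": (-35.0, -35.0),
    "LR": (35.0, -35.0),
}


@dataclass(frozen=True)
class GazeDirection:
    """World-based gaze direction, quantised to a scene quadrant."""

    quadrant: str

    def __post_init__(self) -> None:
        if self.quadrant not in QUADRANT_OFFSETS:
            raise ValueError(
                f"invalid quadrant {self.quadrant!r}; expected one of "
                f"{sorted(QUADRANT_OFFSETS)}"
            )

    @property
    def offset(self) -> tuple[int, int]:
        """(row0, col0) placement offset in the 32x32 scene frame."""
        return QUADRANT_OFFSETS[self.quadrant]

    @property
    def world_angle_deg(self) -> tuple[float, float]:
        """(azimuth, elevation) of the quadrant centre in degrees."""
        return QUADRANT_ANGLES_DEG[self.quadrant]


def remap_by_gaze(layer2_rates: np.ndarray, gaze: GazeDirection | str) -> np.ndarray:
    """Place the 32x32 fixation-patch rates into the scene frame.

    The rate map is reduced in size by two times (2x2 block averaging, which
    conserves total activity up to the averaging factor 4) and written into
    the gaze quadrant; all other entries are zero.
    """
    if isinstance(gaze, str):
        gaze = GazeDirection(gaze)
    r = np.asarray(layer2_rates, dtype=np.float64)
    if r.shape != (32, 32):
        raise ValueError(f"expected 32x32 rates, got {r.shape}")
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    half = r.reshape(16, 2, 16, 2).mean(axis=(1, 3))
    out = np.zeros(SCENE_DIMS, dtype=np.float64)
    r0, c0 = gaze.offset
    out[r0 : r0 + 16, c0 : c0 + 16] = half
    return out


@dataclass
class RecurrentWeights:
    """Symmetric, zero-diagonal, non-negative N x N associative weights of
    the scene-layer continuous attractor."""

    W: np.ndarray
    sigma_d: float = 4.0
    dims: tuple[int, int] = SCENE_DIMS
    w_max: float = 1.0
    _dist_kernel: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def zeros(cls, dims: tuple[int, int] = SCENE_DIMS, sigma_d: float = 4.0,
              w_max: float = 1.0) -> "RecurrentWeights":
        n = dims[0] * dims[1]
        return cls(np.zeros((n, n)), sigma_d=sigma_d, dims=dims, w_max=w_max)

    def distance_kernel(self) -> np.ndarray:
        """exp(-d_ij^2 / 2 sigma_d^2): the decreasing distance factor."""
        if self._dist_kernel is None:
            d = distance_matrix(self.dims)
            self._dist_kernel = np.exp(-(d**2) / (2.0 * self.sigma_d**2))
        return self._dist_kernel


def ca_update(
    weights: RecurrentWeights, y_map: np.ndarray, alpha: float
) -> RecurrentWeights:
    """Distance-weighted associative update of the recurrent weights.

    dw_ij = alpha * y_i * y_j * exp(-d_ij^2 / 2 sigma_d^2): co-active
    neuron pairs are linked, and the further apart they are in the scene
    frame the weaker the added link.  Symmetry and the zero diagonal are
    preserved; entries are clipped at ``w_max`` (logged growth cap).
    """
    if weights.sigma_d <= 0:
        raise ValueError("sigma_d must be positive")
    y = np.asarray(y_map, dtype=np.float64).ravel()
    if y.size != weights.W.shape[0]:
        raise ValueError("rate map size does not match recurrent weights")
    weights.W += alpha * np.outer(y, y) * weights.distance_kernel()
    np.fill_diagonal(weights.W, 0.0)
    np.clip(weights.W, 0.0, weights.w_max, out=weights.W)
    return weights


def ca_recall(
    weights: RecurrentWeights,
    cue_rates: np.ndarray,
    n_iter: int = 10,
    a_target: float = 0.08,
) -> np.ndarray:
    """Relax the attractor from a cue: iterate
    r <- set_sparseness(W r + cue) for ``n_iter`` steps.

    Returns the final non-negative rate map with sparseness ``a_target``.
    An all-zero cue with all-zero weights is degenerate and raises.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    cue = np.asarray(cue_rates, dtype=np.float64).ravel()
    if not cue.any() and not weights.W.any():
        raise ValueError("degenerate recall: all-zero cue and weights")
    r = cue.copy()
    for _ in range(n_iter):
        drive = weights.W @ r
        peak = drive.max()
        if peak > 0:  # global divisive inhibition: drive on a 0-1 scale
            drive /= peak
        r, _ = set_sparseness((drive + cue).reshape(weights.dims), a_target)
        r = r.ravel()
    return r.reshape(weights.dims)


def settle(
    weights: RecurrentWeights,
    init_rates: np.ndarray,
    a_target: float = 0.08,
    max_steps: int = 500,
    tol: float = 1e-9,
) -> np.ndarray:
    """Relax the cue-free attractor dynamics to a fixed point.

    Iterates r <- set_sparseness(W r / max(W r)) until the state changes by
    less than ``tol`` (sup norm) or ``max_steps`` is reached.  The settled
    state is the proper initial condition for the adaptation demonstration:
    from it the non-adapting dynamics are stationary, so any bump movement
    under adaptation is attributable to the adaptation alone.
    """
    r = np.asarray(init_rates, dtype=np.float64).ravel().copy()
    for _ in range(max_steps):
        drive = weights.W @ r
        peak = drive.max()
        if peak > 0:
            drive /= peak
        y, _ = set_sparseness(drive.reshape(weights.dims), a_target)
        y = y.ravel()
        if np.abs(y - r).max() < tol:
            r = y
            break
        r = y
    return r.reshape(weights.dims)


@dataclass
class AdaptationState:
    """Firing-rate adaptation used only to demonstrate the attractor's
    continuity: adapted neurons yield to unadapted neighbours, so the
    activity bump moves across the map.

    a_i >= 0 per neuron; ``decay`` is the trace constant lambda in [0, 1);
    ``strength`` beta >= 0 scales the subtractive adaptation current.  With
    beta = 0 the dynamics reduce to non-adapting recall.
    """

    a: np.ndarray
    decay: float = 0.9
    strength: float = 1.0

    @classmethod
    def fresh(cls, dims: tuple[int, int] = SCENE_DIMS, decay: float = 0.9,
              strength: float = 1.0) -> "AdaptationState":
        if not (0.0 <= decay < 1.0):
            raise ValueError("decay must lie in [0, 1)")
        if strength < 0:
            raise ValueError("strength must be >= 0")
        return cls(np.zeros(dims[0] * dims[1]), decay, strength)


def bump_dynamics(
    weights: RecurrentWeights,
    init_rates: np.ndarray,
    adaptation: AdaptationState,
    n_steps: int,
    a_target: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the adapting attractor and track the activity bump.

    Per step: a <- lambda a + (1 - lambda) r, then
    r <- set_sparseness(W r - beta a).  Returns ``(trajectory, centroids)``
    with trajectory shape (n_steps, rows, cols) and centroids shape
    (n_steps, 2) holding the rate-weighted mean (row, col) each step.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    r = np.asarray(init_rates, dtype=np.float64).ravel().copy()
    traj = np.empty((n_steps,) + weights.dims)
    cents = np.empty((n_steps, 2))
    for t in range(n_steps):
        adaptation.a = adaptation.decay * adaptation.a + (1.0 - adaptation.decay) * r
        drive = weights.W @ r
        peak = drive.max()
        if peak > 0:  # global divisive inhibition keeps rates on a 0-1 scale
            drive /= peak
        h = drive - adaptation.strength * adaptation.a
        y, _ = set_sparseness(h.reshape(weights.dims), a_target)
        r = y.ravel()
        traj[t] = y
        cents[t] = bump_centroid(y)
    return traj, cents


def bump_centroid(rate_map: np.ndarray) -> tuple[float, float]:
    """Rate-weighted mean (row, col) of an activity map."""
    r = np.asarray(rate_map, dtype=np.float64)
    total = r.sum()
    if total <= 0:
        raise ValueError("cannot take the centroid of an all-zero rate map")
    rows = np.arange(r.shape[0])[:, None]
    cols = np.arange(r.shape[1])[None, :]
    return float((r * rows).sum() / total), float((r * cols).sum() / total)
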