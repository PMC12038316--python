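"""Radius-limited topological connectivity between layers.

Each neuron in a layer receives a fixed number of afferents drawn from a
radially symmetric Gaussian probability kernel centred on the topologically
corresponding position in the source layer.  The layer's "radius" parameter
is calibrated so that the kernel places ~67% of its connection probability
within one radius of the aligned position: for a 2-D radial Gaussian,
P(r <= R) = 1 - exp(-R^2 / 2 sigma^2) = 0.67 gives sigma = R / 1.489.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# z with 1 - exp(-z^2/2) = 0.67, i.e. the 67%-containment calibration
CONTAINMENT_Z = float(np.sqrt(-2.0 * np.log(1.0 - 0.67)))

# kernel truncation, in units of sigma (no wraparound; renormalized)
TRUNCATION_SIGMAS = 4.0


@dataclass
class LayerConfig:
    """Architecture and learning parameters of one competitive layer.

    Defaults are not provided here; see :mod:`scenenet.config` for the
    standard three-layer architecture table.
    """

    n_rows: int
    n_cols: int
    n_connections: int
    radius: float
    sparseness: float
    alpha: float = 0.1
    trace_eta: float = 0.0
    inhibition_enabled: bool = True
    inhibition_center_radius: float = 0.2
    inhibition_surround_radius: float = 1.5

    def __post_init__(self) -> None:
        if self.n_connections < 1:
            raise ValueError("n_connections must be >= 1")
        if not (0.0 < self.sparseness <= 1.0):
            raise ValueError("sparseness must lie in (0, 1]")
        if not (0.0 <= self.trace_eta < 1.0):
            raise ValueError("trace_eta must lie in [0, 1)")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def dims(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_neurons(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class ConnectivityMap:
    """Afferent lists and weights for every neuron of a target layer.

    ``indices[t, k]`` is the k-th afferent of target neuron t as a flat
    index into the flattened source array (a 2-D layer or a 3-D V1 stack);
    ``weights[t, k]`` its synaptic weight.  Weight vectors are kept at unit
    Euclidean norm by initialisation and by every learning step.
    """

    source_shape: tuple[int, ...]
    target_dims: tuple[int, int]
    indices: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.indices.shape != self.weights.shape:
            raise ValueError("indices and weights must have the same shape")

    @property
    def n_targets(self) -> int:
        return self.indices.shape[0]

    @property
    def n_connections(self) -> int:
        return self.indices.shape[1]


def aligned_position(target_pos: tuple[int, int], target_dims: tuple[int, int],
                     source_dims: tuple[int, int]) -> tuple[float, float]:
    """Source-layer position topologically corresponding to ``target_pos``
    (proportional scaling of cell centres)."""
    tr, tc = target_pos
    sr = (tr + 0.5) * source_dims[0] / target_dims[0] - 0.5
    sc = (tc + 0.5) * source_dims[1] / target_dims[1] - 0.5
    return sr, sc


def connection_probabilities(
    center: tuple[float, float], source_dims: tuple[int, int], radius: float
) -> np.ndarray:
    """Gaussian connection-probability kernel over the source grid.

    Truncated at ``TRUNCATION_SIGMAS`` * sigma and at the grid edges (no
    wraparound), then renormalized to sum to 1.
    """
    sigma = radius / CONTAINMENT_Z
    rows = np.arange(source_dims[0])[:, None]
    cols = np.arange(source_dims[1])[None, :]
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    p = np.exp(-d2 / (2.0 * sigma**2))
    p[d2 > (TRUNCATION_SIGMAS * sigma) ** 2] = 0.0
    total = p.sum()
    if total <= 0:
        raise ValueError("empty connection kernel (radius too small for grid)")
    return p / total


def sample_afferents(
    target_pos: tuple[int, int],
    source_dims: tuple[int, int],
    n_connections: int,
    radius: float,
    rng: np.random.Generator,
    target_dims: tuple[int, int] | None = None,
    replace: bool = False,
) -> np.ndarray:
    """Draw afferent source indices (flat, into the source grid).

    Without replacement by default (no duplicate afferents).  If the
    truncated kernel support holds fewer than ``n_connections`` cells, the
    kernel scale is widened by 1.5x iteratively (logged).  Sampling *with*
    replacement draws i.i.d. from the connection-probability kernel itself,
    which is what the 67%-containment calibration describes.
    """
    if n_connections > source_dims[0] * source_dims[1] and not replace:
        raise ValueError(
            f"n_connections={n_connections} exceeds source size "
            f"{source_dims[0] * source_dims[1]}"
        )
    center = aligned_position(target_pos, target_dims or source_dims, source_dims)
    eff_radius = radius
    while True:
        p = connection_probabilities(center, source_dims, eff_radius)
        if replace or np.count_nonzero(p) >= n_connections:
            break
        eff_radius *= 1.5
        logger.info(
            "widening connection kernel at %s: radius %.3f -> %.3f",
            target_pos, radius, eff_radius,
        )
    flat_p = p.ravel()
    return rng.choice(flat_p.size, size=n_connections, replace=replace, p=flat_p)


def _local_window_probs(
    center: tuple[float, float], source_dims: tuple[int, int], radius: float
) -> tuple[int, int, np.ndarray]:
    """Connection-probability kernel restricted to its truncation window.

    Returns (row0, col0, p) where p covers source rows/cols starting at
    (row0, col0); p sums to 1.  Equivalent to
    :func:`connection_probabilities` (which is zero outside the window) but
    cheap on large source grids.
    """
    sigma = radius / CONTAINMENT_Z
    reach = TRUNCATION_SIGMAS * sigma
    r0 = max(0, int(np.ceil(center[0] - reach)))
    r1 = min(source_dims[0], int(np.floor(center[0] + reach)) + 1)
    c0 = max(0, int(np.ceil(center[1] - reach)))
    c1 = min(source_dims[1], int(np.floor(center[1] + reach)) + 1)
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    p = np.exp(-d2 / (2.0 * sigma**2))
    p[d2 > reach**2] = 0.0
    total = p.sum()
    if total <= 0:
        raise ValueError("empty connection kernel (radius too small for grid)")
    return r0, c0, p / total


def allocate_by_frequency(
    n_connections: int, n_freq: int = 4, ratio: float = 2.0
) -> np.ndarray:
    """Apportion V1 afferents across spatial-frequency bands.

    Counts are proportional to band frequency with geometric ``ratio`` per
    octave (band 0 = highest frequency gets the most), rounded by the
    largest-remainder method so they sum exactly to ``n_connections``.
    """
    if n_connections < n_freq:
        raise ValueError("n_connections must be >= n_freq")
    w = np.array([ratio ** (n_freq - 1 - f) for f in range(n_freq)], dtype=np.float64)
    quota = n_connections * w / w.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    # stable tie-break: earlier (higher-frequency) bands first
    order = np.argsort(-remainder, kind="stable")
    for f in order[: n_connections - counts.sum()]:
        counts[f] += 1
    return counts


def init_weights(n_afferents: int, rng: np.random.Generator) -> np.ndarray:
    """Positive uniform (0, 1] weights normalised to unit Euclidean norm."""
    if n_afferents < 1:
        raise ValueError("afferent list must be nonempty")
    w = 1.0 - rng.random(n_afferents)  # (0, 1]
    return w / np.linalg.norm(w)


def neuron_distance(i, j, dims: tuple[int, int]) -> float:
    """Euclidean distance between two neurons of a 2-D layer.

    ``i`` and ``j`` may be flat indices or (row, col) pairs.
    """
    def pos(k):
        if np.isscalar(k):
            k = int(k)
            if not 0 <= k < dims[0] * dims[1]:
                raise IndexError(f"neuron index {k} out of range for {dims}")
            return divmod(k, dims[1])
        r, c = k
        if not (0 <= r < dims[0] and 0 <= c < dims[1]):
            raise IndexError(f"neuron position {k} out of range for {dims}")
        return r, c

    (ri, ci), (rj, cj) = pos(i), pos(j)
    return float(np.hypot(ri - rj, ci - cj))


def distance_matrix(dims: tuple[int, int]) -> np.ndarray:
    """All-pairs Euclidean neuron distances, shape (N, N)."""
    rows, cols = np.divmod(np.arange(dims[0] * dims[1]), dims[1])
    return np.hypot(rows[:, None] - rows[None, :], cols[:, None] - cols[None, :])


def save_connectivity_csv(conn: ConnectivityMap, path) -> None:
    """Serialise connectivity as columnar text: target, source, weight."""
    n_t, n_c = conn.indices.shape
    targets = np.repeat(np.arange(n_t), n_c)
    table = np.column_stack([targets, conn.indices.ravel(), conn.weights.ravel()])
    np.savetxt(path, table, fmt=("%d", "%d", "%.12g"), delimiter=",",
               header="target_index,source_index,weight")


def build_layer_connectivity(
    source_dims: tuple[int, int],
    target_cfg: LayerConfig,
    rng: np.random.Generator,
) -> ConnectivityMap:
    """Connectivity from a 2-D source layer into ``target_cfg``'s layer."""
    n = target_cfg.n_neurons
    idx = np.empty((n, target_cfg.n_connections), dtype=np.int64)
    wts = np.empty_like(idx, dtype=np.float64)
    for t in range(n):
        pos = divmod(t, target_cfg.n_cols)
        idx[t] = sample_afferents(
            pos, source_dims, target_cfg.n_connections, target_cfg.radius, rng,
            target_dims=target_cfg.dims,
        )
        wts[t] = init_weights(target_cfg.n_connections, rng)
    return ConnectivityMap(source_dims, target_cfg.dims, idx, wts)


def build_v1_connectivity(
    v1_shape: tuple[int, int, int],
    target_cfg: LayerConfig,
    rng: np.random.Generator,
    n_freq: int = 4,
    n_orient: int = 4,
    freq_ratio: float = 2.0,
) -> ConnectivityMap:
    """Connectivity from the V1 stack (H, W, channels) into Layer 1.

    The spatial position of each afferent is drawn from the Gaussian kernel
    on the V1 pixel grid, with the layer radius scaled from neuron units to
    pixel units by the grid ratio (256/32 = 8 by default).  The channel is
    allocated per spatial-frequency band (more afferents to higher
    frequencies) with orientation and sign uniform within a band.
    Afferent (position, channel) pairs are unique per neuron.
    """
    h, w, n_chan = v1_shape
    if n_chan != n_freq * n_orient * 2:
        raise ValueError("V1 channel count inconsistent with n_freq/n_orient")
    scale = h / target_cfg.n_rows
    radius_px = target_cfg.radius * scale
    counts = allocate_by_frequency(target_cfg.n_connections, n_freq, freq_ratio)
    n = target_cfg.n_neurons
    idx = np.empty((n, target_cfg.n_connections), dtype=np.int64)
    wts = np.empty_like(idx, dtype=np.float64)
    for t in range(n):
        pos = divmod(t, target_cfg.n_cols)
        center = aligned_position(pos, target_cfg.dims, (h, w))
        r0, c0, p = _local_window_probs(center, (h, w), radius_px)
        flat_p = p.ravel()
        chosen: set[int] = set()
        flat: list[int] = []
        # draw spatial positions from the kernel, channels uniform per band;
        # re-draw on the rare (position, channel) collision to keep afferents unique
        for f in range(n_freq):
            for _ in range(counts[f]):
                while True:
                    loc = int(rng.choice(flat_p.size, p=flat_p))
                    sr, sc = r0 + loc // p.shape[1], c0 + loc % p.shape[1]
                    chan = (f * n_orient + rng.integers(n_orient)) * 2 + rng.integers(2)
                    flat_idx = (sr * w + sc) * n_chan + int(chan)
                    if flat_idx not in chosen:
                        chosen.add(flat_idx)
                        flat.append(flat_idx)
                        break
        idx[t] = flat
        wts[t] = init_weights(target_cfg.n_connections, rng)
    return ConnectivityMap(v1_shape, target_cfg.dims, idx, wts)
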