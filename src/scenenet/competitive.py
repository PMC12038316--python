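"""One competitive layer: dot-product activation, Mexican-hat lateral
inhibition, sparseness-constrained threshold-linear output, and the
associative / memory-trace learning rules.

Competition is implemented algorithmically rather than with an explicit
inhibitory population: lateral inhibition is a difference-of-Gaussians
convolution of the activations, and the global threshold of the
threshold-linear activation function is set so that the population
sparseness of the rates

    a = (sum_i y_i / n)^2 / (sum_i y_i^2 / n)

matches a per-layer target.  For binary rates a is simply the fraction of
active neurons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.ndimage import convolve as _nd_convolve

from .topology import ConnectivityMap

logger = logging.getLogger(__name__)

SPARSENESS_TOL = 1e-3
_BISECT_MAX_ITER = 60


@dataclass
class LayerState:
    """Mutable per-layer state during a presentation sequence."""

    activations: np.ndarray      # h, pre-threshold (post-inhibition)
    rates: np.ndarray            # y = max(0, h - theta)
    threshold: float
    trace: np.ndarray            # y-bar, short-term memory trace
    time_index: int = 0


def activate(rates_in: np.ndarray, connectivity: ConnectivityMap) -> np.ndarray:
    """Synaptically weighted input sum for every target neuron.

    h_i = sum_j w_ij x_j over neuron i's afferent list (an inner product of
    its weight vector with the gathered source rates).
    """
    x = np.asarray(rates_in, dtype=np.float64)
    if x.shape != tuple(connectivity.source_shape):
        raise ValueError(
            f"input shape {x.shape} does not match connectivity source "
            f"{connectivity.source_shape}"
        )
    gathered = x.ravel()[connectivity.indices]
    h = np.einsum("tk,tk->t", connectivity.weights, gathered)
    return h.reshape(connectivity.target_dims)


@lru_cache(maxsize=8)
def _dog_kernel(center_radius: float, surround_radius: float) -> np.ndarray:
    hw = int(np.ceil(4.0 * surround_radius))
    y, x = np.mgrid[-hw : hw + 1, -hw : hw + 1].astype(np.float64)
    d2 = x**2 + y**2
    g_c = np.exp(-d2 / (2.0 * center_radius**2))
    g_s = np.exp(-d2 / (2.0 * surround_radius**2))
    k = g_c / g_c.sum() - g_s / g_s.sum()
    k -= k.mean()  # exact zero sum after the two normalisations
    return k


def lateral_inhibit(
    h_map: np.ndarray, center_radius: float = 0.2, surround_radius: float = 1.5
) -> np.ndarray:
    """Mexican-hat (difference of Gaussians) lateral inhibition.

    The centre and surround Gaussians are normalised to equal mass so the
    filter sums to zero; borders are reflective.
    """
    if center_radius <= 0 or surround_radius <= 0:
        raise ValueError("radii must be positive")
    if center_radius >= surround_radius:
        raise ValueError("center_radius must be smaller than surround_radius")
    k = _dog_kernel(float(center_radius), float(surround_radius))
    return _nd_convolve(np.asarray(h_map, dtype=np.float64), k, mode="reflect")


def sparseness(y: np.ndarray) -> float:
    """Population sparseness a = (mean y)^2 / (mean y^2); 0 for all-zero y."""
    y = np.asarray(y, dtype=np.float64).ravel()
    ssq = float(np.mean(y**2))
    if ssq == 0.0:
        return 0.0
    return float(np.mean(y)) ** 2 / ssq


def set_sparseness(
    h_map: np.ndarray, a_target: float, tol: float = SPARSENESS_TOL
) -> tuple[np.ndarray, float]:
    """Threshold-linear rates with the threshold set to meet a sparseness
    target.

    Returns ``(y, theta)`` with ``y = max(0, h - theta)`` and theta found by
    bisection on [min(h), max(h)]; the sparseness of the thresholded rates
    decreases (at the resolution of distinct activation values) as theta
    rises, from its value at theta = min(h) down to 1/n.  A constant
    activation map is degenerate: all-zero rates are returned with a
    logged warning.
    """
    if not (0.0 < a_target <= 1.0):
        raise ValueError("a_target must lie in (0, 1]")
    h = np.asarray(h_map, dtype=np.float64)
    # the search range includes 0 so an already-satisfying map keeps theta=0
    lo, hi = min(float(h.min()), 0.0), float(h.max())
    if float(h.max()) - float(h.min()) < 1e-300:
        logger.warning("constant activation map: returning all-zero rates")
        return np.zeros_like(h), 0.0

    def a_of(theta: float) -> float:
        return sparseness(np.maximum(h - theta, 0.0))

    best_theta, best_err = lo, abs(a_of(lo) - a_target)
    for _ in range(_BISECT_MAX_ITER):
        mid = 0.5 * (lo + hi)
        a_mid = a_of(mid)
        err = abs(a_mid - a_target)
        if err < best_err or (err == best_err and mid < best_theta):
            best_theta, best_err = mid, err
        if err <= tol:
            break
        if a_mid > a_target:
            lo = mid
        else:
            hi = mid
    theta = best_theta
    return np.maximum(h - theta, 0.0), theta


def _assoc_update(
    connectivity: ConnectivityMap,
    x: np.ndarray,
    post: np.ndarray,
    alpha: float,
) -> ConnectivityMap:
    """Shared associative update: dw_j = alpha * post * x_j, then each
    updated weight vector is renormalised to unit Euclidean norm.

    Neurons with zero postsynaptic term are left untouched (their update is
    identically zero), so their stored weights are bit-identical before and
    after.  The connectivity is modified in place and returned.
    """
    if alpha <= 0:
        raise ValueError("learning rate alpha must be positive")
    post = np.asarray(post, dtype=np.float64).ravel()
    active = post > 0
    if not np.any(active):
        return connectivity
    xa = np.asarray(x, dtype=np.float64).ravel()[connectivity.indices[active]]
    w = connectivity.weights[active] + alpha * post[active, None] * xa
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    connectivity.weights[active] = w
    return connectivity


def hebb_update(
    connectivity: ConnectivityMap, x: np.ndarray, y: np.ndarray, alpha: float
) -> ConnectivityMap:
    """Purely associative (Hebbian) weight update dw_j = alpha * y * x_j."""
    return _assoc_update(connectivity, x, y, alpha)


def trace_step(trace_prev: np.ndarray, y: np.ndarray, eta: float) -> np.ndarray:
    """Short-term memory trace update: ybar = (1 - eta) y + eta ybar_prev.

    eta = 0 means no trace (ybar equals the instantaneous rate exactly).
    """
    if not (0.0 <= eta < 1.0):
        raise ValueError("eta must lie in [0, 1)")
    return (1.0 - eta) * np.asarray(y, dtype=np.float64) + eta * np.asarray(
        trace_prev, dtype=np.float64
    )


def trace_update(
    connectivity: ConnectivityMap, x: np.ndarray, trace: np.ndarray, alpha: float
) -> ConnectivityMap:
    """Memory-trace learning rule dw_j = alpha * ybar * x_j.

    With eta = 0 the trace equals the instantaneous rate and this is
    bit-identical to :func:`hebb_update`.
    """
    return _assoc_update(connectivity, x, trace, alpha)
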