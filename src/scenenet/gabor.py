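"""V1-like front end: a Gabor filter bank with sign-split rectified channels.

The input image is encoded by 4 spatial frequencies x 4 orientations x 2
signs = 32 channels of non-negative "firing rates" on the full pixel grid,
emulating V1 simple cells.  The two signs of a (frequency, orientation)
pair are the half-wave rectified positive and negative parts of the same
linear filter response, so each underlying response is carried by exactly
one of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .stimuli import GrayImage

N_FREQ = 4
N_ORIENT = 4
DEFAULT_WAVELENGTHS = (4.0, 8.0, 16.0, 32.0)  # pixels, octave spaced, high->low freq


@dataclass
class GaborBank:
    """Even-symmetric Gabor kernels indexed by (frequency, orientation, sign).

    ``kernels[f][o]`` is the positive-sign kernel for frequency band ``f``
    (band 0 = highest spatial frequency) and carrier orientation ``o``
    (0, 45, 90, 135 degrees); the negative-sign kernel is its negation.
    Channel index = (f * n_orient + o) * 2 + s with s in {0: +, 1: -}.
    """

    kernels: list[list[np.ndarray]]
    wavelengths: tuple[float, ...]
    orientations_deg: tuple[float, ...]
    sigma_factor: float = 0.5

    @property
    def n_freq(self) -> int:
        return len(self.wavelengths)

    @property
    def n_orient(self) -> int:
        return len(self.orientations_deg)

    @property
    def n_channels(self) -> int:
        return self.n_freq * self.n_orient * 2

    def channel_index(self, f: int, o: int, sign: int) -> int:
        return (f * self.n_orient + o) * 2 + sign

    def half_width(self, f: int) -> int:
        return (self.kernels[f][0].shape[0] - 1) // 2

    def preferred_stimulus_orientation_deg(self, o: int) -> float:
        """Orientation of the bar/grating a channel prefers (carrier + 90)."""
        return (self.orientations_deg[o] + 90.0) % 180.0


def _gabor_kernel(wavelength: float, theta_rad: float, sigma: float) -> np.ndarray:
    hw = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-hw : hw + 1, -hw : hw + 1].astype(np.float64)
    xr = x * np.cos(theta_rad) + y * np.sin(theta_rad)
    env = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    k = env * np.cos(2.0 * np.pi * xr / wavelength)
    k -= k.mean()  # exact DC balance
    k /= np.linalg.norm(k)
    k -= k.mean()  # re-balance after scaling (numerically exact to ~1e-17)
    return k


def build_gabor_bank(
    n_freq: int = N_FREQ,
    n_orient: int = N_ORIENT,
    base_wavelength: float = 4.0,
    octave_spacing: float = 2.0,
    sigma_factor: float = 0.5,
) -> GaborBank:
    """Construct the filter bank.

    Wavelengths are ``base_wavelength * octave_spacing**f`` for band f;
    orientations are uniform over 180 degrees; the Gaussian envelope width
    is ``sigma_factor * wavelength`` (aspect ratio 1, cosine phase).  Every
    kernel is mean-subtracted to zero DC response.
    """
    if n_freq < 1 or n_orient < 1:
        raise ValueError("n_freq and n_orient must be >= 1")
    wavelengths = tuple(base_wavelength * octave_spacing**f for f in range(n_freq))
    orientations = tuple(180.0 * o / n_orient for o in range(n_orient))
    kernels = [
        [
            _gabor_kernel(lam, np.deg2rad(theta), sigma_factor * lam)
            for theta in orientations
        ]
        for lam in wavelengths
    ]
    return GaborBank(kernels, wavelengths, orientations, sigma_factor)


@dataclass
class V1Stack:
    """Non-negative V1 responses, shape (H, W, n_channels).

    These are the presynaptic input rates to Layer 1.
    """

    responses: np.ndarray

    def __post_init__(self) -> None:
        if self.responses.ndim != 3:
            raise ValueError("V1Stack requires (H, W, channels)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.responses.shape  # type: ignore[return-value]


def save_v1_stack(stack: "V1Stack", path) -> None:
    """Export a V1 stack to a compressed array container for inspection."""
    np.savez_compressed(path, responses=stack.responses)


def load_v1_stack(path) -> "V1Stack":
    with np.load(path) as z:
        return V1Stack(z["responses"])


def _filter_linear(pixels: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size linear filtering with reflective borders."""
    hw = (kernel.shape[0] - 1) // 2
    padded = np.pad(pixels, hw, mode="reflect")
    return fftconvolve(padded, kernel, mode="valid")


def encode(img: GrayImage, bank: GaborBank, expected_size: int | None = 256) -> V1Stack:
    """Encode an image into the V1 channel stack.

    The image is mean-subtracted, filtered by each (f, o) kernel with
    reflective borders, and each linear response split into half-rectified
    positive and negative channels.  All outputs are >= 0.
    """
    h, w = img.shape
    if expected_size is not None and (h, w) != (expected_size, expected_size):
        raise ValueError(
            f"expected a {expected_size}x{expected_size} image, got {h}x{w}"
        )
    pixels = img.pixels - img.pixels.mean()
    out = np.empty((h, w, bank.n_channels), dtype=np.float64)
    for f in range(bank.n_freq):
        for o in range(bank.n_orient):
            lin = _filter_linear(pixels, bank.kernels[f][o])
            out[:, :, bank.channel_index(f, o, 0)] = np.maximum(lin, 0.0)
            out[:, :, bank.channel_index(f, o, 1)] = np.maximum(-lin, 0.0)
    return V1Stack(out)
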