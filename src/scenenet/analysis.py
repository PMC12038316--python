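"""Receptive-field mapping by systematic probe patches, selectivity
metrics, and figure-style rate-map exports.

The receptive field of a neuron is mapped by cutting a small probe
(typically 32x32 pixels) out of the whole 256x256 image, presenting it at
its true location on a zero background, and recording the neuron's rate
while the probe is stepped in 2-pixel increments over the image: a
((256-32)/2 + 1)^2 = 113x113 response lattice.  The forward pass is the
same as during training (lateral inhibition and sparseness-setting
included), with the threshold re-solved for every probe.

Because a probe image is zero outside a small square, its Gabor responses
are nonzero only within one kernel half-width of the square.  The mapper
exploits this: each probe is filtered on a small window with cached kernel
FFTs, which is numerically identical to encoding the full probe image
(reflective borders included) but orders of magnitude faster.  The
equivalence is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.fft import irfft2, next_fast_len, rfft2

from . import competitive as comp
from .gabor import GaborBank
from .scene import GazeDirection, remap_by_gaze
from .stimuli import GrayImage, write_image
from .training import Model

PROBE_SIZE = 32
PROBE_STEP = 2

# angular calibration: one 256-px fixation patch subtends 70 degrees, so
# the 2x2-patch whole scene spans +-70 degrees
DEGREES_PER_PATCH = 70.0
DEG_PER_PX = DEGREES_PER_PATCH / 256.0


@dataclass
class ReceptiveFieldMap:
    """Probe-response grid for one neuron."""

    responses: np.ndarray          # (n_lattice, n_lattice), >= 0
    probe_size: int
    step: int
    layer: int
    neuron: tuple[int, int]

    @property
    def lattice_shape(self) -> tuple[int, int]:
        return self.responses.shape  # type: ignore[return-value]

    def peak(self) -> tuple[int, int]:
        """Probe top-left (row, col) in image pixels at the peak response."""
        idx = np.unravel_index(np.argmax(self.responses), self.responses.shape)
        return int(idx[0] * self.step), int(idx[1] * self.step)

    def half_max_area_px(self) -> float:
        """Area (in image px^2) of the lattice region above half the peak."""
        peak = self.responses.max()
        if peak <= 0:
            return 0.0
        n_above = int(np.count_nonzero(self.responses >= 0.5 * peak))
        return n_above * self.step**2

    def equivalent_diameter(self) -> tuple[float, float]:
        """Diameter of the circle with the half-max area, in (px, degrees)."""
        d_px = 2.0 * np.sqrt(self.half_max_area_px() / np.pi)
        return float(d_px), float(d_px * DEG_PER_PX)


class _BandConvolver:
    """Windowed Gabor filtering with cached kernel FFTs.

    For a probe square at (r0, c0), the band-f linear responses are nonzero
    only on the square dilated by the kernel half-width h_f.  The window of
    the reflect-padded probe image covering that region (padded by h_f) is
    convolved 'valid' with each orientation kernel, reusing one forward FFT
    of the window across orientations and precomputing each kernel's FFT
    per window shape.
    """

    def __init__(self, bank: GaborBank, image_size: int):
        self.bank = bank
        self.size = image_size
        self.hw = [bank.half_width(f) for f in range(bank.n_freq)]
        self.hw_max = max(self.hw)
        self._kernel_ffts: dict[tuple[int, int, tuple[int, int]], np.ndarray] = {}

    def padded_probe(self, pixels: np.ndarray, r0: int, c0: int, probe: int
                     ) -> np.ndarray:
        """Reflect-padded (by hw_max) image of the probe on zero background."""
        full = np.zeros((self.size, self.size))
        full[r0 : r0 + probe, c0 : c0 + probe] = pixels[
            r0 : r0 + probe, c0 : c0 + probe
        ]
        return np.pad(full, self.hw_max, mode="reflect")

    def band_responses(self, padded: np.ndarray, r0: int, c0: int, probe: int,
                       f: int) -> tuple[np.ndarray, tuple[int, int]]:
        """Linear responses of band f's orientations on the support region.

        Returns (lin, (row_origin, col_origin)) where lin has shape
        (n_orient, H, W) covering image rows/cols [origin, origin + H/W).
        """
        h = self.hw[f]
        out_r0, out_r1 = max(0, r0 - h), min(self.size, r0 + probe + h)
        out_c0, out_c1 = max(0, c0 - h), min(self.size, c0 + probe + h)
        win = padded[
            out_r0 - h + self.hw_max : out_r1 + h + self.hw_max,
            out_c0 - h + self.hw_max : out_c1 + h + self.hw_max,
        ]
        ksize = 2 * h + 1
        full_shape = (win.shape[0] + ksize - 1, win.shape[1] + ksize - 1)
        fshape = (next_fast_len(full_shape[0]), next_fast_len(full_shape[1]))
        fwin = rfft2(win, fshape)
        n_o = self.bank.n_orient
        lin = np.empty((n_o, out_r1 - out_r0, out_c1 - out_c0))
        for o in range(n_o):
            key = (f, o, fshape)
            if key not in self._kernel_ffts:
                self._kernel_ffts[key] = rfft2(self.bank.kernels[f][o], fshape)
            conv = irfft2(fwin * self._kernel_ffts[key], fshape)
            # 'valid' part of the full linear convolution
            lin[o] = conv[ksize - 1 : win.shape[0], ksize - 1 : win.shape[1]]
        return lin, (out_r0, out_c0)


def _probe_layer1_activation(
    model: Model, convolver: _BandConvolver, pixels: np.ndarray,
    r0: int, c0: int, probe: int,
    aff_rows: np.ndarray, aff_cols: np.ndarray,
    aff_band: np.ndarray, aff_orient: np.ndarray, aff_sign: np.ndarray,
) -> np.ndarray:
    """Layer-1 activations for one probe via the windowed fast path."""
    padded = convolver.padded_probe(pixels, r0, c0, probe)
    x = np.zeros(aff_rows.shape)
    for f in range(model.bank.n_freq):
        lin, (orow, ocol) = convolver.band_responses(padded, r0, c0, probe, f)
        sel = aff_band == f
        rr, cc = aff_rows[sel] - orow, aff_cols[sel] - ocol
        inside = (rr >= 0) & (rr < lin.shape[1]) & (cc >= 0) & (cc < lin.shape[2])
        vals = np.zeros(rr.shape)
        ii = np.where(inside)
        vals[ii] = lin[aff_orient[sel][ii], rr[ii], cc[ii]]
        signs = aff_sign[sel]
        vals = np.where(signs == 0, np.maximum(vals, 0.0), np.maximum(-vals, 0.0))
        x[sel] = vals
    h = np.einsum("tk,tk->t", model.conn_v1_l1.weights, x)
    return h.reshape(model.layer_cfgs[0].dims)


def map_receptive_field(
    model: Model,
    img: GrayImage,
    layer: int,
    neuron: int | tuple[int, int],
    gaze: GazeDirection | str = "UL",
    probe_size: int = PROBE_SIZE,
    step: int = PROBE_STEP,
    frozen_thresholds: tuple[float, float, float] | None = None,
) -> ReceptiveFieldMap:
    """Map one neuron's receptive field over ``img`` with moving probes.

    For every lattice position, the probe (the ``probe_size`` crop placed
    at its true location on a zero background) is run through the standard
    forward pass under ``gaze`` and the neuron's rate recorded.  By default
    the sparseness threshold is re-solved per probe, exactly as during
    training; ``frozen_thresholds`` instead fixes the per-layer thresholds
    (e.g. those of a reference presentation of the whole image).
    """
    h, w = img.shape
    if probe_size > min(h, w):
        raise ValueError("probe larger than image")
    if layer not in (1, 2, 3):
        raise ValueError("layer must be 1, 2 or 3")
    dims = model.layer_cfgs[layer - 1].dims
    if np.isscalar(neuron):
        neuron = divmod(int(neuron), dims[1])
    nr, nc = neuron
    if not (0 <= nr < dims[0] and 0 <= nc < dims[1]):
        raise IndexError(f"neuron {neuron} out of range for layer {layer}")

    n_lat = (h - probe_size) // step + 1
    out = np.zeros((n_lat, n_lat))
    convolver = _BandConvolver(model.bank, h)
    aff = model.conn_v1_l1.indices
    n_chan = model.bank.n_channels
    aff_pix, aff_chan = np.divmod(aff, n_chan)
    aff_rows, aff_cols = np.divmod(aff_pix, w)
    aff_sign = aff_chan % 2
    fo = aff_chan // 2
    aff_band, aff_orient = np.divmod(fo, model.bank.n_orient)
    l1cfg, l2cfg, l3cfg = model.layer_cfgs

    for i in range(n_lat):
        for j in range(n_lat):
            r0, c0 = i * step, j * step
            if not img.pixels[r0 : r0 + probe_size, c0 : c0 + probe_size].any():
                continue  # empty probe -> zero response everywhere
            h1 = _probe_layer1_activation(
                model, convolver, img.pixels, r0, c0, probe_size,
                aff_rows, aff_cols, aff_band, aff_orient, aff_sign,
            )
            if l1cfg.inhibition_enabled:
                h1 = comp.lateral_inhibit(
                    h1, l1cfg.inhibition_center_radius,
                    l1cfg.inhibition_surround_radius,
                )
            theta = frozen_thresholds[0] if frozen_thresholds else None
            y1 = _threshold(h1, l1cfg, theta)
            if layer == 1:
                out[i, j] = y1[nr, nc]
                continue
            theta = frozen_thresholds[1] if frozen_thresholds else None
            y2 = _forward_one(y1, model.conn_l1_l2, l2cfg, theta)
            if layer == 2:
                out[i, j] = y2[nr, nc]
                continue
            x3 = remap_by_gaze(y2, gaze)
            theta = frozen_thresholds[2] if frozen_thresholds else None
            y3 = _forward_one(x3, model.conn_l2_l3, l3cfg, theta)
            out[i, j] = y3[nr, nc]
    return ReceptiveFieldMap(out, probe_size, step, layer, (nr, nc))


def _threshold(hmap, lcfg, frozen_theta=None):
    if frozen_theta is not None:
        return np.maximum(hmap - frozen_theta, 0.0)
    y, _ = comp.set_sparseness(hmap, lcfg.sparseness)
    return y


def _forward_one(x_in, conn, lcfg, frozen_theta=None):
    hmap = comp.activate(x_in, conn)
    if lcfg.inhibition_enabled:
        hmap = comp.lateral_inhibit(
            hmap, lcfg.inhibition_center_radius, lcfg.inhibition_surround_radius
        )
    return _threshold(hmap, lcfg, frozen_theta)


def selectivity_index(rate_a: float, rate_b: float) -> float:
    """|A - B| / (A + B) in [0, 1]; 1 = responds to one stimulus only."""
    if rate_a < 0 or rate_b < 0:
        raise ValueError("rates must be non-negative")
    total = rate_a + rate_b
    if total == 0:
        raise ValueError("selectivity undefined for two zero rates")
    return abs(rate_a - rate_b) / total


def export_rate_map(rates: np.ndarray, path: str | Path) -> tuple[Path, Path]:
    """Write a 2-D rate map as a CSV grid and a grayscale PNG heatmap.

    PNG intensities are the rates scaled to [0, 1] (max maps to 255 for any
    nonzero map); an all-zero map gives a uniform black image.  Returns the
    (csv_path, png_path) pair.
    """
    rates = np.asarray(rates, dtype=np.float64)
    if rates.ndim != 2:
        raise ValueError("rate map must be 2-D")
    base = Path(path)
    csv_path = base.with_suffix(".csv")
    png_path = base.with_suffix(".png")
    try:
        np.savetxt(csv_path, rates, delimiter=",", fmt="%.10g")
        peak = rates.max()
        scaled = rates / peak if peak > 0 else rates
        write_image(GrayImage(scaled), png_path)
    except OSError as exc:
        raise OSError(f"failed writing rate map to {base}: {exc}") from exc
    return csv_path, png_path
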