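"""Fixation-patch stimuli: alphanumeric glyph patches, 1/f "natural-like"
images, and image file I/O.

A *fixation patch* is the part of a scene encoded during one visual
fixation: a 256x256 grayscale image that is the unit stimulus fed to the
V1 front-end.  A whole scene is an ordered set of such patches, each tagged
with the gaze direction (scene quadrant) under which it was fixated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from ._font import GLYPH_HEIGHT, GLYPH_WIDTH, glyph_bitmap

PATCH_SIZE = 256

__all__ = [
    "GrayImage",
    "GlyphGrid",
    "SceneSpec",
    "render_glyph_patch",
    "make_natural_like",
    "read_image",
    "write_image",
    "digits_patch",
    "letters_patch",
]


@dataclass
class GrayImage:
    """A 2-D luminance field with values in [0, 1]."""

    pixels: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage requires a 2-D pixel array")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-12 or hi > 1 + 1e-12:
            raise ValueError(f"luminance values must lie in [0, 1], got [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class GlyphGrid:
    """A 3x3 arrangement of glyph identifiers forming one fixation patch.

    ``offset_lr`` displaces the lower-right glyph only, by (dx, dy) pixels;
    the small offset breaks the symmetry of the grid so that the topology of
    the learned maps can be traced through the network layers.
    """

    glyphs: tuple[tuple[str, str, str], ...]
    offset_lr: tuple[int, int] = (3, 3)

    def __post_init__(self) -> None:
        if len(self.glyphs) != 3 or any(len(row) != 3 for row in self.glyphs):
            raise ValueError("GlyphGrid requires a 3x3 grid of glyph ids")


@dataclass
class SceneSpec:
    """A whole scene: fixation patches keyed by gaze quadrant.

    Quadrant labels are UL, UR, LL, LR (upper/lower x left/right).  At least
    one quadrant must be populated; each label may appear once.
    """

    patches: dict[str, GrayImage]
    name: str = "scene"

    _QUADRANTS = ("UL", "UR", "LL", "LR")

    def __post_init__(self) -> None:
        if not self.patches:
            raise ValueError("SceneSpec requires at least one populated quadrant")
        bad = [q for q in self.patches if q not in self._QUADRANTS]
        if bad:
            raise ValueError(f"invalid quadrant labels: {bad}; expected {self._QUADRANTS}")

    def items(self):
        """(quadrant, patch) pairs in a fixed canonical order."""
        return [(q, self.patches[q]) for q in self._QUADRANTS if q in self.patches]


def render_glyph_patch(grid: GlyphGrid, size: int = PATCH_SIZE, scale: int = 6,
                       invert: bool = False) -> GrayImage:
    """Rasterise a 3x3 glyph grid into a ``size`` x ``size`` patch.

    Glyph strokes are 1 on a 0 background (``invert=True`` gives black
    strokes on white).  The 3x3 cell lattice spans the
    central 75% of the field; each 5x7 bitmap is upscaled by nearest
    neighbour (factor ``scale``) and centred in its cell.  The lower-right
    glyph is shifted by ``grid.offset_lr``.  Rendering is deterministic.
    """
    img = np.zeros((size, size), dtype=np.float64)
    span = int(round(size * 0.75))
    cell = span // 3
    origin = (size - span) // 2
    gh, gw = GLYPH_HEIGHT * scale, GLYPH_WIDTH * scale
    if gh > cell or gw > cell:
        raise ValueError(f"glyph ({gh}x{gw}) does not fit cell ({cell}x{cell})")
    labels = []
    for gr in range(3):
        for gc in range(3):
            char = grid.glyphs[gr][gc]
            bmp = glyph_bitmap(char)  # raises KeyError naming unknown ids
            big = np.kron(bmp, np.ones((scale, scale)))
            r0 = origin + gr * cell + (cell - gh) // 2
            c0 = origin + gc * cell + (cell - gw) // 2
            if (gr, gc) == (2, 2):
                dx, dy = grid.offset_lr
                r0 += dy
                c0 += dx
            img[r0 : r0 + gh, c0 : c0 + gw] = np.maximum(
                img[r0 : r0 + gh, c0 : c0 + gw], big
            )
            labels.append(char)
    if invert:
        img = 1.0 - img
    return GrayImage(img, label="".join(labels).strip())


def make_natural_like(
    seed: int, size: int = PATCH_SIZE, spectrum_exponent: float = 1.0
) -> GrayImage:
    """Procedural natural-like image: isotropic noise with a 1/f^exponent
    amplitude spectrum, rescaled to [0, 1].

    ``spectrum_exponent`` = 1 gives the ~1/f amplitude (1/f^2 power) falloff
    characteristic of natural scenes; 0 gives white noise.  Reproducible
    from ``seed``.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((size, size))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # DC handled separately
    amp = f ** (-float(spectrum_exponent))
    amp[0, 0] = 0.0
    field = np.fft.ifft2(np.fft.fft2(white) * amp).real
    lo, hi = field.min(), field.max()
    if hi - lo < 1e-30:
        field = np.zeros_like(field)
    else:
        field = (field - lo) / (hi - lo)
    return GrayImage(field, label=f"natural-like(seed={seed})")


def digits_patch(offset_lr: tuple[int, int] = (3, 3)) -> GrayImage:
    """The digits 1-9 fixation patch (scene patch 1 of the worked demos)."""
    return render_glyph_patch(
        GlyphGrid((("1", "2", "3"), ("4", "5", "6"), ("7", "8", "9")), offset_lr)
    )


def letters_patch(offset_lr: tuple[int, int] = (3, 3)) -> GrayImage:
    """The letters A-I fixation patch (scene patch 2 of the worked demos)."""
    return render_glyph_patch(
        GlyphGrid((("A", "B", "C"), ("D", "E", "F"), ("G", "H", "I")), offset_lr)
    )


def read_image(path: str | Path) -> GrayImage:
    """Read a PNG or PGM image as luminance in [0, 1].

    Colour inputs are converted to luminance (ITU-R 601 weights, via PIL
    mode "L").  Missing files raise FileNotFoundError; other formats raise
    ValueError naming the format.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            if im.format not in ("PNG", "PPM"):  # PIL reports PGM as PPM family
                raise ValueError(f"unsupported image format {im.format!r} for {path}")
            arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
    except UnidentifiedImageError as exc:
        raise ValueError(f"unsupported image format for {path}") from exc
    return GrayImage(arr, label=path.stem)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write a GrayImage as 8-bit PNG or PGM (by file extension)."""
    path = Path(path)
    data = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    pil = Image.fromarray(data, mode="L")
    ext = path.suffix.lower()
    if ext == ".png":
        pil.save(path, format="PNG")
    elif ext == ".pgm":
        pil.save(path, format="PPM")
    else:
        raise ValueError(f"unsupported output extension {ext!r}; use .png or .pgm")
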