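"""Render the demonstration fixation patches.

Builds the two alphanumeric 3x3 glyph patches (digits and letters, with the
lower-right glyph offset by 3 px so the map topology can be traced through
the network) and a seeded 1/f natural-like image, and writes them as PNGs.
"""

from pathlib import Path

import scenenet as sn

out = Path("scratch/examples")
out.mkdir(parents=True, exist_ok=True)

digits = sn.digits_patch()
letters = sn.letters_patch()
natural = sn.make_natural_like(seed=11)

for img, name in [(digits, "patch1_digits"), (letters, "patch2_letters"),
                  (natural, "natural_11")]:
    sn.write_image(img, out / f"{name}.png")
    ink = (img.pixels > 0.5).mean()
    print(f"{name}: {img.shape[0]}x{img.shape[1]}, "
          f"fraction of bright pixels {ink:.3f}")

# bright-pixel fractions: ~7-8% for glyph patches (sparse strokes on
# black), ~50% for the natural-like image (graded luminance)
print(f"wrote 3 images to {out}/")
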