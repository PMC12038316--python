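"""Encode a fixation patch into the V1-like channel stack.

The 256x256 image becomes 32 channels of non-negative rates: 4 spatial
frequencies x 4 orientations x 2 signs (the rectified positive and
negative halves of each linear Gabor response).
"""

import numpy as np

import scenenet as sn

bank = sn.build_gabor_bank()
stack = sn.encode(sn.digits_patch(), bank)

print(f"V1 stack shape: {stack.shape} (all values >= 0)")
for f in range(bank.n_freq):
    chans = [bank.channel_index(f, o, s) for o in range(4) for s in (0, 1)]
    band = stack.responses[:, :, chans]
    print(f"  wavelength {bank.wavelengths[f]:4.0f} px: "
          f"mean rate {band.mean():.4f}, active fraction {(band > 0).mean():.3f}")

# low-frequency channels carry more energy per unit area for glyph images;
# the network compensates by allocating more Layer-1 connections to the
# high-frequency bands (29/14/7/4 of the 54 afferents, high to low)
print("Layer-1 connections per band:",
      tuple(int(c) for c in sn.allocate_by_frequency(54)))
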