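"""Map a spatial view neuron's receptive field with moving probes.

A 32x32 probe cut from the image is presented at its true position on a
zero background and stepped across the whole patch; the neuron's rate at
each probe position is its receptive-field map.  A coarse 8-px step is
used here for speed (the standard procedure steps by 2 px).
"""

import numpy as np

import scenenet as sn

p3 = sn.make_natural_like(11)
p4 = sn.make_natural_like(12)
overrides = {"architecture": {
    "layer1": {"sparseness": 0.3, "lateral_inhibition": {"enabled": False}},
    "layer2": {"sparseness": 0.4, "lateral_inhibition": {"enabled": False}},
    "layer3": {"sparseness": 0.4, "lateral_inhibition": {"enabled": False}},
}}
model = sn.build_model(sn.make_config({"seed": 0, **overrides}))
sn.train(model, sn.SceneSpec({"UL": p3, "UR": p4}, name="natural"))

y3 = sn.present(model, p3, "UL")["layer3"]
y4 = sn.present(model, p4, "UR")["layer3"]
neuron = divmod(int(np.argmax(y3.ravel() - y4.ravel())), 32)
print(f"mapping Layer-3 neuron {neuron} "
      f"(rate {y3[neuron]:.2f} to patch 3, {y4[neuron]:.2f} to patch 4)")

rf = sn.map_receptive_field(model, p3, 3, neuron, "UL", step=8)
d_px, d_deg = rf.equivalent_diameter()
print(f"lattice {rf.lattice_shape}, peak rate {rf.responses.max():.2f} "
      f"at probe position {rf.peak()}")
print(f"half-max receptive field: equivalent diameter "
      f"{d_px:.1f} px = {d_deg:.1f} degrees of visual angle")
# the neuron responds only when the probe covers its feature region of
# patch 3 -- a spatial view field anchored to scene content
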