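"""The cosinusoidal daily forcing and what a gradient means in molecules.

Evaluates the 2-fold circadian blood forcing for CXCL12-alpha over one
day and converts the canonical migration-threshold gradient into the
molecule-count difference a 10-um cell experiences.
"""

import numpy as np

import cxclgrad as cg
from cxclgrad.vessel import CircadianParams, circadian_value

params = CircadianParams.twofold(mean=0.25)  # nM, CXCL12-alpha blood level
t = np.linspace(0.0, 24.0, 24 * 60 + 1)
x = circadian_value(t, params)
print(f"blood CXCL12-alpha over 24 h: mean {x.mean():.3f} nM, "
      f"max {x.max():.3f} at t={t[x.argmax()]:.0f} h, min {x.min():.3f} nM")
print(f"peak:trough fold change = {x.max() / x.min():.3f}")

n = cg.molecules_across_cell(0.002, cell_diameter=10.0, volume_l=1e-12)
print(
    f"\nA 0.002 nM/um gradient across a 10-um cell in a 1-pL compartment is a\n"
    f"difference of about {n:.0f} molecules -- the scale a migrating cell must sense."
)
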