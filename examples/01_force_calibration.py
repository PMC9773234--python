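"""Force calibration: what can a cell lift?

The maximum traction force of a human adipose-derived stem cell (~200 pN)
equals the buoyant weight of an 82 um polystyrene sphere in water; with a
32 um cell this fixes the 82/32 rule used throughout the simulator.
"""

from scipy.optimize import brentq

from granulocell.units import (
    POLYSTYRENE_DENSITY,
    WATER_DENSITY,
    buoyant_weight,
    max_cell_force,
)

w82 = buoyant_weight(82e-6, POLYSTYRENE_DENSITY, WATER_DENSITY)
print(f"buoyant weight of an 82 um polystyrene sphere in water: {w82*1e12:.1f} pN")

f32 = max_cell_force(32e-6)
print(f"maximum force of a 32 um cell (82/32 rule):            {f32*1e12:.1f} pN")

d = brentq(
    lambda d: buoyant_weight(d, POLYSTYRENE_DENSITY, WATER_DENSITY) - 200e-12,
    1e-6,
    1e-3,
)
print(f"sphere diameter whose buoyant weight is exactly 200 pN: {d*1e6:.1f} um")

# The three numbers close the loop: a cell pulling at its maximum force can
# just lift a microparticle 82/32 times its own diameter; larger (or denser)
# particles anchor the cell, smaller ones are dragged along.
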