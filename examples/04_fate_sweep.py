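"""A miniature cell-fate sweep over particle size and density.

Replicates (drop positions x bed configurations) are averaged into the mean
volume ratio per condition — the simulator's counterpart of the cell
survival curves measured on microsphere beds.  This demo uses a reduced
grid; the full protocol uses 16 positions x 10 beds (160 samples per
condition) in a (20d)^3 box.
"""

from granulocell.experiment import ScenarioConfig, run_sweep

cfg = ScenarioConfig(
    box_size=10.0,
    n_drop_positions=4,
    n_bed_configs=1,
    master_seed=11,
)

result = run_sweep(
    cfg,
    aspect_ratios=(1.0, 2.0),
    relative_densities=(1.0, float("inf")),
    progress=False,
)

print(result.aggregate.to_string(index=False))
print(f"({len(result.samples)} samples, {result.n_failed} failed)")

# Expected pattern: the sintered (infinite-density) rows stay near 1 at all
# size ratios, while mobile polystyrene beds lose volume as the particles
# get smaller relative to the cell (larger aspect ratio).
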