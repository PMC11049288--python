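"""Density histogram, h_rel and entropy of a droplet in vacuum.

All particles sit inside a central ball, the rest of the cell is empty.
The relative-density histogram then has a dominant peak at 0 (the vacuum),
h_rel is far above 1 at probe radii near the droplet size (two-phase
variance), and the configuration entropy deviates from the ideal-gas
reference.
"""

import numpy as np

from microhet import (
    BinningSpec,
    Observation,
    PeriodicCell,
    entropy_curve,
    generate_droplet,
    h_rel,
    histogram,
    ideal_gas_model,
    scan_field,
)

cell = PeriodicCell.cubic(5000.0)
config = generate_droplet(600, cell, droplet_radius=700.0, seed=0)
obs = Observation("all")

r_s = 600.0
field = scan_field(config, 24, obs, r_s)
hist = histogram(field)
model = ideal_gas_model(600, r_s, cell)
curve = entropy_curve([field], [model], BinningSpec(n_bins=100))

frac_zero = float(np.mean(field.values == 0.0))
print(f"rS = {r_s:.0f} pm")
print(f"fraction of probe spheres with zero density: {frac_zero:.2f} (vacuum)")
print(f"h_rel = {h_rel(field.sigma, model):.2f}  (>> 1: two-phase system)")
print(f"relative entropy dH = {curve.delta_h[0]:+.3f} nats vs ideal gas")
print("\nThe histogram maximum at 0 and the large h_rel identify a dense")
print("droplet coexisting with vacuum rather than a homogeneous fluid.")
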