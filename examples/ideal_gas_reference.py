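"""Uniform random points are their own ideal-gas reference: h_rel = 1.

Draws 512 uniformly random point particles in a 5538-pm cubic cell, scans
sampling spheres of three radii over a 32^3 grid, and compares the observed
relative-density standard deviation with the closed-form binomial value
sqrt((1-p)/(np)).  The quotient h_rel should sit at 1 up to sampling noise:
the configuration is literally a draw from the reference model.
"""

import numpy as np

from microhet import (
    Observation,
    PeriodicCell,
    generate_ideal_gas,
    h_rel,
    ideal_gas_model,
    scan_field,
)

cell = PeriodicCell.cubic(5538.0)
obs = Observation("all")
frames = [generate_ideal_gas(512, cell, seed=s) for s in range(5)]

print("rS/pm   sigma_obs  sigma_IG   h_rel")
for r_s in (300.0, 600.0, 1000.0):
    field = scan_field(frames, 32, obs, r_s)
    model = ideal_gas_model(512, r_s, cell)
    print(
        f"{r_s:6.0f}  {field.sigma:9.4f}  {model.sigma:8.4f}  "
        f"{h_rel(field.sigma, model):6.4f}"
    )
print("\nh_rel ~ 1 at every radius: no structure beyond random placement.")
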