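# Methods

## The model

`microhet` quantifies microheterogeneity (microphase separation) in particle
simulations from local density fluctuations.  A probe ("sampling") sphere of
radius r_S is placed at every node of a regular Cartesian grid spanning the
periodic simulation cell.  Atoms are solid balls of radius r_A (Van-der-Waals
radii by default); each atom contributes to a probe sphere the fraction f of
its volume lying inside it.  f has a closed form with four cases in the
centre–centre distance d:

- d ≥ r_A + r_S (disjunct): f = 0
- d ≤ r_A − r_S and r_S ≤ r_A (probe inside atom): f = (r_S/r_A)³
- d ≤ r_S − r_A and r_S ≥ r_A (atom inside probe): f = 1
- otherwise (partial overlap):
  f = (r_A + r_S − d)² (d² + 2d(r_A + r_S) − 3(r_A − r_S)²) / (16 d r_A³)

The partial case is the classical spherical-lens volume divided by the atom
volume; all branches agree at the case boundaries, so f is continuous in d.
Distances use the minimum-image convention in an orthorhombic cell.

Summing f over the sites of an *observation* (a named subset of atoms or
pseudo-particles), optionally mass-weighted, and dividing by the sphere
volume gives the local particle or mass density; dividing further by the
observation's whole-cell density gives the relative density ρ_i of sphere i.
Pooling ρ_i over all grid nodes and frames yields a distribution whose mean
μ is 1 by construction for fine grids and whose population standard
deviation σ = sqrt(N⁻¹ Σ(ρ_i − μ)²) measures heterogeneity.

## Ideal-gas reference and h_rel

For n non-interacting point particles placed uniformly in the cell, the
count k inside a probe of volume V_S is binomial with inclusion probability
p = V_S / V_Total, so the relative density k/(np) has standard deviation
σ_IG = sqrt((1 − p)/(np)).  The relative heterogeneity measure is

    h_rel(r_S) = σ_Observed / σ_IdealGas.

h_rel > 1 indicates heterogeneity; h_rel < 1 a distribution more regular
than random, as in dense packings with exclusion volume.  Note that for
finite atom radii the overlap fraction f itself smooths the observed
distribution: even uniformly random 188-pm atoms give h_rel ≈ 0.68–0.80 for
r_S between 250 and 400 pm in a 5538-pm cell.  h_rel at probe radii
comparable to r_A therefore reflects both this smoothing and genuine
structure, which is worth keeping in mind when reading small-radius values.

## Entropy estimate

The Shannon entropy of the relative-density distribution is estimated from
its histogram as H ≈ −Σ_i f(x_i) log f(x_i) w(x_i) with bin densities
f(x_i) and widths w(x_i); empty bins contribute zero.  The natural
logarithm is the default (values in nats; configurable).  Because histogram
entropy estimates depend on the binning, the ideal-gas reference entropy is
computed by rasterizing the exact binomial pmf onto the *same* bin grid
(mass assigned to the containing bin, converted to density) and only the
difference ΔH = H_observed − H_idealgas is interpreted.  ΔH comparisons are
meaningful when the bin width spans several binomial support points
(spacing 1/(np)) while remaining small against the distribution width — the
estimator is consistent only in that joint refinement.

## Voids and correlation

A probe sphere is a (partial) void for an observation when no selected site
lies within r_A + r_S of its centre — a distance criterion, deliberately not
a floating-point test on the summed density.  The empty fraction as a
function of r_S characterizes void sizes.  For two observations scanned on
the identical grid and frames, the per-sphere pairs (ρ_i^A, ρ_i^B) populate
a 2D histogram and a Pearson correlation coefficient; segregated species
give negative correlation.

## Numerical choices

- **Grid.** Probe centres at i·(L/n), i = 0…n−1 per axis.  Defaults follow
  common practice for production analyses (150³ nodes, 200 equidistant
  frames); tests and examples use 16³–64³ and a few frames, which is ample
  for the synthetic systems analysed here.  The grid mean μ converges
  spectrally fast (periodic equispaced quadrature) but oscillates between
  neighbouring grid counts.
- **Neighbor search.** A periodic `scipy.spatial.cKDTree` is built on the
  grid nodes once per (cell, grid); each site then queries the spheres it
  can reach (radius r_A + r_S), so cost scales with local density rather
  than total particle count.
- **Image safety.** r_S + max r_A must not exceed half the smallest cell
  edge; larger probes are rejected rather than silently double-counting
  periodic images.
- **Normalization.** Each frame is normalized by its own whole-cell
  observation density, so μ = 1 per frame even if selections change
  between trajectories.
- **σ from raw samples**, never from the binned histogram, to keep h_rel
  free of binning bias.
- **Binning.** 500 equal-width bins over [0, ceil(max ρ)] by default; bin
  edges are recorded in all outputs.
- **Case boundaries.** d = r_A + r_S is assigned to the disjunct case and
  the containment boundaries to the containment cases; the assignment is
  arbitrary (the branches agree there) but fixed.
- **n for the reference** is the observation's selected-site count, which
  must be constant across frames; the cell volume is taken from the first
  frame (constant-volume trajectories assumed).

## Synthetic generators

The bundled generators create configurations with known statistics: uniform
random points (an ideal-gas draw, point-like 1-pm radii so f is defined), a
simple cubic lattice, a demixed two-species box (species in opposite
half-cells), a liquid droplet in vacuum with an optional coexisting uniform
gas phase, and Lennard-Jones argon.  The argon sampler is canonical-ensemble
Metropolis Monte Carlo: single-particle displacement moves (uniform within
±250 pm, accepted with min(1, e^(−βΔE))), plain truncated LJ energy
(σ = 340.5 pm, ε = 0.996 kJ/mol, cutoff 1500 pm, no shift or tail
correction), lattice initialization, 2000 equilibration sweeps, then 20
snapshots 50 sweeps apart by default.  512 atoms at 0.2 g/cm³ correspond to
a 5538-pm cubic cell.  At 300 K the measured acceptance is ~65 % and the
sampled pair correlation matches the low-density limit g(r) ≈ exp(−βu(r))
to a few percent, which validates the sampler independently of the density
analysis.

Monte Carlo is used instead of molecular dynamics because the analysis only
needs decorrelated equilibrium NVT configurations; no integrator or
thermostat machinery is required.

What the generators do *not* emulate: real liquids' many-body structure
beyond pairwise LJ, molecular connectivity (pseudo-particle grouping is
exercised on synthetic groups, not real force-field topologies), and
long-wavelength coexistence dynamics.  Passing tests on these fixtures
demonstrate the correctness of the geometry, statistics and estimators, not
force-field fidelity.  Low-temperature two-phase argon (droplet–gas
coexistence) needs far longer equilibration than single-move MC achieves at
desk scale; the corresponding histogram signature (maximum at the gas
density, ≈0.2 relative) is exercised on a constructed droplet+gas
configuration instead.

## Known limitations

- Orthorhombic cells only; triclinic cells are rejected.
- Probe radii are limited by the minimum-image bound; no image summation.
- The entropy estimator is the plain histogram plug-in (no Miller–Madow or
  similar debiasing); only relative entropies should be interpreted.
- At probe radii comparable to the atom radius, h_rel is dominated by
  overlap smoothing (see above); cross-temperature or cross-system
  comparisons at identical r_S remain well-defined.
- Single-particle-move MC converges slowly for strongly clustered states
  (near-critical or two-phase); the bundled sampler is intended for
  gas-like and moderately dense states.
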