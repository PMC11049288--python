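"""Synthetic configurations with known statistical structure.

These generators make every analysis stage testable without external data:
uniform random points (the ideal-gas reference made concrete), a perfect
cubic lattice, a demixed two-species box, a liquid droplet in vacuum (with an
optional coexisting uniform gas), and a small Metropolis Monte Carlo sampler
for Lennard-Jones argon in the canonical (NVT) ensemble.

All generators are deterministic under a fixed seed.  Lengths are in pm,
masses in u, energies in kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


import numpy as np
from numpy.typing import NDArray

from .elements import ATOMIC_MASS_U, VDW_RADIUS_PM
from .geometry import PeriodicCell
from .sampling import Observation, ParticleConfiguration

__all__ = [
    "GeneratorSpec",
    "generate_ideal_gas",
    "generate_lattice",
    "generate_demixed_binary",
    "generate_droplet",
    "LJParameters",
    "LJSampleResult",
    "sample_lj_argon",
    "argon_cell_edge",
    "generate",
]

KB_KJ_PER_MOL_K = 8.31446262e-3  # gas constant in kJ/(mol K)
AMU_G = 1.66053907e-24  # g per atomic mass unit
POINT_RADIUS = 1.0  # pm; epsilon-radius for "point" particles so f is defined


def generate_ideal_gas(
    n: int,
    cell: PeriodicCell | float,
    seed: int | np.random.Generator = 0,
    radius: float = POINT_RADIUS,
) -> ParticleConfiguration:
    """n uniformly random, non-interacting point-like particles."""
    if n < 1:
        raise ValueError("need at least one particle")
    cell = cell if isinstance(cell, PeriodicCell) else PeriodicCell.cubic(cell)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * cell.edges
    return ParticleConfiguration(
        positions=pos,
        radii=np.full(n, radius),
        masses=np.ones(n),
        cell=cell,
        elements=["X"] * n,
    )


def generate_lattice(
    n_per_axis: int,
    cell: PeriodicCell | float,
    radius: float = 100.0,
) -> ParticleConfiguration:
    """Simple cubic lattice of identical sites filling the cell."""
    cell = cell if isinstance(cell, PeriodicCell) else PeriodicCell.cubic(cell)
    axes = [np.arange(n_per_axis) * (cell.edges[ax] / n_per_axis) for ax in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pos = np.stack([m.ravel() for m in mesh], axis=1)
    n = pos.shape[0]
    return ParticleConfiguration(
        positions=pos,
        radii=np.full(n, radius),
        masses=np.ones(n),
        cell=cell,
        elements=["X"] * n,
    )


def generate_demixed_binary(
    n_per_species: int,
    cell: PeriodicCell | float,
    interface_axis: int = 0,
    seed: int | np.random.Generator = 0,
    radius: float = 100.0,
) -> tuple[ParticleConfiguration, Observation, Observation]:
    """Two species fully segregated into opposite half-cells.

    Species A occupies the lower half along ``interface_axis``, species B the
    upper half; matching observations are returned pre-wired.
    """
    cell = cell if isinstance(cell, PeriodicCell) else PeriodicCell.cubic(cell)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1.0, size=(2 * n_per_species, 3)) * cell.edges
    half = 0.5 * cell.edges[interface_axis]
    pos[:n_per_species, interface_axis] = rng.uniform(0.0, half, size=n_per_species)
    pos[n_per_species:, interface_axis] = rng.uniform(half, cell.edges[interface_axis], size=n_per_species)
    elements = ["A"] * n_per_species + ["B"] * n_per_species
    config = ParticleConfiguration(
        positions=pos,
        radii=np.full(2 * n_per_species, radius),
        masses=np.ones(2 * n_per_species),
        cell=cell,
        elements=elements,
    )
    return config, Observation("A", "element A"), Observation("B", "element B")


def generate_droplet(
    n: int,
    cell: PeriodicCell | float,
    droplet_radius: float,
    seed: int | np.random.Generator = 0,
    radius: float = 100.0,
    background_fraction: float = 0.0,
) -> ParticleConfiguration:
    """A liquid droplet in the cell centre, vacuum (or dilute gas) outside.

    With ``background_fraction > 0`` that fraction of the particles is spread
    uniformly over the whole cell, emulating a droplet in coexistence with
    its gas phase.
    """
    cell = cell if isinstance(cell, PeriodicCell) else PeriodicCell.cubic(cell)
    if droplet_radius <= 0 or 2 * droplet_radius > cell.min_edge:
        raise ValueError("droplet must have positive radius and fit inside the cell")
    if not 0.0 <= background_fraction < 1.0:
        raise ValueError("background_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_gas = int(round(background_fraction * n))
    n_drop = n - n_gas
    # uniform in a ball: isotropic direction times cbrt-distributed radius
    direction = rng.normal(size=(n_drop, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = droplet_radius * rng.uniform(0.0, 1.0, size=(n_drop, 1)) ** (1.0 / 3.0)
    drop = 0.5 * cell.edges + direction * r
    gas = rng.uniform(0.0, 1.0, size=(n_gas, 3)) * cell.edges
    pos = np.vstack([drop, gas])
    return ParticleConfiguration(
        positions=pos,
        radii=np.full(n, radius),
        masses=np.ones(n),
        cell=cell,
        elements=["X"] * n,
    )


# ---------------------------------------------------------------------------
# Lennard-Jones argon via Metropolis Monte Carlo
# ---------------------------------------------------------------------------


def argon_cell_edge(n: int, density_g_cm3: float) -> float:
    """Cubic cell edge in pm for n argon atoms at a given mass density."""
    mass_g = n * ATOMIC_MASS_U["Ar"] * AMU_G
    volume_cm3 = mass_g / density_g_cm3
    return (volume_cm3 * 1e30) ** (1.0 / 3.0)  # 1 cm^3 = 1e30 pm^3


@dataclass(frozen=True)
class LJParameters:
    """Lennard-Jones argon model and Monte Carlo run parameters.

    Defaults are the argon model used throughout this package: sigma 340.5 pm,
    epsilon 0.996 kJ/mol, plain cutoff at 1500 pm (no shift or tail
    correction), 512 atoms at 0.2 g/cm3 (cubic cell ~5538 pm).
    """

    n: int = 512
    temperature: float = 300.0  # K
    density_g_cm3: float = 0.2
    sigma: float = 340.5  # pm
    epsilon: float = 0.996  # kJ/mol
    cutoff: float = 1500.0  # pm
    max_move: float = 250.0  # pm, uniform displacement half-width
    equilibration_sweeps: int = 2000
    n_snapshots: int = 20
    snapshot_stride_sweeps: int = 50

    @property
    def cell_edge(self) -> float:
        return argon_cell_edge(self.n, self.density_g_cm3)


@dataclass
class LJSampleResult:
    """Snapshots plus run diagnostics from the Monte Carlo sampler."""

    frames: list[ParticleConfiguration]
    acceptance_rate: float
    energy_trace: NDArray[np.float64]  # total energy (kJ/mol) per sweep
    params: LJParameters


def _pair_energy_one(
    positions: NDArray[np.float64],
    i: int,
    xi: NDArray[np.float64],
    edges: NDArray[np.float64],
    sigma: float,
    epsilon: float,
    rc2: float,
) -> float:
    """LJ energy of particle i at position xi with all others (minimum image)."""
    delta = positions - xi
    delta -= edges * np.round(delta / edges)
    r2 = np.einsum("ij,ij->i", delta, delta)
    r2[i] = np.inf
    mask = r2 < rc2
    if not np.any(mask):
        return 0.0
    inv6 = (sigma * sigma / r2[mask]) ** 3
    return float(4.0 * epsilon * np.sum(inv6 * inv6 - inv6))


def lj_total_energy(
    positions: NDArray[np.float64],
    cell: PeriodicCell,
    sigma: float,
    epsilon: float,
    cutoff: float,
) -> float:
    """Full pairwise LJ energy with plain cutoff (reference recomputation)."""
    rc2 = cutoff * cutoff
    e = 0.0
    for i in range(positions.shape[0] - 1):
        delta = positions[i + 1 :] - positions[i]
        delta -= cell.edges * np.round(delta / cell.edges)
        r2 = np.einsum("ij,ij->i", delta, delta)
        mask = r2 < rc2
        if np.any(mask):
            inv6 = (sigma * sigma / r2[mask]) ** 3
            e += 4.0 * epsilon * np.sum(inv6 * inv6 - inv6)
    return float(e)


def sample_lj_argon(
    params: LJParameters | None = None,
    seed: int | np.random.Generator = 0,
) -> LJSampleResult:
    """Canonical-ensemble Metropolis Monte Carlo for Lennard-Jones argon.

    Atoms start on a simple cubic lattice (no overlapping initialization),
    equilibrate for ``equilibration_sweeps`` sweeps of single-particle
    displacement moves, then ``n_snapshots`` decorrelated snapshots are saved
    every ``snapshot_stride_sweeps`` sweeps.  One sweep is n attempted moves.
    The total energy is tracked incrementally from the accepted move deltas
    and recorded once per sweep.
    """
    params = params or LJParameters()
    if params.temperature <= 0:
        raise ValueError("temperature must be positive")
    cell = PeriodicCell.cubic(params.cell_edge)
    if params.cutoff >= 0.5 * cell.min_edge:
        raise ValueError("LJ cutoff must be below half the cell edge")
    rng = np.random.default_rng(seed)
    n = params.n
    edges = cell.edges

    # lattice start: smallest cubic lattice holding n sites
    m = math.ceil(n ** (1.0 / 3.0))
    lat = generate_lattice(m, cell, radius=1.0).positions[:n].copy()
    positions = lat

    beta = 1.0 / (KB_KJ_PER_MOL_K * params.temperature)
    rc2 = params.cutoff**2
    energy = lj_total_energy(positions, cell, params.sigma, params.epsilon, params.cutoff)

    total_sweeps = params.equilibration_sweeps + params.n_snapshots * params.snapshot_stride_sweeps
    energy_trace = np.empty(total_sweeps)
    frames: list[ParticleConfiguration] = []
    accepted = 0
    attempted = 0
    ar_radius = VDW_RADIUS_PM["Ar"]
    ar_mass = ATOMIC_MASS_U["Ar"]

    for sweep in range(total_sweeps):
        moved = rng.integers(0, n, size=n)
        steps = rng.uniform(-params.max_move, params.max_move, size=(n, 3))
        accepts = rng.uniform(size=n)
        for k in range(n):
            i = int(moved[k])
            old = positions[i].copy()
            new = (old + steps[k]) % edges
            e_old = _pair_energy_one(positions, i, old, edges, params.sigma, params.epsilon, rc2)
            e_new = _pair_energy_one(positions, i, new, edges, params.sigma, params.epsilon, rc2)
            de = e_new - e_old
            attempted += 1
            if de <= 0.0 or accepts[k] < math.exp(-beta * de):
                positions[i] = new
                energy += de
                accepted += 1
        energy_trace[sweep] = energy
        past_equil = sweep >= params.equilibration_sweeps
        if past_equil and (sweep - params.equilibration_sweeps + 1) % params.snapshot_stride_sweeps == 0:
            frames.append(
                ParticleConfiguration(
                    positions=positions.copy(),
                    radii=np.full(n, ar_radius),
                    masses=np.full(n, ar_mass),
                    cell=cell,
                    elements=["Ar"] * n,
                    frame_index=len(frames),
                )
            )
    return LJSampleResult(
        frames=frames,
        acceptance_rate=accepted / max(attempted, 1),
        energy_trace=energy_trace,
        params=params,
    )


@dataclass
class GeneratorSpec:
    """Declarative description of one synthetic configuration."""

    kind: str  # idealgas | lattice | demixed_binary | droplet | lj_argon
    n: int = 512
    cell_edge: float = 5000.0
    seed: int = 0
    options: dict = field(default_factory=dict)


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to the matching generator."""
    if spec.kind == "idealgas":
        return generate_ideal_gas(spec.n, spec.cell_edge, spec.seed, **spec.options)
    if spec.kind == "lattice":
        m = int(round(spec.n ** (1.0 / 3.0)))
        return generate_lattice(m, spec.cell_edge, **spec.options)
    if spec.kind == "demixed_binary":
        return generate_demixed_binary(spec.n, spec.cell_edge, seed=spec.seed, **spec.options)
    if spec.kind == "droplet":
        opts = dict(spec.options)
        droplet_radius = opts.pop("droplet_radius", 0.25 * spec.cell_edge)
        return generate_droplet(spec.n, spec.cell_edge, droplet_radius, spec.seed, **opts)
    if spec.kind == "lj_argon":
        params = LJParameters(n=spec.n, **spec.options)
        return sample_lj_argon(params, spec.seed)
    raise ValueError(f"unknown generator kind {spec.kind!r}")
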