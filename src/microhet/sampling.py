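"""Sampling-sphere density scans over periodic particle configurations.

A regular Cartesian grid of sampling-sphere centres is moved through the
periodic cell.  For every sphere, each site contributes the fraction of its
volume inside the sphere (see :mod:`microhet.geometry`); dividing the weighted
sum by the sphere volume gives the local particle or mass density, and
dividing by the whole-cell density of the same observation gives the relative
density rho_i.  The pooled rho_i over all spheres and frames form a
:class:`RelativeDensityField`, the raw material for histograms, heterogeneity
measures, entropy estimates and void statistics.

Neighbor search uses a periodic ``scipy.spatial.cKDTree`` built on the grid
points, so the cost per sphere depends only on the local site density, not on
the total number of sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.spatial import cKDTree

from .geometry import PeriodicCell, overlap_factor

__all__ = [
    "ParticleConfiguration",
    "Observation",
    "SamplingSpec",
    "RelativeDensityField",
    "make_pseudo_particles",
    "sphere_density",
    "scan_field",
    "empty_fraction",
]


@dataclass
class ParticleConfiguration:
    """One frame of a particle system: positions, per-site radii/masses, cell.

    Positions are wrapped into the primary cell on construction.
    """

    positions: NDArray[np.float64]
    radii: NDArray[np.float64]
    masses: NDArray[np.float64]
    cell: PeriodicCell
    elements: list[str] | None = None
    frame_index: int = 0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        n = pos.shape[0]
        radii = np.broadcast_to(np.asarray(self.radii, dtype=float), (n,)).copy()
        masses = np.broadcast_to(np.asarray(self.masses, dtype=float), (n,)).copy()
        if np.any(radii <= 0):
            raise ValueError("all site radii must be positive")
        if np.any(masses < 0):
            raise ValueError("site masses must be non-negative")
        self.positions = self.cell.wrap(pos)
        self.radii = radii
        self.masses = masses
        if self.elements is not None and len(self.elements) != n:
            raise ValueError("elements list length must match the number of sites")

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]


_INDEX_TOKEN = re.compile(r"^\d+(-\d+)?$")


@dataclass
class Observation:
    """A named subset of sites analyzed as one partial density.

    ``select`` is either an explicit index array, or a small selection
    expression: ``"all"``, element symbols (``"Ar"``, ``"element C Cl"``) or
    0-based index lists with inclusive ranges (``"index 0,2,5-9"``; a bare
    ``"0,2,5-9"`` also works).  ``radius`` overrides the per-site radius for
    all selected sites; ``mode`` chooses particle-count or mass weighting.
    """

    name: str
    select: str | Sequence[int] | None = "all"
    radius: float | None = None
    mode: str = "particle"

    def __post_init__(self) -> None:
        if self.mode not in ("particle", "mass"):
            raise ValueError(f"density mode must be 'particle' or 'mass', got {self.mode!r}")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius override must be positive")

    def indices(self, config: ParticleConfiguration) -> NDArray[np.intp]:
        """Resolve the selection against one configuration."""
        sel = self.select
        if sel is None:
            sel = "all"
        if not isinstance(sel, str):
            idx = np.asarray(sel, dtype=np.intp)
        else:
            expr = sel.strip()
            if expr == "all":
                idx = np.arange(config.n_sites, dtype=np.intp)
            else:
                tokens = [t for t in re.split(r"[,\s]+", expr) if t]
                if tokens and tokens[0] in ("element", "index"):
                    kind, tokens = tokens[0], tokens[1:]
                elif all(_INDEX_TOKEN.match(t) for t in tokens):
                    kind = "index"
                else:
                    kind = "element"
                if not tokens:
                    raise ValueError(f"empty selection expression {sel!r}")
                if kind == "element":
                    if config.elements is None:
                        raise ValueError(
                            f"selection {sel!r} needs element labels, but the "
                            "configuration carries none"
                        )
                    wanted = set(tokens)
                    elems = np.asarray(config.elements)
                    idx = np.flatnonzero(np.isin(elems, list(wanted)))
                else:
                    out: list[int] = []
                    for t in tokens:
                        if not _INDEX_TOKEN.match(t):
                            raise ValueError(f"bad index token {t!r} in selection {sel!r}")
                        if "-" in t:
                            lo, hi = map(int, t.split("-"))
                            out.extend(range(lo, hi + 1))
                        else:
                            out.append(int(t))
                    idx = np.asarray(out, dtype=np.intp)
        if idx.size == 0:
            raise ValueError(f"observation {self.name!r} selects no sites")
        if np.any(idx < 0) or np.any(idx >= config.n_sites):
            raise IndexError(f"observation {self.name!r} selects out-of-range site indices")
        return idx

    def site_radii(self, config: ParticleConfiguration, idx: NDArray[np.intp]) -> NDArray[np.float64]:
        if self.radius is not None:
            return np.full(idx.size, float(self.radius))
        return config.radii[idx]

    def site_weights(self, config: ParticleConfiguration, idx: NDArray[np.intp]) -> NDArray[np.float64]:
        if self.mode == "mass":
            return config.masses[idx]
        return np.ones(idx.size)


@dataclass(frozen=True)
class SamplingSpec:
    """Grid resolution, sampling radii and frame selection for a scan."""

    grid: tuple[int, int, int]
    radii: tuple[float, ...]
    n_frames: int | None = None

    def __post_init__(self) -> None:
        grid = tuple(int(g) for g in np.broadcast_to(np.asarray(self.grid), (3,)))
        if any(g < 2 for g in grid):
            raise ValueError("grid must have at least 2 points per axis")
        radii = tuple(float(r) for r in self.radii)
        if any(r <= 0 for r in radii) or any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("sampling radii must be positive and strictly increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "radii", radii)


@dataclass
class RelativeDensityField:
    """Pooled per-sphere relative densities for one observation at one radius.

    ``values[k]`` and ``empty[k]`` refer to the same sphere; sphere order is
    frame-major, then x-major grid order, so fields scanned on identical
    grids/frames pair sphere-by-sphere.
    """

    r_s: float
    observation: str
    values: NDArray[np.float64]
    empty: NDArray[np.bool_]
    grid: tuple[int, int, int]
    n_frames: int
    reference_density: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.empty = np.asarray(self.empty, dtype=bool).ravel()
        if self.values.shape != self.empty.shape:
            raise ValueError("values and empty masks must align")
        if np.any(self.values < 0):
            raise ValueError("relative densities cannot be negative")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mu(self) -> float:
        return float(np.mean(self.values))

    @property
    def sigma(self) -> float:
        """Population standard deviation of the pooled relative densities."""
        return float(np.std(self.values))

    def merge(self, other: "RelativeDensityField") -> "RelativeDensityField":
        """Pool two fields scanned with the same observation, radius and grid."""
        if (self.r_s, self.observation, self.grid) != (other.r_s, other.observation, other.grid):
            raise ValueError("fields must share radius, observation and grid to merge")
        return RelativeDensityField(
            r_s=self.r_s,
            observation=self.observation,
            values=np.concatenate([self.values, other.values]),
            empty=np.concatenate([self.empty, other.empty]),
            grid=self.grid,
            n_frames=self.n_frames + other.n_frames,
            reference_density=0.5 * (self.reference_density + other.reference_density),
        )


def make_pseudo_particles(
    config: ParticleConfiguration,
    groups: Sequence[Sequence[int]],
    radius: float,
    name: str | None = None,
) -> ParticleConfiguration:
    """Collapse groups of sites into pseudo-particles at their geometric centres.

    Each group (e.g. the ring atoms of one cation) becomes a single site at
    the unweighted geometric centre, computed minimum-image consistently: all
    group members are unwrapped relative to the first member before averaging,
    so groups crossing a periodic boundary are centred correctly.  The
    pseudo-site carries the user-assigned ``radius`` and the summed group
    mass.

    Raises if a group is empty or spreads over more than half the cell (its
    unwrapping would be ambiguous).
    """
    if len(groups) == 0:
        raise ValueError("no pseudo-particle groups matched")
    if radius <= 0:
        raise ValueError("pseudo-particle radius must be positive")
    centers = np.empty((len(groups), 3))
    masses = np.empty(len(groups))
    for g, members in enumerate(groups):
        idx = np.asarray(members, dtype=np.intp)
        if idx.size == 0:
            raise ValueError(f"pseudo-particle group {g} is empty")
        pos = config.positions[idx]
        ref = pos[0]
        unwrapped = ref + config.cell.minimum_image(pos - ref)
        extent = unwrapped.max(axis=0) - unwrapped.min(axis=0)
        if np.any(extent >= 0.5 * config.cell.edges):
            raise ValueError(
                f"pseudo-particle group {g} spans more than half the cell; "
                "cannot unwrap consistently"
            )
        centers[g] = unwrapped.mean(axis=0)
        masses[g] = config.masses[idx].sum()
    return ParticleConfiguration(
        positions=centers,
        radii=np.full(len(groups), float(radius)),
        masses=masses,
        cell=config.cell,
        elements=[name or "X"] * len(groups),
        frame_index=config.frame_index,
    )


def _check_image_safety(r_s: float, max_rA: float, cell: PeriodicCell) -> None:
    bound = 0.5 * cell.min_edge
    if r_s + max_rA > bound:
        raise ValueError(
            f"sampling radius rS={r_s:g} plus largest site radius rA={max_rA:g} "
            f"exceeds the image-safety bound min(cell edge)/2 = {bound:g}; "
            "minimum-image overlap counting would be ambiguous"
        )


def sphere_density(
    config: ParticleConfiguration,
    center: ArrayLike,
    r_s: float,
    obs: Observation,
) -> float:
    """Absolute (particle or mass) density inside one sampling sphere.

    Sum of per-site overlap fractions, weighted by 1 (particle mode) or the
    site mass (mass mode), divided by the sphere volume.
    """
    idx = obs.indices(config)
    radii = obs.site_radii(config, idx)
    weights = obs.site_weights(config, idx)
    _check_image_safety(r_s, float(np.max(radii)), config.cell)
    delta = config.cell.minimum_image(config.positions[idx] - np.asarray(center, dtype=float))
    d = np.linalg.norm(delta, axis=1)
    f = overlap_factor(d, radii, r_s)
    v_sphere = 4.0 / 3.0 * np.pi * r_s**3
    return float(np.sum(weights * f) / v_sphere)


def grid_points(cell: PeriodicCell, grid: tuple[int, int, int]) -> NDArray[np.float64]:
    """Sampling-sphere centres at i*(L/n), i = 0..n-1, per axis (x-major order)."""
    axes = [np.arange(n) * (cell.edges[ax] / n) for ax, n in enumerate(grid)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def _frame_relative_densities(
    config: ParticleConfiguration,
    tree: cKDTree,
    n_grid: int,
    r_s: float,
    obs: Observation,
) -> tuple[NDArray[np.float64], NDArray[np.bool_]]:
    """Relative densities and emptiness flags on the grid for one frame.

    The KD-tree is built on the grid points (periodic), so each site queries
    only the spheres it can reach; sphere emptiness is decided by the distance
    criterion d < rA + rS, never by comparing summed densities to zero.
    """
    idx = obs.indices(config)
    radii = obs.site_radii(config, idx)
    weights = obs.site_weights(config, idx)
    _check_image_safety(r_s, float(np.max(radii)), config.cell)

    sums = np.zeros(n_grid)
    reached = np.zeros(n_grid, dtype=bool)
    pts = tree.data  # grid points, same order as construction
    positions = config.positions[idx]
    neighborhoods = tree.query_ball_point(positions, radii + r_s)
    for pos_j, rA_j, w_j, neigh in zip(positions, radii, weights, neighborhoods):
        if not neigh:
            continue
        neigh = np.asarray(neigh, dtype=np.intp)
        delta = config.cell.minimum_image(pts[neigh] - pos_j)
        d = np.linalg.norm(delta, axis=1)
        inside = d < rA_j + r_s
        neigh = neigh[inside]
        if neigh.size == 0:
            continue
        reached[neigh] = True
        f = overlap_factor(d[inside], rA_j, r_s)
        np.add.at(sums, neigh, w_j * f)

    v_sphere = 4.0 / 3.0 * np.pi * r_s**3
    reference = float(np.sum(weights)) / config.cell.volume
    rel = sums / v_sphere / reference
    return rel, ~reached


def scan_field(
    frames: Iterable[ParticleConfiguration] | ParticleConfiguration,
    spec: SamplingSpec | tuple[int, int, int] | int,
    obs: Observation,
    r_s: float,
) -> RelativeDensityField:
    """Scan sampling spheres of radius ``r_s`` over every frame and pool.

    Every frame is normalized by its own whole-cell observation density, so
    the pooled mean is ~1 per frame by construction.  ``spec`` may be a full
    :class:`SamplingSpec`, a grid triple, or a single per-axis grid count.
    """
    if isinstance(frames, ParticleConfiguration):
        frames = [frames]
    if isinstance(spec, SamplingSpec):
        grid = spec.grid
    else:
        grid = tuple(int(g) for g in np.broadcast_to(np.asarray(spec), (3,)))

    values: list[NDArray[np.float64]] = []
    empties: list[NDArray[np.bool_]] = []
    refs: list[float] = []
    tree: cKDTree | None = None
    tree_edges: NDArray[np.float64] | None = None
    n_grid = int(np.prod(grid))
    for config in frames:
        if tree is None or not np.allclose(config.cell.edges, tree_edges):
            pts = grid_points(config.cell, grid)
            tree = cKDTree(pts, boxsize=config.cell.edges)
            tree_edges = config.cell.edges
        rel, empty = _frame_relative_densities(config, tree, n_grid, r_s, obs)
        values.append(rel)
        empties.append(empty)
        idx = obs.indices(config)
        refs.append(float(np.sum(obs.site_weights(config, idx))) / config.cell.volume)
    if not values:
        raise ValueError("trajectory must contain at least one frame")
    return RelativeDensityField(
        r_s=float(r_s),
        observation=obs.name,
        values=np.concatenate(values),
        empty=np.concatenate(empties),
        grid=grid,
        n_frames=len(values),
        reference_density=float(np.mean(refs)),
    )


def empty_fraction(field: RelativeDensityField) -> float:
    """Fraction of sampling spheres containing no site of the observation.

    A sphere is empty when no selected site lies within rA + rS of its
    centre (void criterion, distance-based).
    """
    if field.n == 0:
        raise ValueError("field is empty")
    return float(np.mean(field.empty))
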