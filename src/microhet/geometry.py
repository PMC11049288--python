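"""Sphere-sphere overlap geometry and periodic-cell distances.

An atom is modelled as a solid ball of radius ``rA``; a sampling sphere is a
probe ball of radius ``rS``.  The overlap factor ``f`` is the fraction of the
atom's volume lying inside the sampling sphere, which has a closed form with
four cases depending on the centre-centre distance ``d``:

* disjunct (``d >= rA + rS``): ``f = 0``
* sampling sphere contained in the atom (``d <= rA - rS``, ``rS <= rA``):
  ``f = (rS/rA)**3``
* atom contained in the sampling sphere (``d <= rS - rA``, ``rS >= rA``):
  ``f = 1``
* partial overlap (otherwise):
  ``f = (rA + rS - d)**2 * (d**2 + 2 d (rA + rS) - 3 (rA - rS)**2)
  / (16 d rA**3)``

The partial-overlap expression is the classical spherical-lens intersection
volume divided by the atom volume; all four branches agree at the case
boundaries, so ``f`` is continuous in ``d``.

Lengths are unit-agnostic; picometres are used by convention throughout the
package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["PeriodicCell", "overlap_factor", "minimum_image_distance"]


@dataclass(frozen=True)
class PeriodicCell:
    """Orthorhombic periodic cell.

    Parameters
    ----------
    edges
        Edge lengths along x, y, z (must all be positive).
    periodic
        Per-axis periodicity flags; all axes periodic by default.
    """

    edges: NDArray[np.float64]
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.shape == ():
            edges = np.full(3, float(edges))
        if edges.shape != (3,):
            raise ValueError(f"cell edges must be a length-3 vector, got shape {edges.shape}")
        if not np.all(np.isfinite(edges)) or np.any(edges <= 0):
            raise ValueError(f"cell edges must be positive and finite, got {edges}")
        object.__setattr__(self, "edges", edges)

    @classmethod
    def cubic(cls, edge: float) -> "PeriodicCell":
        return cls(np.full(3, float(edge)))

    @classmethod
    def from_matrix(cls, h: ArrayLike) -> "PeriodicCell":
        """Build from a 3x3 cell matrix; off-diagonal (triclinic) terms are rejected."""
        h = np.asarray(h, dtype=float)
        if h.shape != (3, 3):
            raise ValueError("cell matrix must be 3x3")
        off = h - np.diag(np.diag(h))
        if np.max(np.abs(off)) > 1e-9 * max(1.0, np.max(np.abs(h))):
            raise ValueError("triclinic cells are not supported; orthorhombic cells only")
        return cls(np.diag(h))

    @property
    def volume(self) -> float:
        return float(np.prod(self.edges))

    @property
    def min_edge(self) -> float:
        return float(np.min(self.edges))

    def wrap(self, positions: ArrayLike) -> NDArray[np.float64]:
        """Wrap positions into [0, L) along each periodic axis."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float)).copy()
        for ax in range(3):
            if self.periodic[ax]:
                pos[:, ax] %= self.edges[ax]
        return pos

    def minimum_image(self, delta: ArrayLike) -> NDArray[np.float64]:
        """Map displacement vectors onto their minimum periodic image."""
        d = np.asarray(delta, dtype=float).copy()
        for ax in range(3):
            if self.periodic[ax]:
                L = self.edges[ax]
                d[..., ax] -= L * np.round(d[..., ax] / L)
        return d


def overlap_factor(d: ArrayLike, rA: ArrayLike, rS: ArrayLike) -> NDArray[np.float64] | float:
    """Fraction of a spherical atom's volume inside a sampling sphere.

    Vectorized over ``d`` (and broadcastable ``rA``, ``rS``).  Degenerate
    boundary distances are routed to the adjacent constant case, which is
    equivalent by continuity: ``d == rA + rS`` gives 0, the containment
    boundaries give ``(rS/rA)**3`` respectively 1.  In particular ``d == 0``
    never reaches the partial-overlap branch (which divides by ``d``).

    Parameters
    ----------
    d
        Centre-centre distance(s), >= 0.
    rA
        Atom radius, > 0.
    rS
        Sampling-sphere radius, > 0.

    Returns
    -------
    f in [0, 1], same shape as the broadcast inputs; scalar in, scalar out.
    """
    d_arr = np.asarray(d, dtype=float)
    rA_arr = np.asarray(rA, dtype=float)
    rS_arr = np.asarray(rS, dtype=float)
    scalar = d_arr.ndim == 0 and rA_arr.ndim == 0 and rS_arr.ndim == 0

    if np.any(rA_arr <= 0) or np.any(rS_arr <= 0):
        raise ValueError("atom and sampling-sphere radii must be positive")
    if np.any(d_arr < 0):
        raise ValueError("centre-centre distance must be non-negative")

    d_b, rA_b, rS_b = np.broadcast_arrays(d_arr, rA_arr, rS_arr)

    disjunct = d_b >= rA_b + rS_b
    sphere_in_atom = (d_b <= rA_b - rS_b) & (rS_b <= rA_b)
    atom_in_sphere = (d_b <= rS_b - rA_b) & (rS_b >= rA_b)
    partial = ~(disjunct | sphere_in_atom | atom_in_sphere)

    f = np.zeros_like(d_b, dtype=float)
    f[sphere_in_atom] = (rS_b[sphere_in_atom] / rA_b[sphere_in_atom]) ** 3
    f[atom_in_sphere] = 1.0
    if np.any(partial):
        dp = d_b[partial]
        ra = rA_b[partial]
        rs = rS_b[partial]
        f[partial] = (
            (ra + rs - dp) ** 2
            * (dp**2 + 2.0 * dp * (ra + rs) - 3.0 * (ra - rs) ** 2)
            / (16.0 * dp * ra**3)
        )
    # guard tiny negative values from cancellation right at the boundaries
    np.clip(f, 0.0, 1.0, out=f)
    return float(f[()]) if scalar else f


def minimum_image_distance(a: ArrayLike, b: ArrayLike, cell: PeriodicCell) -> float:
    """Euclidean distance between ``a`` and the nearest periodic image of ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("positions must be finite")
    delta = cell.minimum_image(b - a)
    return float(np.linalg.norm(delta, axis=-1))
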