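"""Trajectory ingestion and tabular result output.

Supported input formats: extended XYZ (with a ``Lattice="..."`` comment key),
LAMMPS dump, GRO and PDB (CRYST1).  Extended XYZ is read and written natively
and its coordinates are taken as picometres (the package convention); the
other formats are read through MDAnalysis, whose Angstrom coordinates are
converted to pm.  Every frame must carry cell information — the method is
defined on periodic cells — and every site needs a Van-der-Waals radius,
either from the bundled element table or as an explicit override.

Outputs are plain-text: per-observation CSV curve tables, per-radius
histogram columns, radius-by-density histogram matrices, 2D correlation
matrices, and a JSON run manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .elements import atomic_mass, vdw_radius
from .geometry import PeriodicCell
from .sampling import ParticleConfiguration

__all__ = [
    "read_trajectory",
    "read_extxyz",
    "write_extxyz",
    "write_results",
]

ANGSTROM_PM = 100.0

_EXT_FORMAT = {
    ".xyz": "extxyz",
    ".extxyz": "extxyz",
    ".gro": "gro",
    ".pdb": "pdb",
    ".lammpstrj": "lammpsdump",
    ".dump": "lammpsdump",
    ".lammpsdump": "lammpsdump",
}


def _sites_from_elements(
    elements: Sequence[str],
    radii_override: dict[str, float] | None,
) -> tuple[np.ndarray, np.ndarray]:
    radii = np.empty(len(elements))
    masses = np.empty(len(elements))
    override = radii_override or {}
    for i, el in enumerate(elements):
        if el in override:
            radii[i] = override[el]
        else:
            radii[i] = vdw_radius(el)  # raises for unknown elements
        try:
            masses[i] = atomic_mass(el)
        except KeyError:
            masses[i] = 1.0
    return radii, masses


def _normalize_symbol(label: str) -> str:
    """Map atom names like 'AR' onto element symbols where possible."""
    label = label.strip()
    cand = label.capitalize()
    from .elements import VDW_RADIUS_PM

    return cand if cand in VDW_RADIUS_PM else label


def read_extxyz(
    path: str | Path,
    radii_override: dict[str, float] | None = None,
) -> list[ParticleConfiguration]:
    """Read an (extended) XYZ trajectory; coordinates in pm.

    The comment line must contain ``Lattice="ax ay az bx by bz cx cy cz"``
    (orthorhombic); frames without it are rejected because the analysis needs
    a periodic cell.
    """
    frames: list[ParticleConfiguration] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i].strip())
        comment = lines[i + 1]
        if 'Lattice="' not in comment:
            raise ValueError(
                f"{path}: frame {len(frames)} has no Lattice cell information; "
                "the analysis requires a periodic cell"
            )
        lattice = comment.split('Lattice="', 1)[1].split('"', 1)[0]
        h = np.array([float(v) for v in lattice.split()]).reshape(3, 3)
        cell = PeriodicCell.from_matrix(h)
        elements: list[str] = []
        pos = np.empty((natoms, 3))
        for a in range(natoms):
            parts = lines[i + 2 + a].split()
            elements.append(parts[0])
            pos[a] = [float(v) for v in parts[1:4]]
        radii, masses = _sites_from_elements(elements, radii_override)
        frames.append(
            ParticleConfiguration(
                positions=pos,
                radii=radii,
                masses=masses,
                cell=cell,
                elements=elements,
                frame_index=len(frames),
            )
        )
        i += 2 + natoms
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def _read_mdanalysis(
    path: str | Path,
    fmt: str,
    radii_override: dict[str, float] | None,
) -> list[ParticleConfiguration]:
    import MDAnalysis as mda

    kwargs = {"format": "LAMMPSDUMP"} if fmt == "lammpsdump" else {}
    u = mda.Universe(str(path), **kwargs)
    atoms = u.atoms
    elements = None
    for attr in ("elements", "names", "types"):
        try:
            elements = [_normalize_symbol(str(v)) for v in getattr(atoms, attr)]
            break
        except (AttributeError, mda.exceptions.NoDataError):
            continue
    if elements is None:
        raise ValueError(f"{path}: no element/name/type information in topology")
    frames: list[ParticleConfiguration] = []
    for k, ts in enumerate(u.trajectory):
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            raise ValueError(
                f"{path}: frame {k} carries no cell information (e.g. a PDB "
                "without CRYST1); the analysis requires a periodic cell"
            )
        if not np.allclose(ts.dimensions[3:], 90.0, atol=1e-3):
            raise ValueError("triclinic cells are not supported; orthorhombic cells only")
        cell = PeriodicCell(np.asarray(ts.dimensions[:3], dtype=float) * ANGSTROM_PM)
        radii, masses = _sites_from_elements(elements, radii_override)
        frames.append(
            ParticleConfiguration(
                positions=np.asarray(ts.positions, dtype=float) * ANGSTROM_PM,
                radii=radii,
                masses=masses,
                cell=cell,
                elements=elements,
                frame_index=k,
            )
        )
    return frames


def read_trajectory(
    path: str | Path,
    fmt: str | None = None,
    n_frames: int | None = None,
    radii_override: dict[str, float] | None = None,
) -> list[ParticleConfiguration]:
    """Read a trajectory into per-frame configurations.

    ``fmt`` is one of ``extxyz``, ``gro``, ``pdb``, ``lammpsdump``; inferred
    from the file extension when omitted.  ``n_frames`` selects that many
    equidistant frames from the trajectory.
    """
    path = Path(path)
    if fmt is None:
        try:
            fmt = _EXT_FORMAT[path.suffix.lower()]
        except KeyError:
            raise ValueError(f"cannot infer trajectory format from suffix {path.suffix!r}") from None
    if fmt == "extxyz":
        frames = read_extxyz(path, radii_override)
    elif fmt in ("gro", "pdb", "lammpsdump"):
        frames = _read_mdanalysis(path, fmt, radii_override)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    if n_frames is not None and n_frames < len(frames):
        pick = np.unique(np.linspace(0, len(frames) - 1, n_frames).round().astype(int))
        frames = [frames[i] for i in pick]
        for k, f in enumerate(frames):
            f.frame_index = k
    return frames


def write_extxyz(frames: Iterable[ParticleConfiguration], path: str | Path) -> None:
    """Write frames as extended XYZ with a Lattice cell key; coordinates in pm."""
    out = []
    for config in frames:
        e = config.cell.edges
        lattice = f"{e[0]:.6f} 0.0 0.0 0.0 {e[1]:.6f} 0.0 0.0 0.0 {e[2]:.6f}"
        out.append(str(config.n_sites))
        out.append(f'Lattice="{lattice}" Properties=species:S:1:pos:R:3 units=pm')
        elements = config.elements or ["X"] * config.n_sites
        for el, p in zip(elements, config.positions):
            out.append(f"{el} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def write_results(outdir: str | Path, results: dict, manifest: dict | None = None) -> list[Path]:
    """Write analysis results as plain-text tables.

    ``results`` maps observation names to
    :class:`~microhet.analysis.ObservationResult`; per observation a curve CSV
    and a radius-by-density histogram matrix are produced, plus one file per
    2D correlation analysis and a JSON manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, res in results.items():
        curve_path = outdir / f"curves_{name}.csv"
        res.curve_table().to_csv(curve_path, index=False)
        written.append(curve_path)

        hist_path = outdir / f"histograms_{name}.dat"
        hists = res.histograms
        edges = hists[0].edges
        header = (
            "# relative-density histograms (probability density, dimensionless)\n"
            f"# rows: {len(edges) - 1} bins, first column = bin centre; "
            "remaining columns: one per sampling radius\n"
            "# radii/pm: " + " ".join(f"{h.r_s:g}" for h in hists) + "\n"
            "# bin edges: " + " ".join(f"{e:g}" for e in edges) + "\n"
        )
        matrix = np.column_stack([hists[0].centers] + [h.densities for h in hists])
        with open(hist_path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, matrix, fmt="%.8g")
        written.append(hist_path)
    if manifest is not None:
        man_path = outdir / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        written.append(man_path)
    return written


def write_correlation(outdir: str | Path, corr) -> Path:
    """Write one 2D correlation histogram as whitespace-delimited text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"correlation_{corr.observation_a}_{corr.observation_b}_rs{corr.r_s:g}.dat"
    with open(path, "w") as fh:
        fh.write(
            f"# joint probability mass, rows = {corr.observation_a} bins, "
            f"columns = {corr.observation_b} bins, rS = {corr.r_s:g} pm\n"
            f"# pearson = {corr.pearson:.6f}\n"
            "# edges_a: " + " ".join(f"{e:g}" for e in corr.edges_a) + "\n"
            "# edges_b: " + " ".join(f"{e:g}" for e in corr.edges_b) + "\n"
        )
        np.savetxt(fh, corr.mass, fmt="%.8g")
    return path
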