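"""TOML analysis configuration mirroring the command-line workflow.

Example::

    [trajectory]
    path = "traj.xyz"          # extxyz | gro | pdb | lammpsdump
    n_frames = 200             # equidistant frames to use

    [sampling]
    grid = 150                 # grid points per axis
    radius_start_pm = 100.0
    radius_stop_pm = 2500.0
    radius_step_pm = 100.0

    [histogram]
    bins = 500

    [[observation]]
    name = "polar"
    select = "element Cl"
    radius_pm = 175.0
    mode = "particle"          # or "mass"

Observations may add ``group_size`` plus ``radius_pm`` to collapse the
selected sites, molecule by molecule, into pseudo-particles at their
geometric ring centres.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np

from .reference_stats import BinningSpec
from .sampling import Observation, SamplingSpec

__all__ = ["ObservationSpec", "AnalysisConfig", "load_config"]


@dataclass
class ObservationSpec:
    name: str
    select: str = "all"
    radius_pm: float | None = None
    mode: str = "particle"
    group_size: int | None = None  # pseudo-particle grouping

    def to_observation(self) -> Observation:
        if self.group_size is not None:
            # frames are first rewritten to pseudo-particles; the scan then
            # observes all pseudo-sites
            return Observation(self.name, "all", None, self.mode)
        return Observation(self.name, self.select, self.radius_pm, self.mode)


@dataclass
class AnalysisConfig:
    trajectory: str
    fmt: str | None = None
    n_frames: int | None = None
    grid: int = 150
    radii: tuple[float, ...] = ()
    bins: int = 500
    log_base: float | None = None
    seed: int = 0
    outdir: str = "microhet_out"
    observations: list[ObservationSpec] = dfield(default_factory=list)

    def sampling_spec(self) -> SamplingSpec:
        if not self.radii:
            raise ValueError("configuration defines no sampling radii")
        return SamplingSpec(grid=(self.grid,) * 3, radii=self.radii, n_frames=self.n_frames)

    def binning(self) -> BinningSpec:
        return BinningSpec(n_bins=self.bins)

    def manifest(self) -> dict:
        return {
            "trajectory": self.trajectory,
            "format": self.fmt,
            "n_frames": self.n_frames,
            "grid": self.grid,
            "radii_pm": list(self.radii),
            "histogram_bins": self.bins,
            "entropy_log_base": self.log_base or "e (nats)",
            "seed": self.seed,
            "observations": [vars(o) for o in self.observations],
        }


def load_config(path: str | Path) -> AnalysisConfig:
    raw = tomllib.loads(Path(path).read_text())
    traj = raw.get("trajectory", {})
    if "path" not in traj:
        raise ValueError(f"{path}: [trajectory] section must define 'path'")
    samp = raw.get("sampling", {})
    if "radii_pm" in samp:
        radii = tuple(float(r) for r in samp["radii_pm"])
    else:
        try:
            start = float(samp["radius_start_pm"])
            stop = float(samp["radius_stop_pm"])
            step = float(samp["radius_step_pm"])
        except KeyError as exc:
            raise ValueError(f"{path}: [sampling] must define radii_pm or a start/stop/step scan") from exc
        radii = tuple(np.arange(start, stop + 0.5 * step, step))
    hist = raw.get("histogram", {})
    obs = [
        ObservationSpec(
            name=o["name"],
            select=o.get("select", "all"),
            radius_pm=o.get("radius_pm"),
            mode=o.get("mode", "particle"),
            group_size=o.get("group_size"),
        )
        for o in raw.get("observation", [])
    ]
    if not obs:
        obs = [ObservationSpec(name="all")]
    return AnalysisConfig(
        trajectory=traj["path"],
        fmt=traj.get("format"),
        n_frames=traj.get("n_frames"),
        grid=int(samp.get("grid", 150)),
        radii=radii,
        bins=int(hist.get("bins", 500)),
        log_base=hist.get("log_base"),
        seed=int(raw.get("seed", 0)),
        outdir=raw.get("outdir", "microhet_out"),
        observations=obs,
    )
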