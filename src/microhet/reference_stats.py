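"""Histograms, ideal-gas reference, heterogeneity and entropy measures.

The relative-density samples of a :class:`~microhet.sampling.RelativeDensityField`
are summarized by

* a density-normalized histogram with the sample mean mu and the population
  standard deviation sigma (computed from the raw samples, not from bins);
* the ideal-gas reference: for n uniformly random point particles, the count
  k inside a sphere of volume V_S is binomial with inclusion probability
  p = V_S / V_Total, so the relative density k/(n p) has standard deviation
  sigma_IG = sqrt((1 - p) / (n p));
* the relative heterogeneity measure h_rel = sigma_Observed / sigma_IdealGas
  (> 1: heterogeneous, < 1: more regular than random);
* a histogram-based Shannon entropy H = -sum_i f(x_i) log f(x_i) w(x_i),
  reported relative to the ideal-gas reference entropy evaluated on the same
  bin grid;
* two-observation joint (2D) histograms with the Pearson correlation of the
  paired per-sphere densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import stats as sps

from .geometry import PeriodicCell
from .sampling import RelativeDensityField

__all__ = [
    "BinningSpec",
    "DensityHistogram",
    "IdealGasModel",
    "HeterogeneityCurve",
    "EntropyCurve",
    "CorrelationHistogram2D",
    "histogram",
    "ideal_gas_model",
    "h_rel",
    "shannon_entropy",
    "entropy_curve",
    "correlate",
]

DEFAULT_BINS = 500


@dataclass(frozen=True)
class BinningSpec:
    """Equal-width binning: ``n_bins`` bins over [lo, hi].

    When ``hi`` is None the upper edge defaults to ceil(max sample) per
    histogram, with a floor of 1 so near-empty fields still bin sensibly.
    """

    n_bins: int = DEFAULT_BINS
    lo: float = 0.0
    hi: float | None = None

    def edges(self, samples: NDArray[np.float64] | None = None) -> NDArray[np.float64]:
        hi = self.hi
        if hi is None:
            if samples is None or samples.size == 0:
                raise ValueError("binning range is open and no samples were given")
            hi = max(1.0, math.ceil(float(np.max(samples))))
        if hi <= self.lo:
            raise ValueError("histogram range is empty")
        return np.linspace(self.lo, hi, self.n_bins + 1)


@dataclass
class DensityHistogram:
    """Density-normalized histogram of relative densities.

    ``densities`` integrate to 1 over the bin edges; ``mu`` and ``sigma`` come
    from the raw samples.
    """

    edges: NDArray[np.float64]
    densities: NDArray[np.float64]
    mu: float
    sigma: float
    n: int
    r_s: float | None = None
    observation: str | None = None

    @property
    def centers(self) -> NDArray[np.float64]:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> NDArray[np.float64]:
        return np.diff(self.edges)

    def check_normalized(self, tol: float = 1e-9) -> None:
        total = float(np.sum(self.densities * self.widths))
        if abs(total - 1.0) > tol:
            raise AssertionError(f"histogram mass {total} != 1")


def histogram(
    field: RelativeDensityField | NDArray[np.float64],
    bins: BinningSpec | None = None,
) -> DensityHistogram:
    """Bin a relative-density field into a density-normalized histogram.

    sigma is the population standard deviation of the raw samples; with fewer
    than two distinct samples it is 0 and the histogram is still valid.
    """
    if isinstance(field, RelativeDensityField):
        samples = field.values
        r_s, obs = field.r_s, field.observation
    else:
        samples = np.asarray(field, dtype=float).ravel()
        r_s, obs = None, None
    if samples.size == 0:
        raise ValueError("cannot histogram an empty field")
    bins = bins or BinningSpec()
    edges = bins.edges(samples)
    counts, _ = np.histogram(samples, bins=edges)
    widths = np.diff(edges)
    densities = counts / (samples.size * widths)
    return DensityHistogram(
        edges=edges,
        densities=densities,
        mu=float(np.mean(samples)),
        sigma=float(np.std(samples)),
        n=int(samples.size),
        r_s=r_s,
        observation=obs,
    )


@dataclass
class IdealGasModel:
    """Binomial reference for n uniformly random point particles.

    The relative-density support points are x_k = k / (n p) for k = 0..n.
    """

    n: int
    p: float
    v_sphere: float
    v_total: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("particle count n must be >= 1")
        if not 0.0 < self.p < 1.0:
            raise ValueError(
                f"inclusion probability p = V_S/V_Total must lie in (0, 1), got {self.p:g}"
            )

    @property
    def support(self) -> NDArray[np.float64]:
        """Relative densities k/(n p) for k = 0..n."""
        return np.arange(self.n + 1) / (self.n * self.p)

    @property
    def pmf(self) -> NDArray[np.float64]:
        return sps.binom.pmf(np.arange(self.n + 1), self.n, self.p)

    @property
    def sigma(self) -> float:
        """Closed-form standard deviation of the relative density."""
        return math.sqrt((1.0 - self.p) / (self.n * self.p))

    def rasterize(self, edges: NDArray[np.float64]) -> DensityHistogram:
        """Place the pmf mass onto a bin grid and convert to densities.

        Mass at support points beyond the last edge is clipped into the final
        bin so the rasterized histogram always integrates to 1, which keeps
        entropy differences on a shared grid meaningful.
        """
        edges = np.asarray(edges, dtype=float)
        x = self.support
        mass = self.pmf
        which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)
        binned = np.zeros(edges.size - 1)
        np.add.at(binned, which, mass)
        widths = np.diff(edges)
        densities = binned / binned.sum() / widths
        return DensityHistogram(
            edges=edges,
            densities=densities,
            mu=1.0,
            sigma=self.sigma,
            n=self.n,
        )


def ideal_gas_model(n: int, r_s: float, cell: PeriodicCell | float) -> IdealGasModel:
    """Build the binomial reference for n particles and sphere radius ``r_s``."""
    v_total = cell.volume if isinstance(cell, PeriodicCell) else float(cell)
    v_sphere = 4.0 / 3.0 * math.pi * float(r_s) ** 3
    p = v_sphere / v_total
    if p >= 1.0:
        raise ValueError("sampling sphere is larger than the simulation cell (p >= 1)")
    return IdealGasModel(n=int(n), p=p, v_sphere=v_sphere, v_total=v_total)


def h_rel(sigma_observed: float, model: IdealGasModel | float) -> float:
    """Relative heterogeneity measure: sigma_Observed / sigma_IdealGas."""
    sigma_ig = model.sigma if isinstance(model, IdealGasModel) else float(model)
    if sigma_ig <= 0:
        raise ValueError("ideal-gas sigma must be positive")
    if sigma_observed < 0:
        raise ValueError("observed sigma cannot be negative")
    return float(sigma_observed) / sigma_ig


@dataclass
class HeterogeneityCurve:
    """h_rel as a function of sampling-sphere radius for one observation."""

    observation: str
    r_s: NDArray[np.float64]
    sigma_observed: NDArray[np.float64]
    sigma_idealgas: NDArray[np.float64]

    @property
    def h_rel(self) -> NDArray[np.float64]:
        return self.sigma_observed / self.sigma_idealgas


def shannon_entropy(hist: DensityHistogram, log_base: float | None = None) -> float:
    """Histogram estimate of the Shannon (differential) entropy.

    H = -sum_i f(x_i) * log f(x_i) * w(x_i) over occupied bins; empty bins
    contribute zero.  Natural logarithm by default.
    """
    f = hist.densities
    w = hist.widths
    nz = f > 0
    h = -float(np.sum(f[nz] * np.log(f[nz]) * w[nz]))
    if log_base is not None:
        h /= math.log(log_base)
    return h


@dataclass
class EntropyCurve:
    """Observed and ideal-gas reference entropies per sampling radius."""

    observation: str
    r_s: NDArray[np.float64]
    h_observed: NDArray[np.float64]
    h_idealgas: NDArray[np.float64]
    log_base: float | None = None  # None = natural log (nats)

    @property
    def delta_h(self) -> NDArray[np.float64]:
        return self.h_observed - self.h_idealgas


def entropy_curve(
    fields: list[RelativeDensityField],
    models: list[IdealGasModel],
    bins: BinningSpec | None = None,
    log_base: float | None = None,
) -> EntropyCurve:
    """Entropies of observed fields minus the ideal-gas reference, per radius.

    For each radius the binomial pmf is rasterized onto the observed
    histogram's bin grid, so both entropies share identical bins and their
    difference is binning-independent to first order.
    """
    if len(fields) != len(models):
        raise ValueError("need one ideal-gas model per field")
    bins = bins or BinningSpec()
    r_s, h_obs, h_ig = [], [], []
    for fld, model in zip(fields, models):
        hist = histogram(fld, bins)
        ref = model.rasterize(hist.edges)
        r_s.append(fld.r_s)
        h_obs.append(shannon_entropy(hist, log_base))
        h_ig.append(shannon_entropy(ref, log_base))
    return EntropyCurve(
        observation=fields[0].observation,
        r_s=np.asarray(r_s),
        h_observed=np.asarray(h_obs),
        h_idealgas=np.asarray(h_ig),
        log_base=log_base,
    )


@dataclass
class CorrelationHistogram2D:
    """Joint histogram of two paired per-sphere relative densities."""

    r_s: float
    observation_a: str
    observation_b: str
    edges_a: NDArray[np.float64]
    edges_b: NDArray[np.float64]
    mass: NDArray[np.float64]  # probability mass per 2D bin, sums to 1
    pearson: float

    def marginal(self, axis: int) -> NDArray[np.float64]:
        """Probability mass of one axis, summing out the other."""
        return self.mass.sum(axis=1 - axis)


def correlate(
    field_a: RelativeDensityField,
    field_b: RelativeDensityField,
    bins: BinningSpec | None = None,
) -> CorrelationHistogram2D:
    """Joint 2D histogram plus Pearson correlation of paired sphere densities.

    Fields must come from the same grid, frame set and sampling radius so
    sphere k of one field is sphere k of the other.
    """
    if field_a.r_s != field_b.r_s:
        raise ValueError("fields must share the sampling radius")
    if field_a.grid != field_b.grid or field_a.n_frames != field_b.n_frames:
        raise ValueError("fields must be scanned on the same grid and frames to pair spheres")
    if field_a.n != field_b.n:
        raise ValueError("fields have different sphere counts and cannot be paired")
    bins = bins or BinningSpec(n_bins=100)
    edges_a = bins.edges(field_a.values)
    edges_b = bins.edges(field_b.values)
    counts, _, _ = np.histogram2d(field_a.values, field_b.values, bins=[edges_a, edges_b])
    mass = counts / counts.sum()
    if np.std(field_a.values) == 0 or np.std(field_b.values) == 0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(field_a.values, field_b.values)[0, 1])
    return CorrelationHistogram2D(
        r_s=field_a.r_s,
        observation_a=field_a.observation,
        observation_b=field_b.observation,
        edges_a=edges_a,
        edges_b=edges_b,
        mass=mass,
        pearson=pearson,
    )
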