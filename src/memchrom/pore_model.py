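"""Polydisperse parallel-pore (Hagen-Poiseuille) membrane model.

The membrane is idealized as a bundle of straight cylindrical pores of
length L whose radii follow a truncated Gaussian distribution f(r_p). Each
pore carries laminar flow proportional to r_p^4, so the per-pore mean
velocity is quadratic in r_p,

    v_m(r_p) = <v> * (M2 / M4) * r_p^2,

with M2, M4 the second and fourth raw moments of f and <v> = F/(eps A) the
interstitial velocity. A step fed to the bundle emerges as the flow-weighted
superposition of delayed copies of itself, one delay tau(r_p) = L/v_m(r_p)
per pore class — the entire breakthrough shape comes from the spread of
residence times across the distribution (intra-pore Taylor-Aris dispersion
is deliberately neglected).

Units are CGS throughout (radii in cm); :meth:`PoreSizeDistribution.from_microns`
accepts the bench-unit parameterization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    FluidContext,
    MembraneColumn,
    OperatingConditions,
    Signal,
    interstitial_velocity,
    um_to_cm,
)

__all__ = [
    "PoreSizeDistribution",
    "PoreBundle",
    "discretize_psd",
    "pore_count",
    "pore_flowrate",
    "flow_fractions",
    "pore_velocity",
    "breakthrough",
    "default_time_grid",
]


@dataclass(frozen=True)
class PoreSizeDistribution:
    """Truncated Gaussian pore-radius distribution, discretized on a uniform grid.

    The effective support is [max(r_min, mu - m*sigma), min(r_max, mu + m*sigma)]
    with m = sqrt(2 ln(1/theta)): radii where the Gaussian density has fallen
    below the relative threshold ``theta`` of its mode carry no pores. Bin
    midpoint densities are renormalized so the discrete weights f_k * dr sum
    to one.
    """

    mu: float
    sigma: float
    r_min: float
    r_max: float
    theta: float
    n_bins: int
    radii: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)
    bin_width: float

    @classmethod
    def discretize(
        cls,
        mu: float,
        sigma: float,
        r_min: float = 0.0,
        r_max: float = math.inf,
        theta: float = 1e-5,
        n_bins: int = 600,
    ) -> "PoreSizeDistribution":
        if sigma <= 0:
            raise ValueError(f"psd.sigma must be > 0, got {sigma}")
        if not 0 <= r_min < mu:
            raise ValueError(f"psd: need 0 <= r_min < mu, got r_min={r_min}, mu={mu}")
        if not r_max > mu:
            raise ValueError(f"psd: need r_max > mu, got r_max={r_max}, mu={mu}")
        if not 0 < theta < 1:
            raise ValueError(f"psd.theta must lie in (0, 1), got {theta}")
        if n_bins < 1:
            raise ValueError(f"psd.n_bins must be >= 1, got {n_bins}")
        m = math.sqrt(2.0 * math.log(1.0 / theta))
        lo = max(r_min, mu - m * sigma)
        hi = min(r_max, mu + m * sigma)
        if not hi > lo:
            raise ValueError(
                f"psd: empty effective support [{lo:g}, {hi:g}] "
                f"(theta={theta:g}, bounds [{r_min:g}, {r_max:g}])"
            )
        edges = np.linspace(lo, hi, n_bins + 1)
        radii = 0.5 * (edges[:-1] + edges[1:])
        dr = edges[1] - edges[0]
        dens = np.exp(-0.5 * ((radii - mu) / sigma) ** 2) / (math.sqrt(2 * math.pi) * sigma)
        dens = dens / (dens.sum() * dr)
        return cls(mu, sigma, r_min, r_max, theta, n_bins, radii, dens, dr)

    @classmethod
    def from_microns(
        cls,
        mu_um: float,
        sigma_um: float,
        r_min_um: float = 0.0,
        r_max_um: float = math.inf,
        theta: float = 1e-5,
        n_bins: int = 600,
    ) -> "PoreSizeDistribution":
        return cls.discretize(
            um_to_cm(mu_um),
            um_to_cm(sigma_um),
            um_to_cm(r_min_um),
            r_max_um if math.isinf(r_max_um) else um_to_cm(r_max_um),
            theta,
            n_bins,
        )

    def raw_moment(self, order: int) -> float:
        """Discrete raw moment M_k = sum r^k f(r) dr of the truncated density."""
        return float(np.sum(self.radii**order * self.density) * self.bin_width)

    @property
    def support(self) -> tuple:
        """(low, high) edges of the retained radius range, cm."""
        return float(self.radii[0] - self.bin_width / 2), float(
            self.radii[-1] + self.bin_width / 2
        )


def discretize_psd(
    mu: float,
    sigma: float,
    r_min: float = 0.0,
    r_max: float = math.inf,
    theta: float = 1e-5,
    n_bins: int = 600,
) -> PoreSizeDistribution:
    """Functional alias for :meth:`PoreSizeDistribution.discretize` (cm units)."""
    return PoreSizeDistribution.discretize(mu, sigma, r_min, r_max, theta, n_bins)


class PoreBundle:
    """A discretized pore-size distribution mounted in a column at a flowrate.

    Precomputes, per radius class: the flow fraction w_k (proportional to
    r^4 f dr, normalized), the mean in-pore velocity v_m(r_k) and the
    residence time tau(r_k) = L / v_m(r_k). These three arrays are all that
    the breakthrough superposition and the moment oracles need.
    """

    def __init__(
        self,
        psd: PoreSizeDistribution,
        column: MembraneColumn,
        conditions: OperatingConditions,
    ) -> None:
        self.psd = psd
        self.column = column
        self.conditions = conditions
        self.interstitial_velocity = conditions.interstitial_velocity(column)

        r, f, dr = psd.radii, psd.density, psd.bin_width
        self.m2 = psd.raw_moment(2)
        self.m4 = psd.raw_moment(4)
        self.n_pores = column.void_fraction * column.area / (math.pi * self.m2)
        w = r**4 * f * dr
        self.flow_fractions = w / w.sum()
        self.velocities = self.interstitial_velocity * (self.m2 / self.m4) * r**2
        self.residence_times = column.thickness / self.velocities

    @property
    def t_lag(self) -> float:
        """Residence time of the fastest (largest) retained pore, s."""
        return float(self.residence_times.min())

    def tau_mean(self) -> float:
        """Flow-weighted mean residence time; identically L/<v>."""
        return float(np.sum(self.flow_fractions * self.residence_times))

    def tau_variance(self) -> float:
        """Flow-weighted variance of the residence time, s^2."""
        mean = self.tau_mean()
        return float(np.sum(self.flow_fractions * (self.residence_times - mean) ** 2))

    def breakthrough(
        self,
        time_grid: Optional[np.ndarray] = None,
        inlet: Optional[Signal] = None,
        c0: float = 1.0,
    ) -> Signal:
        return breakthrough(self, time_grid=time_grid, inlet=inlet, c0=c0)


def pore_count(psd: PoreSizeDistribution, column: MembraneColumn) -> float:
    """Total number of pores n_p = eps*A / (pi * M2): the pore cross-sections
    tile the void area of the frontal face."""
    return column.void_fraction * column.area / (math.pi * psd.raw_moment(2))


def pore_flowrate(r_p, column: MembraneColumn, fluid: FluidContext):
    """Hagen-Poiseuille volumetric flow through one pore of radius r_p:
    F(r_p) = dP * pi * r_p^4 / (8 * eta * L)."""
    r_p = np.asarray(r_p, dtype=float)
    q = fluid.pressure_drop * math.pi * r_p**4 / (8.0 * fluid.viscosity * column.thickness)
    return q if q.ndim else float(q)


def flow_fractions(bundle: PoreBundle) -> np.ndarray:
    """Per-class fraction of the total flowrate, w_k ~ r_k^4 f_k dr (sums to 1).

    Pressure drop and viscosity cancel: only the r^4 weighting survives.
    """
    return bundle.flow_fractions


def pore_velocity(bundle: PoreBundle, r_p) -> np.ndarray:
    """Mean velocity in a pore of radius r_p: <v> * (M2/M4) * r_p^2, cm/s."""
    r_p = np.asarray(r_p, dtype=float)
    v = bundle.interstitial_velocity * (bundle.m2 / bundle.m4) * r_p**2
    return v if v.ndim else float(v)


def default_time_grid(
    bundle: PoreBundle,
    n_intervals: int = 4000,
    plateau_threshold: float = 0.999,
    extension: float = 0.2,
) -> np.ndarray:
    """Uniform grid [0, T] with T = (1+extension) * (time at which a unit-step
    breakthrough first exceeds ``plateau_threshold``).

    For the pure delay-superposition model that time is the flow-weighted
    ``plateau_threshold`` quantile of the residence-time distribution, so no
    preliminary simulation is needed.
    """
    order = np.argsort(bundle.residence_times)
    tau_sorted = bundle.residence_times[order]
    cumw = np.cumsum(bundle.flow_fractions[order])
    idx = int(np.searchsorted(cumw, plateau_threshold))
    idx = min(idx, tau_sorted.size - 1)
    t_end = (1.0 + extension) * tau_sorted[idx]
    return np.linspace(0.0, t_end, n_intervals + 1)


def breakthrough(
    bundle: PoreBundle,
    time_grid: Optional[np.ndarray] = None,
    inlet: Optional[Signal] = None,
    c0: float = 1.0,
) -> Signal:
    """Outlet concentration from residence-time superposition (step response).

    With no explicit ``inlet`` an ideal step of amplitude ``c0`` applied at
    t = 0 is assumed and the outlet is the flow-weighted staircase
    c_out(t) = c0 * sum_k w_k * 1[t >= tau_k]. A sampled inlet is delayed
    per class and superposed (the inlet is taken to be zero before its first
    sample).
    """
    if time_grid is None:
        time_grid = default_time_grid(bundle)
    t = np.asarray(time_grid, dtype=float)
    tau = bundle.residence_times
    w = bundle.flow_fractions
    if t[-1] < tau.max():
        warnings.warn(
            f"time grid ends at {t[-1]:g} s but the slowest pore class needs "
            f"{tau.max():g} s: breakthrough tail is truncated",
            stacklevel=2,
        )
    if inlet is None:
        order = np.argsort(tau)
        cumw = np.concatenate([[0.0], np.cumsum(w[order])])
        out = c0 * cumw[np.searchsorted(tau[order], t, side="right")]
    else:
        out = np.zeros_like(t)
        for wk, tk in zip(w, tau):
            out += wk * np.interp(t - tk, inlet.times, inlet.values, left=0.0,
                                  right=inlet.values[-1])
    return Signal(t, out, kind="step_response")
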