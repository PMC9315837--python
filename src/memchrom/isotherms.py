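"""Equilibrium adsorption isotherms and the lumped capacity factor.

The transport equation lumps local adsorption equilibrium into a
concentration-dependent multiplier of the accumulation term,

    phi(c) = 1 + ((1 - eps)/eps) * sum_sites q_m K_d / (c + K_d)^2,

which is 1 + ((1-eps)/eps) * dq/dc. Adsorbed-phase concentrations q are per
unit volume of *solid* membrane material, so (1 - eps) multiplies q in every
mass balance. An irreversible site is the K_d -> 0 limit, whose dq/dc is a
Dirac spike at c = 0; it is regularized by substituting a small delta (mg/mL)
for the vanishing K_d inside phi only (the isotherm itself keeps the exact
discontinuous form).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np

__all__ = [
    "Isotherm",
    "Langmuir",
    "BiLangmuir",
    "SingularIsothermError",
    "equilibrium_loading",
    "regularized_loading",
    "capacity_factor",
    "loading_curve_csv",
]

ArrayLike = Union[float, np.ndarray]


class SingularIsothermError(ZeroDivisionError):
    """Capacity factor requested at c = 0 for an unregularized K_d = 0 site."""


@dataclass(frozen=True)
class Isotherm:
    """Base class; concrete isotherms expose ``sites`` as (q_m, K_d) pairs."""

    @property
    def variant(self) -> str:
        raise NotImplementedError

    @property
    def sites(self) -> Sequence[Tuple[float, float]]:
        raise NotImplementedError

    @property
    def total_capacity(self) -> float:
        """Saturation loading sum(q_m), mg per mL of solid."""
        return sum(q for q, _ in self.sites)

    def _validate(self) -> None:
        for q_m, k_d in self.sites:
            if q_m < 0 or k_d < 0:
                raise ValueError(
                    f"{self.variant}: q_m and K_d must be >= 0, got ({q_m}, {k_d})"
                )
        if not any(q > 0 for q, _ in self.sites):
            raise ValueError(f"{self.variant}: at least one q_m must be > 0")


@dataclass(frozen=True)
class Langmuir(Isotherm):
    """Single-site Langmuir isotherm: q = q_m c / (K_d + c).

    q_m is mg per mL of solid membrane material, K_d is mg/mL.
    """

    q_m: float
    k_d: float

    def __post_init__(self) -> None:
        self._validate()

    @property
    def variant(self) -> str:
        return "langmuir"

    @property
    def sites(self):
        return ((self.q_m, self.k_d),)


@dataclass(frozen=True)
class BiLangmuir(Isotherm):
    """Two-site (bi-)Langmuir isotherm, one site per interaction class.

    Conventionally the first site is the (quasi-)irreversible one (K_d = 0
    means infinitely strong binding) and the second the reversible one.
    """

    q_m_irr: float
    k_d_irr: float
    q_m_rev: float
    k_d_rev: float

    def __post_init__(self) -> None:
        self._validate()

    @property
    def variant(self) -> str:
        return "bi_langmuir"

    @property
    def sites(self):
        return ((self.q_m_irr, self.k_d_irr), (self.q_m_rev, self.k_d_rev))


def _check_concentration(c: ArrayLike) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    return c


def equilibrium_loading(iso: Isotherm, c: ArrayLike) -> ArrayLike:
    """Adsorbed concentration q(c), mg per mL of solid.

    For a site with K_d = 0 exactly the term is q_m for c > 0 and 0 at c = 0
    (the irreversible-binding step); all other sites follow q_m c/(K_d + c).
    """
    carr = _check_concentration(c)
    q = np.zeros_like(carr)
    for q_m, k_d in iso.sites:
        if k_d == 0.0:
            q = q + q_m * (carr > 0)
        else:
            q = q + q_m * carr / (k_d + carr)
    return q if isinstance(c, np.ndarray) else float(q)


def regularized_loading(iso: Isotherm, c: ArrayLike, delta: float) -> ArrayLike:
    """q(c) with K_d = 0 sites replaced by K_d = delta.

    This is the isotherm actually implied by the delta-regularized capacity
    factor; transport mass audits use it so that held + adsorbed mass is
    exactly consistent with the PDE being integrated.
    """
    carr = _check_concentration(c)
    q = np.zeros_like(carr)
    for q_m, k_d in iso.sites:
        k = k_d if k_d > 0 else delta
        if k == 0.0:
            q = q + q_m * (carr > 0)
        else:
            q = q + q_m * carr / (k + carr)
    return q if isinstance(c, np.ndarray) else float(q)


def capacity_factor(
    iso: Isotherm, c: ArrayLike, void_fraction: float, delta: float = 1e-3
) -> ArrayLike:
    """Dimensionless multiplier of dc/dt in the lumped transport equation.

    phi(c) = 1 + ((1-eps)/eps) * sum q_m K/(c + K)^2 with K = K_d, or K =
    delta where K_d = 0. phi >= 1 always and decreases with c (the front
    slows most where the isotherm is steepest, i.e. at low concentration).

    Raises
    ------
    SingularIsothermError
        If delta = 0 while some K_d = 0 and c = 0 (a genuine Dirac term).
    """
    carr = _check_concentration(c)
    if not 0 < void_fraction < 1:
        raise ValueError(f"void_fraction must lie in (0, 1), got {void_fraction}")
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    total = np.zeros_like(carr)
    for q_m, k_d in iso.sites:
        k = k_d if k_d > 0 else delta
        if k == 0.0:
            if q_m > 0 and np.any(carr == 0):
                raise SingularIsothermError(
                    "capacity factor is singular: K_d = 0 with delta = 0 at c = 0"
                )
            # q_m * k / (c+k)^2 -> 0 as k -> 0 for c > 0
            continue
        total = total + q_m * k / (carr + k) ** 2
    phi = 1.0 + (1.0 - void_fraction) / void_fraction * total
    return phi if isinstance(c, np.ndarray) else float(phi)


def loading_curve_csv(iso: Isotherm, c_grid: np.ndarray, path) -> None:
    """Write a q(c) curve as ``c_mg_ml,q_mg_ml`` CSV (12 significant digits)."""
    c_grid = np.asarray(c_grid, dtype=float)
    q = equilibrium_loading(iso, c_grid)
    np.savetxt(
        path,
        np.column_stack([c_grid, q]),
        fmt="%.12g",
        delimiter=",",
        header="c_mg_ml,q_mg_ml",
        comments="",
    )
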