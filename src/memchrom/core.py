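"""Domain types, unit conventions and configuration loading.

The internal unit system is CGS: lengths in cm, times in s, masses in mg,
volumes in mL (== cm^3), so concentrations are mg/mL and flowrates cm^3/s.
User-facing constructors accept the usual bench units (mL/min, um) through
explicitly named arguments or classmethods; nothing converts implicitly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "MembraneColumn",
    "OperatingConditions",
    "ExtraColumnConfig",
    "FluidContext",
    "Signal",
    "NumericsConfig",
    "SimulationConfig",
    "interstitial_velocity",
    "superficial_velocity",
    "ml_min_to_cm3_s",
    "cm3_s_to_ml_min",
    "um_to_cm",
    "cm_to_um",
    "load_config",
]

SCHEMA_VERSION = 1

#: seconds per minute; 1 mL/min = (1/60) cm^3/s
_S_PER_MIN = 60.0


def ml_min_to_cm3_s(flowrate_ml_min: float) -> float:
    """Convert a flowrate from mL/min to cm^3/s."""
    return flowrate_ml_min / _S_PER_MIN


def cm3_s_to_ml_min(flowrate_cm3_s: float) -> float:
    """Convert a flowrate from cm^3/s to mL/min."""
    return flowrate_cm3_s * _S_PER_MIN


def um_to_cm(length_um: float) -> float:
    return length_um * 1e-4


def cm_to_um(length_cm: float) -> float:
    return length_cm * 1e4


class ConfigError(ValueError):
    """A configuration file or parameter set violates the documented schema."""


@dataclass(frozen=True)
class MembraneColumn:
    """Geometry and porosity of a stacked-membrane bed.

    Parameters
    ----------
    thickness : float
        Total bed thickness L along the flow axis, cm.
    area : float
        Frontal cross-section area A, cm^2.
    void_fraction : float
        Bed porosity (void fraction) epsilon, dimensionless, in (0, 1).
    n_layers : int
        Number of stacked membrane sheets (informational only).
    """

    thickness: float
    area: float
    void_fraction: float
    n_layers: int = 1

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ConfigError(f"column.thickness: must be > 0 cm, got {self.thickness}")
        if not self.area > 0:
            raise ConfigError(f"column.area: must be > 0 cm^2, got {self.area}")
        if not 0 < self.void_fraction < 1:
            raise ConfigError(
                f"column.void_fraction: must lie strictly in (0, 1), got {self.void_fraction}"
            )
        if self.n_layers < 1:
            raise ConfigError(f"column.n_layers: must be >= 1, got {self.n_layers}")

    @classmethod
    def from_disc(
        cls,
        thickness: float,
        diameter: float,
        void_fraction: float,
        n_layers: int = 1,
    ) -> "MembraneColumn":
        """Build a column from a circular disc diameter (cm); A = pi d^2 / 4."""
        return cls(thickness, math.pi * diameter**2 / 4.0, void_fraction, n_layers)


def superficial_velocity(column: MembraneColumn, flowrate: float) -> float:
    """Superficial (empty-bed) velocity u = F / A, cm/s."""
    return flowrate / column.area


def interstitial_velocity(column: MembraneColumn, flowrate: float) -> float:
    """Mean interstitial velocity <v> = F / (epsilon * A), cm/s.

    This is the average fluid velocity inside the void space and the velocity
    that appears in the convection-dispersion equation and in the definition
    of the dispersivity alpha = D_L / <v>.
    """
    return flowrate / (column.void_fraction * column.area)


@dataclass(frozen=True)
class OperatingConditions:
    """Feed flowrate and concentration for a frontal-loading run.

    ``flowrate`` is stored in cm^3/s; use :meth:`ml_per_min` for bench units.
    ``feed_concentration`` (c0) is in mg/mL.
    """

    flowrate: float
    feed_concentration: float = 1.0

    def __post_init__(self) -> None:
        if not self.flowrate > 0:
            raise ConfigError(f"conditions.flowrate: must be > 0, got {self.flowrate}")
        if self.feed_concentration < 0:
            raise ConfigError(
                f"conditions.feed_concentration: must be >= 0, got {self.feed_concentration}"
            )

    @classmethod
    def ml_per_min(
        cls, flowrate_ml_min: float, feed_concentration: float = 1.0
    ) -> "OperatingConditions":
        return cls(ml_min_to_cm3_s(flowrate_ml_min), feed_concentration)

    @property
    def flowrate_ml_min(self) -> float:
        return cm3_s_to_ml_min(self.flowrate)

    def superficial_velocity(self, column: MembraneColumn) -> float:
        return superficial_velocity(column, self.flowrate)

    def interstitial_velocity(self, column: MembraneColumn) -> float:
        return interstitial_velocity(column, self.flowrate)


@dataclass(frozen=True)
class ExtraColumnConfig:
    """Extra-column (system) volumes: a stirred mixer plus flow-dependent tubing.

    The plug-flow (tubing) volume grows linearly with the set flowrate:
    ``V_pfr(F) = v_pfr_intercept + v_pfr_slope * F[mL/min]`` (all volumes mL).
    """

    v_cstr: float = 0.0
    v_pfr_intercept: float = 0.0
    v_pfr_slope: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v_cstr", "v_pfr_intercept", "v_pfr_slope"):
            if getattr(self, name) < 0:
                raise ConfigError(
                    f"extra_column.{name}: must be >= 0 mL, got {getattr(self, name)}"
                )

    def v_pfr(self, flowrate: float) -> float:
        """Effective plug-flow volume (mL) at a flowrate given in cm^3/s."""
        return self.v_pfr_intercept + self.v_pfr_slope * cm3_s_to_ml_min(flowrate)


@dataclass(frozen=True)
class FluidContext:
    """Pressure drop and viscosity, needed only for absolute per-pore flowrates.

    Both cancel out of the flow-fraction and pore-velocity relations, so most
    of the pore-bundle model never touches this object. Use one consistent
    unit system (CGS: dyn/cm^2 and poise, or SI throughout).
    """

    pressure_drop: float
    viscosity: float

    def __post_init__(self) -> None:
        if not self.pressure_drop > 0:
            raise ConfigError(f"fluid.pressure_drop must be > 0, got {self.pressure_drop}")
        if not self.viscosity > 0:
            raise ConfigError(f"fluid.viscosity must be > 0, got {self.viscosity}")


_SIGNAL_KINDS = ("step_response", "pulse_response", "inlet")


@dataclass
class Signal:
    """A sampled concentration time series at the column inlet or outlet.

    ``times`` are in seconds and must be strictly increasing; ``values`` are
    concentrations (mg/mL) or the dimensionless ratio c/c0. Evaluating the
    signal at arbitrary times interpolates linearly; times before the first
    sample evaluate to 0 (signals are implicitly zero before they start) and
    times after the last sample hold the final value.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "step_response"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in _SIGNAL_KINDS:
            raise ConfigError(f"signal.kind: must be one of {_SIGNAL_KINDS}, got {self.kind!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ConfigError("signal: times and values must be 1-d arrays of equal length")
        if self.times.size < 2:
            raise ConfigError("signal: need at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise ConfigError("signal.times: must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("signal.values: must be finite")
        if self.kind == "pulse_response" and np.any(self.values < 0):
            raise ConfigError("signal.values: a pulse response must be non-negative")

    def __call__(self, t: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        return np.interp(t, self.times, self.values, left=0.0, right=self.values[-1])

    def to_csv(self, path: Union[str, Path], normalized: bool = False) -> None:
        """Write ``time_s,concentration`` (or ``time_s,c_over_c0``) at 12 digits."""
        header = "time_s,c_over_c0" if normalized else "time_s,concentration"
        data = np.column_stack([self.times, self.values])
        np.savetxt(path, data, fmt="%.12g", delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path: Union[str, Path], kind: str = "step_response") -> "Signal":
        with open(path) as fh:
            header = fh.readline().strip().split(",")
        if header[0] != "time_s" or header[1] not in ("concentration", "c_over_c0"):
            raise ConfigError(
                f"{path}: expected header 'time_s,concentration' or 'time_s,c_over_c0', "
                f"got {','.join(header)!r}"
            )
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1], kind=kind)


@dataclass(frozen=True)
class NumericsConfig:
    """Numerical knobs shared by the solvers.

    delta is the regularization concentration (mg/mL) substituted for an
    exactly-zero dissociation constant in the capacity factor; the time-grid
    triple controls the breakthrough sampling used by the moments pipeline
    (number of intervals, the c/c0 level defining the grid end, and the
    fractional extension past that level).
    """

    n_cells: int = 400
    rtol: float = 1e-8
    atol: float = 1e-10
    delta: float = 1e-3
    time_grid_intervals: int = 4000
    plateau_threshold: float = 0.999
    grid_extension: float = 0.2

    def __post_init__(self) -> None:
        if self.n_cells < 50:
            raise ConfigError(f"numerics.n_cells: must be >= 50, got {self.n_cells}")
        if not (self.rtol > 0 and self.atol > 0):
            raise ConfigError("numerics: tolerances must be > 0")
        if self.delta < 0:
            raise ConfigError(f"numerics.delta: must be >= 0, got {self.delta}")
        if not 0 < self.plateau_threshold < 1:
            raise ConfigError("numerics.plateau_threshold: must lie in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Fully validated configuration for any workflow in the package."""

    column: MembraneColumn
    conditions: OperatingConditions
    isotherm: Optional[object] = None  # memchrom.isotherms.Isotherm
    psd: Optional[object] = None  # memchrom.pore_model.PoreSizeDistribution
    extra_column: ExtraColumnConfig = field(default_factory=ExtraColumnConfig)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    dispersivity: Optional[float] = None  # cm, measured material property
    dispersion: Optional[float] = None  # cm^2/s, overrides dispersivity if set
    epsilon_in_eq6: bool = False

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def axial_dispersion(self) -> float:
        """D_L (cm^2/s) from the configured dispersion or dispersivity."""
        if self.dispersion is not None:
            return self.dispersion
        if self.dispersivity is not None:
            v = self.conditions.interstitial_velocity(self.column)
            return self.dispersivity * v
        raise ConfigError("config: neither 'dispersion' nor 'dispersivity' is set")


def _require(section: dict, key: str, section_name: str):
    if key not in section:
        raise ConfigError(f"{section_name}.{key}: missing required key")
    return section[key]


def _parse_column(sec: dict) -> MembraneColumn:
    if "thickness_cm" in sec:
        thickness = float(sec["thickness_cm"])
    elif "thickness_um" in sec:
        thickness = um_to_cm(float(sec["thickness_um"]))
    else:
        raise ConfigError("column: one of thickness_cm / thickness_um is required")
    eps = float(_require(sec, "void_fraction", "column"))
    n_layers = int(sec.get("n_layers", 1))

    area = float(sec["area_cm2"]) if "area_cm2" in sec else None
    diameter = float(sec["diameter_cm"]) if "diameter_cm" in sec else None
    if diameter is not None:
        from_d = math.pi * diameter**2 / 4.0
        if area is not None and abs(from_d - area) / area > 1e-3:
            raise ConfigError(
                f"column: diameter_cm implies area {from_d:.6g} cm^2 but area_cm2 is "
                f"{area:.6g} cm^2 (disagreement > 0.1%)"
            )
        area = from_d
    if area is None:
        raise ConfigError("column: one of area_cm2 / diameter_cm is required")
    return MembraneColumn(thickness, area, eps, n_layers)


def _parse_isotherm(sec: dict):
    from . import isotherms

    variant = _require(sec, "variant", "isotherm")
    if variant == "langmuir":
        return isotherms.Langmuir(
            q_m=float(_require(sec, "q_m", "isotherm")),
            k_d=float(_require(sec, "k_d", "isotherm")),
        )
    if variant == "bi_langmuir":
        return isotherms.BiLangmuir(
            q_m_irr=float(_require(sec, "q_m_irr", "isotherm")),
            k_d_irr=float(_require(sec, "k_d_irr", "isotherm")),
            q_m_rev=float(_require(sec, "q_m_rev", "isotherm")),
            k_d_rev=float(_require(sec, "k_d_rev", "isotherm")),
        )
    raise ConfigError(f"isotherm.variant: unknown variant {variant!r}")


def _parse_psd(sec: dict):
    from . import pore_model

    return pore_model.PoreSizeDistribution.from_microns(
        mu_um=float(_require(sec, "mu_um", "psd")),
        sigma_um=float(_require(sec, "sigma_um", "psd")),
        r_min_um=float(sec.get("rmin_um", 0.0)),
        r_max_um=float(sec.get("rmax_um", math.inf)),
        theta=float(sec.get("theta", 1e-5)),
        n_bins=int(sec.get("n_bins", 600)),
    )


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Load and validate a YAML/JSON configuration file.

    The documented schema has a ``schema_version`` key and sections
    ``column``, ``conditions`` and optionally ``isotherm``, ``psd``,
    ``extra_column``, ``numerics``, ``dispersion``, ``moments``. All units in
    the file are bench units (mL/min, um, mL) unless the key name says cm.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"schema_version: expected {SCHEMA_VERSION}, got {version!r}"
        )

    if "column" not in raw:
        raise ConfigError("column: missing required section")
    column = _parse_column(raw["column"])

    if "conditions" not in raw:
        raise ConfigError("conditions: missing required section")
    cs = raw["conditions"]
    conditions = OperatingConditions.ml_per_min(
        float(_require(cs, "flowrate_ml_min", "conditions")),
        float(cs.get("feed_concentration_mg_ml", 1.0)),
    )

    isotherm = _parse_isotherm(raw["isotherm"]) if "isotherm" in raw else None
    psd = _parse_psd(raw["psd"]) if "psd" in raw else None

    ec = raw.get("extra_column", {})
    extra = ExtraColumnConfig(
        v_cstr=float(ec.get("v_cstr_ml", 0.0)),
        v_pfr_intercept=float(ec.get("v_pfr_intercept_ml", 0.0)),
        v_pfr_slope=float(ec.get("v_pfr_slope_ml_per_ml_min", 0.0)),
    )

    nm = raw.get("numerics", {})
    numerics = NumericsConfig(
        n_cells=int(nm.get("n_cells", 400)),
        rtol=float(nm.get("rtol", 1e-8)),
        atol=float(nm.get("atol", 1e-10)),
        delta=float(nm.get("delta_mg_ml", 1e-3)),
        time_grid_intervals=int(nm.get("time_grid_intervals", 4000)),
        plateau_threshold=float(nm.get("plateau_threshold", 0.999)),
        grid_extension=float(nm.get("grid_extension", 0.2)),
    )

    disp = raw.get("dispersion", {})
    alpha = disp.get("alpha_cm")
    d_l = disp.get("d_l_cm2_s")

    mo = raw.get("moments", {})
    eps_flag = bool(mo.get("epsilon_in_eq6", False))

    return SimulationConfig(
        column=column,
        conditions=conditions,
        isotherm=isotherm,
        psd=psd,
        extra_column=extra,
        numerics=numerics,
        dispersivity=None if alpha is None else float(alpha),
        dispersion=None if d_l is None else float(d_l),
        epsilon_in_eq6=eps_flag,
    )
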