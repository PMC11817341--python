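"""Thermophysical properties of shrimp tissue and water sub-models.

The tissue is treated as a two-component (water + protein), isotropic,
non-deformable medium.  Component densities, heat capacities and thermal
conductivities are quadratic polynomials in temperature (°C); mixture values
follow standard composition-based mixing rules:

* density     -- harmonic (mass-fraction-weighted reciprocal) mixing,
* heat capacity -- linear mass-fraction mixing,
* conductivity  -- mean of the parallel (volume-fraction arithmetic) and
  series (volume-fraction harmonic) bounds.

Water activity is given by a sigmoid desorption isotherm
``a_w = exp(-A * exp(-B * X_db**C))`` with parameter sets fitted at 60 and
70 °C air temperature; saturation vapor pressure by an Antoine correlation
validated against steam tables; the latent heat of vaporization by a linear
steam-table fit.

Unit conventions: property polynomials take °C; ``saturation_pressure``
takes K.  Each function documents its own units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ComponentPropertyTable",
    "Composition",
    "SorptionIsotherm",
    "DEFAULT_PROPERTY_TABLE",
    "mixture_density",
    "mixture_heat_capacity",
    "mixture_conductivity",
    "water_activity",
    "saturation_pressure",
    "latent_heat",
    "wet_basis",
    "dry_basis",
    "solids_concentration",
]

#: Gas constant, J/(mol K)
R_GAS = 8.314
#: Molar mass of water, kg/mol
M_WATER = 0.018

_T_MIN_C, _T_MAX_C = 0.0, 100.0


def _check_temperature_celsius(T):
    T = np.asarray(T, dtype=float)
    if np.any(T < _T_MIN_C) or np.any(T > _T_MAX_C):
        raise ValueError(
            f"temperature {T} °C outside the property-model domain "
            f"[{_T_MIN_C}, {_T_MAX_C}] °C"
        )
    return T


@dataclass(frozen=True)
class ComponentPropertyTable:
    """Quadratic polynomial coefficients (a0, a1, a2) in T (°C) per
    component and property.

    Keys are ``(component, property)`` with component in {"water",
    "protein"} and property in {"density", "heat_capacity",
    "conductivity"}.  Units: kg/m3, J/(kg K), W/(m K).
    """

    coefficients: dict = field(
        default_factory=lambda: {
            ("water", "density"): (997.18, 3.1439e-3, -3.7574e-3),
            ("protein", "density"): (1329.9, -0.51840, 0.0),
            ("water", "heat_capacity"): (4176.2, -0.0909, 5.4731e-3),
            ("protein", "heat_capacity"): (2008.2, 1.2089, -1.3129e-3),
            ("water", "conductivity"): (0.57109, 1.762e-3, -6.7036e-6),
            ("protein", "conductivity"): (0.17881, 1.958e-3, -2.7178e-6),
        }
    )

    def evaluate(self, component: str, prop: str, T_celsius):
        """Evaluate one component property polynomial at T (°C)."""
        T = _check_temperature_celsius(T_celsius)
        a0, a1, a2 = self.coefficients[(component, prop)]
        return a0 + a1 * T + a2 * T * T


DEFAULT_PROPERTY_TABLE = ComponentPropertyTable()


@dataclass(frozen=True)
class Composition:
    """Local composition of the tissue.

    x_w + x_p = 1; x_w = X_db / (1 + X_db); the solids volumetric
    concentration c_s (kg/m3) is constant in time for a non-deformable
    medium.
    """

    x_w: float
    x_p: float
    X_db: float
    c_s: float

    def __post_init__(self):
        if np.any(np.asarray(self.X_db) < 0):
            raise ValueError("dry-basis moisture X_db must be >= 0")
        if np.any(np.asarray(self.c_s) <= 0):
            raise ValueError("solids concentration c_s must be > 0")
        if not np.allclose(np.asarray(self.x_w) + np.asarray(self.x_p), 1.0):
            raise ValueError("mass fractions must sum to 1")

    @classmethod
    def from_dry_basis(cls, X_db, c_s: float) -> "Composition":
        X_db = np.asarray(X_db, dtype=float)
        x_w = X_db / (1.0 + X_db)
        return cls(x_w=x_w, x_p=1.0 - x_w, X_db=X_db, c_s=c_s)

    @classmethod
    def from_concentrations(cls, c_w, c_s: float) -> "Composition":
        """Composition from water concentration c_w (kg/m3) and solids
        concentration c_s (kg/m3)."""
        c_w = np.asarray(c_w, dtype=float)
        return cls.from_dry_basis(c_w / c_s, c_s)


def mixture_density(comp: Composition, T_celsius,
                    table: ComponentPropertyTable = DEFAULT_PROPERTY_TABLE):
    """Tissue density (kg/m3): 1/rho = x_w/rho_w + x_p/rho_p."""
    rho_w = table.evaluate("water", "density", T_celsius)
    rho_p = table.evaluate("protein", "density", T_celsius)
    return 1.0 / (comp.x_w / rho_w + comp.x_p / rho_p)


def mixture_heat_capacity(comp: Composition, T_celsius,
                          table: ComponentPropertyTable = DEFAULT_PROPERTY_TABLE):
    """Tissue specific heat capacity (J/(kg K)): linear mixing."""
    cp_w = table.evaluate("water", "heat_capacity", T_celsius)
    cp_p = table.evaluate("protein", "heat_capacity", T_celsius)
    return comp.x_w * cp_w + comp.x_p * cp_p


def mixture_conductivity(comp: Composition, T_celsius,
                         table: ComponentPropertyTable = DEFAULT_PROPERTY_TABLE):
    """Tissue thermal conductivity (W/(m K)).

    Mean of the parallel (volume-fraction arithmetic) and series
    (volume-fraction harmonic) bounds, with volume fractions
    v_i = x_i * rho_mix / rho_i.
    """
    k_w = table.evaluate("water", "conductivity", T_celsius)
    k_p = table.evaluate("protein", "conductivity", T_celsius)
    rho_w = table.evaluate("water", "density", T_celsius)
    rho_p = table.evaluate("protein", "density", T_celsius)
    rho = mixture_density(comp, T_celsius, table)
    v_w = comp.x_w * rho / rho_w
    v_p = comp.x_p * rho / rho_p
    k_parallel = v_w * k_w + v_p * k_p
    k_series = 1.0 / (v_w / k_w + v_p / k_p)
    return 0.5 * (k_parallel + k_series)


Nesting = Literal["exp-inside", "power-outside"]

_ISOTHERM_PARAMS = {60: (6.03, 11.00, 0.0980), 70: (11.09, 11.54, 0.7195)}

# Floor on X_db inside the isotherm: X**(C-1) with C<1 diverges at 0.
_X_FLOOR = 1e-12


@dataclass(frozen=True)
class SorptionIsotherm:
    """Sigmoid desorption isotherm linking dry-basis moisture to water
    activity.

    Default nesting ``power-outside``:
    a_w = exp(-A * exp(-B * X_db) * X_db**C).  The raw correlation is
    non-monotone below its stationary point X* = C/B (a_w would rise
    again as the material dries out, which is unphysical), so moisture
    contents below X* evaluate at X* -- a monotone floor that leaves the
    fitted range untouched.  The alternative reading of the correlation,
    ``exp-inside``: a_w = exp(-A * exp(-B * X_db**C)), is a clean
    monotone sigmoid from exp(-A) to 1 and is kept selectable.
    """

    A: float
    B: float
    C: float
    air_temperature_label: float = 60.0
    nesting: Nesting = "power-outside"

    @classmethod
    def for_air_temperature(cls, label: int | float,
                            nesting: Nesting = "power-outside") -> "SorptionIsotherm":
        """Fitted parameter set for 60 or 70 °C drying air."""
        key = int(round(float(label)))
        if key not in _ISOTHERM_PARAMS:
            raise ValueError(f"no fitted isotherm for {label} °C (have 60, 70)")
        A, B, C = _ISOTHERM_PARAMS[key]
        return cls(A=A, B=B, C=C, air_temperature_label=float(key), nesting=nesting)

    @property
    def stationary_point(self) -> float:
        """X* = C/B, the monotone floor of the power-outside nesting."""
        return self.C / self.B

    def water_activity(self, X_db):
        """Water activity in [0, 1] at dry-basis moisture X_db (kg/kg)."""
        X = np.asarray(X_db, dtype=float)
        if np.any(X < 0):
            raise ValueError("X_db must be >= 0")
        if self.nesting == "exp-inside":
            # 0**C -> 0 for C > 0, giving the dry limit exp(-A)
            aw = np.exp(-self.A * np.exp(-self.B * X**self.C))
        elif self.nesting == "power-outside":
            Xc = np.maximum(X, self.stationary_point)
            aw = np.exp(-self.A * np.exp(-self.B * Xc) * Xc**self.C)
        else:  # pragma: no cover - guarded by type
            raise ValueError(f"unknown nesting {self.nesting!r}")
        return np.clip(aw, 0.0, 1.0)

    def water_activity_derivative(self, X_db):
        """d a_w / d X_db, used to linearize the evaporative flux."""
        X = np.maximum(np.asarray(X_db, dtype=float), _X_FLOOR)
        aw = self.water_activity(X)
        if self.nesting == "exp-inside":
            inner = np.exp(-self.B * X**self.C)
            return aw * self.A * inner * self.B * self.C * X ** (self.C - 1.0)
        # power-outside: f = A e^{-BX} X^C; a_w' = a_w A e^{-BX} X^{C-1} (B X - C);
        # zero below the monotone floor
        d = aw * self.A * np.exp(-self.B * X) * X ** (self.C - 1.0) * (
            self.B * X - self.C
        )
        return np.where(X <= self.stationary_point, 0.0, d)


def water_activity(iso: SorptionIsotherm, X_db):
    """Functional form of :meth:`SorptionIsotherm.water_activity`."""
    return iso.water_activity(X_db)


# Antoine correlation for water, T in K, result in Pa:
#   Psat = 1e3 * exp(16.3872 - 3885.70 / (T - 42.98))
# Matches steam tables within 1% over 0-100 °C.
_ANTOINE_A, _ANTOINE_B, _ANTOINE_C = 16.3872, 3885.70, 42.98
_T_MIN_K, _T_MAX_K = 273.15, 380.0


def saturation_pressure(T_kelvin):
    """Saturation vapor pressure of water (Pa) at T (K), valid on
    [273.15, 380] K."""
    T = np.asarray(T_kelvin, dtype=float)
    if np.any(T < _T_MIN_K) or np.any(T > _T_MAX_K):
        raise ValueError(
            f"temperature {T} K outside the Antoine domain [{_T_MIN_K}, {_T_MAX_K}] K"
        )
    return 1e3 * np.exp(_ANTOINE_A - _ANTOINE_B / (T - _ANTOINE_C))


def latent_heat(T_celsius):
    """Latent heat of water vaporization (J/kg) at T (°C).

    Linear steam-table fit 2.501e6 - 2.36e3 * T, within 0.5% of tabulated
    values at 0 °C and 1% at 100 °C.
    """
    T = _check_temperature_celsius(T_celsius)
    return 2.501e6 - 2.36e3 * T


def wet_basis(X_db):
    """Convert dry-basis moisture (kg/kg solids) to wet-basis fraction."""
    X = np.asarray(X_db, dtype=float)
    return X / (1.0 + X)


def dry_basis(x_wb):
    """Convert wet-basis moisture fraction to dry basis (kg/kg solids)."""
    x = np.asarray(x_wb, dtype=float)
    return x / (1.0 - x)


def solids_concentration(X_db0: float, T_celsius: float = 25.0,
                         table: ComponentPropertyTable = DEFAULT_PROPERTY_TABLE) -> float:
    """Solids volumetric concentration c_s (kg/m3) of fresh tissue at
    initial moisture X_db0 and temperature T (°C).

    c_s = x_p * rho_mix stays constant afterwards (non-deformable medium).
    """
    comp = Composition.from_dry_basis(float(X_db0), c_s=1.0)  # placeholder c_s
    rho = mixture_density(comp, T_celsius, table)
    return float(comp.x_p * rho)
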