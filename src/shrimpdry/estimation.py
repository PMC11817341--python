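"""Parameter estimation for the drying model.

Covers the experimental estimation chain: the lumped-capacitance fit of
the convective heat transfer coefficient from an aluminum surrogate body
(with Biot-number and tray-resistance validity checks), the exhaustive
grid search for the moisture diffusivity D and mass transfer coefficient
h_m against drying curves, the sorption-isotherm refit, and the
goodness-of-fit statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .geometry import Mesh
from .properties import SorptionIsotherm
from .solver import DryingCurve, SimulationConfig, simulate

__all__ = [
    "LumpedBodySpec",
    "HeatTransferFit",
    "GridSpec",
    "EstimationResult",
    "fit_heat_transfer_coefficient",
    "biot_number",
    "resistance_check",
    "simulate_grid",
    "evaluate_grid_objective",
    "grid_search_D_hm",
    "fit_isotherm",
    "goodness_of_fit",
]


@dataclass(frozen=True)
class LumpedBodySpec:
    """Aluminum surrogate body used for the h_T estimation.

    Defaults are the measured mass, area and volume of the cylindrical
    aluminum object, with handbook aluminum properties and the tray wall
    thickness used for the conductive-resistance check.
    """

    mass: float = 0.0111214          # kg
    surface_area: float = 0.0017893  # m2
    volume: float = 4.15e-6          # m3
    heat_capacity: float = 900.0     # J/(kg K)
    conductivity: float = 229.0      # W/(m K)
    wall_thickness: float = 0.0005   # m (tray)

    def __post_init__(self):
        for f in ("mass", "surface_area", "volume", "heat_capacity",
                  "conductivity", "wall_thickness"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


class HeatTransferFit(NamedTuple):
    h_T: float
    r_squared: float
    rmse: float
    tau: float          # m c_p / (h_T A), s
    quality_warning: bool


def lumped_temperature(t, h_T: float, body: LumpedBodySpec,
                       T_air: float, T0: float):
    """Closed-form lumped-capacitance heating curve T(t), K."""
    k = h_T * body.surface_area / (body.mass * body.heat_capacity)
    return T_air + (T0 - T_air) * np.exp(-k * np.asarray(t, dtype=float))


def fit_heat_transfer_coefficient(times, temperatures, body: LumpedBodySpec,
                                  T_air: float, T0: float | None = None
                                  ) -> HeatTransferFit:
    """Nonlinear least-squares fit of the lumped heating curve.

    Only the group h_T A / (m c_p) is identifiable from the curve; h_T is
    reported using the known surface area, mass and heat capacity.
    Requires at least 5 points and T0 != T_air.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(temperatures, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 points to fit h_T")
    if T0 is None:
        T0 = float(y[0])
    if math.isclose(T0, T_air):
        raise ValueError("initial temperature equals air temperature")

    # log-linear starting value, guarded against non-positive ratios
    ratio = (y - T_air) / (T0 - T_air)
    mask = ratio > 1e-6
    slope = -1e-3
    if mask.sum() >= 2:
        A = np.vstack([t[mask], np.ones(mask.sum())]).T
        slope = float(np.linalg.lstsq(A, np.log(ratio[mask]), rcond=None)[0][0])
    h0 = max(-slope, 1e-6) * body.mass * body.heat_capacity / body.surface_area

    popt, _ = curve_fit(
        lambda tt, h: lumped_temperature(tt, h, body, T_air, T0),
        t, y, p0=[max(h0, 1e-3)], bounds=(0, np.inf), maxfev=10000,
    )
    h_T = float(popt[0])
    pred = lumped_temperature(t, h_T, body, T_air, T0)
    r2, rmse = goodness_of_fit(y, pred)
    trend_wrong = (y[-1] - y[0]) * (T_air - T0) <= 0
    warn = trend_wrong or (r2 < 0.9) or np.ptp(y) < 1e-9
    if warn:
        warnings.warn(
            f"lumped heating series poorly conditioned (R2={r2:.3f}); "
            "reported h_T may be unreliable"
        )
    tau = body.mass * body.heat_capacity / (h_T * body.surface_area)
    return HeatTransferFit(h_T=h_T, r_squared=r2, rmse=rmse, tau=tau,
                           quality_warning=bool(warn))


def biot_number(h_T: float, body: LumpedBodySpec) -> float:
    """Bi = h_T (V/A) / k: lumped-capacitance validity requires Bi < 0.1."""
    return h_T * (body.volume / body.surface_area) / body.conductivity


class ResistanceCheck(NamedTuple):
    R_cond: float       # m2 K/W, tray wall conduction
    R_conv: float       # m2 K/W, external convection
    tray_negligible: bool


def resistance_check(body: LumpedBodySpec, h_T: float) -> ResistanceCheck:
    """Tray conduction vs external convection resistances (m2 K/W)."""
    r_cond = body.wall_thickness / body.conductivity
    r_conv = 1.0 / h_T
    return ResistanceCheck(r_cond, r_conv, r_cond / r_conv < 0.01)


# ---------------------------------------------------------------------------
# Exhaustive grid search for (D, h_m)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Candidate grid for the exhaustive (D, h_m) search.

    Defaults are the screening grid used for the estimation: h_m from
    0.005 to 0.01 m/s step 0.001, D from 5e-10 to 1e-9 m2/s step 5e-11
    (66 candidate pairs).
    """

    D_values: tuple = tuple(np.round(np.arange(5e-10, 1.0e-9 + 1e-13, 5e-11), 14))
    h_m_values: tuple = tuple(np.round(np.arange(0.005, 0.01 + 1e-9, 0.001), 6))


@dataclass
class EstimationResult:
    parameters: dict             # name -> {"value": ..., "units": ...}
    objective: float             # RMSE-based objective at the optimum
    table: pd.DataFrame | None   # full grid objective table
    diagnostics: dict = field(default_factory=dict)


def simulate_grid(mesh: Mesh, cfg_template: SimulationConfig,
                  grid: GridSpec | None = None) -> dict:
    """Run the simulation for every (D, h_m) candidate pair.

    Returns {(D, h_m): DryingCurve}; failed runs map to None.  Iteration
    order is D ascending (outer), h_m ascending (inner).
    """
    from dataclasses import replace

    grid = grid or GridSpec()
    out = {}
    for D in grid.D_values:
        for h_m in grid.h_m_values:
            cfg = replace(cfg_template, D=float(D), h_m=float(h_m))
            try:
                out[(float(D), float(h_m))] = simulate(mesh, cfg).curve
            except Exception:
                out[(float(D), float(h_m))] = None
    return out


def _series_rmse(sim_times, sim_values, obs_times, obs_values):
    pred = np.interp(obs_times, sim_times, sim_values)
    return float(np.sqrt(np.mean((obs_values - pred) ** 2)))


def evaluate_grid_objective(grid_curves: dict, data: pd.DataFrame,
                            mode: str = "both") -> pd.DataFrame:
    """Objective table for simulated grid curves against observed data.

    data columns: time_s, Xdb_avg and/or T_probe_C.  mode "both" sums the
    min-max-normalized RMSEs of moisture and temperature; "temperature"
    and "moisture" use a single observable.  Failed simulations get an
    infinite objective.
    """
    use_x = mode in ("both", "moisture") and "Xdb_avg" in data
    use_t = mode in ("both", "temperature") and "T_probe_C" in data
    if not (use_x or use_t):
        raise ValueError(f"mode {mode!r} has no matching columns in data")
    # moisture and temperature may live on different sampling grids
    # (merged frames carry NaNs for the missing observable)
    if use_x:
        dx = data[["time_s", "Xdb_avg"]].dropna()
        tx_obs = dx["time_s"].to_numpy(dtype=float)
        x_obs = dx["Xdb_avg"].to_numpy(dtype=float)
        use_x = len(x_obs) > 0
    if use_t:
        dt_ = data[["time_s", "T_probe_C"]].dropna()
        tT_obs = dt_["time_s"].to_numpy(dtype=float)
        T_obs = dt_["T_probe_C"].to_numpy(dtype=float)
        use_t = len(T_obs) > 0
    x_span = float(np.ptp(x_obs)) if use_x else 1.0
    T_span = float(np.ptp(T_obs)) if use_t else 1.0

    rows = []
    for (D, h_m), curve in grid_curves.items():
        if curve is None:
            rows.append({"D": D, "h_m": h_m, "rmse_X": np.inf,
                         "rmse_T": np.inf, "objective": np.inf})
            continue
        rx = (_series_rmse(curve.times, curve.Xdb_avg, tx_obs, x_obs)
              if use_x else np.nan)
        rt = (_series_rmse(curve.times, curve.T_probe - 273.15, tT_obs, T_obs)
              if use_t else np.nan)
        obj = 0.0
        if use_x:
            obj += rx / max(x_span, 1e-12)
        if use_t:
            obj += rt / max(T_span, 1e-12)
        rows.append({"D": D, "h_m": h_m, "rmse_X": rx, "rmse_T": rt,
                     "objective": obj})
    return pd.DataFrame(rows)


def grid_search_D_hm(data: pd.DataFrame, mesh: Mesh,
                     cfg_template: SimulationConfig,
                     grid: GridSpec | None = None, mode: str = "both",
                     grid_curves: dict | None = None) -> EstimationResult:
    """Exhaustive search for (D, h_m) minimizing the drying-curve RMSE.

    Runs one simulation per candidate pair (or reuses precomputed
    grid_curves), evaluates the objective against the observed curve, and
    returns the argmin pair with the full objective table.  Ties break
    toward smaller D, then smaller h_m (the iteration order).
    """
    grid = grid or GridSpec()
    if grid_curves is None:
        grid_curves = simulate_grid(mesh, cfg_template, grid)
    table = evaluate_grid_objective(grid_curves, data, mode=mode)
    best = int(np.argmin(table["objective"].to_numpy()))  # first minimum
    row = table.iloc[best]
    return EstimationResult(
        parameters={
            "D": {"value": float(row["D"]), "units": "m2/s"},
            "h_m": {"value": float(row["h_m"]), "units": "m/s"},
        },
        objective=float(row["objective"]),
        table=table,
        diagnostics={"mode": mode, "n_candidates": len(table),
                     "n_failed": int(np.isinf(table["objective"]).sum())},
    )


# ---------------------------------------------------------------------------
# Isotherm refit and statistics
# ---------------------------------------------------------------------------

def fit_isotherm(X_db, a_w, initial_guess: Sequence[float] | None = None,
                 nesting: str = "power-outside", n_starts: int = 3,
                 air_temperature_label: float = 60.0) -> SorptionIsotherm:
    """Least-squares fit of the sigmoid isotherm parameters (A, B, C).

    Uses a small multistart (perturbed initial guesses) to avoid local
    minima.  Requires >= 4 points with a_w in (0, 1).
    """
    X = np.asarray(X_db, dtype=float)
    y = np.asarray(a_w, dtype=float)
    if len(X) < 4:
        raise ValueError("need at least 4 (X_db, a_w) points")
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("a_w data must lie strictly inside (0, 1)")

    p0 = np.asarray(initial_guess if initial_guess is not None
                    else [8.0, 11.0, 0.5], dtype=float)

    def resid(p):
        iso = SorptionIsotherm(A=p[0], B=p[1], C=p[2],
                               air_temperature_label=air_temperature_label,
                               nesting=nesting)
        return iso.water_activity(X) - y

    best = None
    rng = np.random.default_rng(0)
    for k in range(max(1, n_starts)):
        start = p0 if k == 0 else p0 * rng.uniform(0.5, 1.8, size=3)
        try:
            sol = least_squares(resid, start, bounds=([1e-6] * 3, [1e3, 1e3, 5.0]),
                                max_nfev=5000)
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e-3:
        warnings.warn("isotherm fit did not converge cleanly; "
                      f"residual cost {None if best is None else best.cost}")
    p = best.x
    return SorptionIsotherm(A=float(p[0]), B=float(p[1]), C=float(p[2]),
                            air_temperature_label=air_temperature_label,
                            nesting=nesting)


def goodness_of_fit(observed, predicted) -> tuple[float, float]:
    """(R2, RMSE) between observed and predicted series.

    R2 = 1 - SS_res/SS_tot (may be negative); RMSE = sqrt(mean squared
    residual).  Zero variance in the observations makes R2 undefined
    (returned as nan with a warning).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ss_res = float(np.sum((obs - pred) ** 2))
    rmse = math.sqrt(ss_res / obs.size)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero variance in observations: R2 undefined")
        return float("nan"), rmse
    return 1.0 - ss_res / ss_tot, rmse
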