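"""Post-processing and numerical experiments on drying curves.

Drying-rate curves, drying-stage detection (warming up, constant rate,
falling rate), time-to-target-moisture, the parametric sensitivity sweeps
over D, the convective coefficients and air humidity, and the irregular
vs cylindrical geometry comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .geometry import Mesh
from .solver import DryingCurve, SimulationConfig, simulate

__all__ = [
    "SensitivitySpec",
    "DryingStages",
    "TimeToMoisture",
    "drying_rate_curve",
    "detect_stages",
    "plateau_temperature",
    "time_to_moisture",
    "sensitivity_sweep",
    "geometry_comparison",
    "GeometryComparison",
]


def drying_rate_curve(curve: DryingCurve) -> tuple[np.ndarray, np.ndarray]:
    """(X_db, dX_db/dt) pairs from central differences of the average
    moisture, with the rate reported positive (kg water / kg solids per
    minute).

    A non-monotone moisture series is differentiated as-is with a
    warning.
    """
    t, X = curve.times, curve.Xdb_avg
    if len(t) < 3:
        raise ValueError("need at least 3 samples for a rate curve")
    if np.any(np.diff(X) > 1e-12):
        warnings.warn("moisture series is not monotone non-increasing; "
                      "rates reported as-is")
    rate = -np.gradient(X, t) * 60.0  # per minute, positive = drying
    return X, rate


class DryingStages(NamedTuple):
    warmup_end_s: float
    constant_rate_window: tuple[float, float]
    falling_rate_start_s: float
    degenerate: bool


def detect_stages(curve: DryingCurve, band: float = 0.05) -> DryingStages:
    """Split a drying run into warming-up, constant-rate and falling-rate
    stages.

    The constant-rate window is the maximal contiguous interval where the
    drying rate stays within `band` (default 5 %) of its maximum; the
    warm-up precedes it and the falling-rate period follows.  A window
    shorter than two samples is flagged degenerate.
    """
    t = curve.times
    _, rate = drying_rate_curve(curve)
    r_max = float(np.max(rate))
    if r_max <= 0:
        return DryingStages(t[-1], (t[-1], t[-1]), t[-1], True)
    near = rate >= (1.0 - band) * r_max
    # maximal contiguous run containing the argmax
    imax = int(np.argmax(rate))
    i0 = imax
    while i0 > 0 and near[i0 - 1]:
        i0 -= 1
    i1 = imax
    while i1 < len(near) - 1 and near[i1 + 1]:
        i1 += 1
    degenerate = (i1 - i0 + 1) < 2
    return DryingStages(
        warmup_end_s=float(t[i0]),
        constant_rate_window=(float(t[i0]), float(t[i1])),
        falling_rate_start_s=float(t[i1]),
        degenerate=degenerate,
    )


def plateau_temperature(curve: DryingCurve,
                        stages: DryingStages | None = None) -> float:
    """Time-averaged probe temperature (K) over the constant-rate
    window."""
    stages = stages or detect_stages(curve)
    t0, t1 = stages.constant_rate_window
    sel = (curve.times >= t0) & (curve.times <= t1)
    if not np.any(sel):
        sel = np.argmin(np.abs(curve.times - 0.5 * (t0 + t1)))
    return float(np.mean(curve.T_probe[sel]))


class TimeToMoisture(NamedTuple):
    reached: bool
    time_s: float        # nan when not reached
    final_Xdb: float


def time_to_moisture(curve: DryingCurve, X_target: float) -> TimeToMoisture:
    """First time the average moisture crosses X_target, by linear
    interpolation between bracketing samples."""
    t, X = curve.times, curve.Xdb_avg
    if X[0] <= X_target:
        return TimeToMoisture(True, 0.0, float(X[-1]))
    below = np.flatnonzero(X <= X_target)
    if below.size == 0:
        return TimeToMoisture(False, float("nan"), float(X[-1]))
    i = int(below[0])
    frac = (X[i - 1] - X_target) / (X[i - 1] - X[i])
    return TimeToMoisture(True, float(t[i - 1] + frac * (t[i] - t[i - 1])),
                          float(X[-1]))


@dataclass(frozen=True)
class SensitivitySpec:
    """Scenario grid for the parametric sensitivity study.

    transfer_multipliers apply jointly to (h_T, h_m); D_multipliers to the
    diffusivity; rh_levels replace the baseline air humidity.  The
    baseline multiplier 1.0 must be included.
    """

    D_multipliers: tuple = (0.5, 1.0, 2.0)
    transfer_multipliers: tuple = (0.5, 0.8, 1.0, 1.5, 2.0, 3.0)
    rh_levels: tuple = (5.0, 20.0, 40.0)
    X_target: float = 1.0

    def __post_init__(self):
        for seq in (self.D_multipliers, self.transfer_multipliers):
            if any(m <= 0 for m in seq):
                raise ValueError("multipliers must be positive")
            if 1.0 not in seq:
                raise ValueError("the baseline multiplier 1.0 must be included")


def _scenario_row(name, param, value, curve, X_target):
    stages = detect_stages(curve)
    ttm = time_to_moisture(curve, X_target)
    _, rate = drying_rate_curve(curve)
    return {
        "scenario": name,
        "parameter": param,
        "value": value,
        "time_to_target_min": ttm.time_s / 60.0 if ttm.reached else np.nan,
        "target_reached": ttm.reached,
        "plateau_T_C": plateau_temperature(curve, stages) - 273.15,
        "max_rate_per_min": float(np.max(rate)),
        "final_Xdb": float(curve.Xdb_avg[-1]),
    }


def sensitivity_sweep(mesh: Mesh, base_cfg: SimulationConfig,
                      spec: SensitivitySpec | None = None) -> pd.DataFrame:
    """One simulation per scenario in the sensitivity spec.

    Rows report time to the target moisture, the constant-rate plateau
    temperature and the maximum drying rate.  A failing scenario is
    logged and skipped; the multiplier-1.0 rows are bit-identical to a
    bare baseline run (the solver is deterministic).
    """
    spec = spec or SensitivitySpec()
    scenarios = []
    for m in spec.D_multipliers:
        scenarios.append((f"D x {m}", "D_multiplier", m, {"D": base_cfg.D * m}))
    for m in spec.transfer_multipliers:
        scenarios.append((f"hT,hm x {m}", "transfer_multiplier", m,
                          {"h_T": base_cfg.h_T * m, "h_m": base_cfg.h_m * m}))
    for rh in spec.rh_levels:
        scenarios.append((f"RH {rh}%", "RH_percent", rh, {"RH": rh}))
    rows = []
    for name, param, value, overrides in scenarios:
        try:
            curve = simulate(mesh, replace(base_cfg, **overrides)).curve
        except Exception as exc:  # keep the sweep going
            warnings.warn(f"scenario {name!r} failed: {exc}")
            continue
        rows.append(_scenario_row(name, param, value, curve, spec.X_target))
    return pd.DataFrame(rows)


@dataclass
class GeometryComparison:
    curve_a: DryingCurve
    curve_b: DryingCurve
    max_moisture_difference: float      # kg/kg, on the common time grid
    max_coldspot_difference: float      # K
    snapshots_a: list = field(default_factory=list)
    snapshots_b: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "max_moisture_difference_kg_kg": self.max_moisture_difference,
            "max_coldspot_difference_K": self.max_coldspot_difference,
        }


def geometry_comparison(mesh_a: Mesh, mesh_b: Mesh, cfg: SimulationConfig,
                        volume_tol: float = 0.05) -> GeometryComparison:
    """Paired drying runs on two equal-volume domains (e.g. irregular
    shrimp shape vs finite cylinder).

    Reports the maximum absolute differences between the average-moisture
    curves and between the cold-spot temperature curves.  Raises if the
    domain volumes differ by more than volume_tol.
    """
    va, vb = mesh_a.volume, mesh_b.volume
    if abs(va - vb) / max(va, vb) > volume_tol:
        raise ValueError(
            f"domain volumes differ by more than {volume_tol:.0%}: "
            f"{va:.3e} vs {vb:.3e} m3"
        )
    res_a = simulate(mesh_a, cfg)
    res_b = simulate(mesh_b, cfg)
    ca, cb = res_a.curve, res_b.curve
    xb = np.interp(ca.times, cb.times, cb.Xdb_avg)
    tb = np.interp(ca.times, cb.times, cb.T_coldspot)
    return GeometryComparison(
        curve_a=ca,
        curve_b=cb,
        max_moisture_difference=float(np.max(np.abs(ca.Xdb_avg - xb))),
        max_coldspot_difference=float(np.max(np.abs(ca.T_coldspot - tb))),
        snapshots_a=res_a.snapshots,
        snapshots_b=res_b.snapshots,
    )
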