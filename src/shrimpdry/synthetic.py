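"""Pseudo-experimental data generation.

Emulates the structure of the drying experiments so every estimation and
analysis stage is testable without laboratory data: drying curves sampled
every 15 min for the first hour and every 30 min until 180 min, probe
temperatures logged at 30 s intervals, replicate runs with additive
Gaussian measurement noise, aluminum-body heating curves, and bounded
random-walk humidity profiles.

All randomness flows from a single seeded generator per experiment; the
replicate index offsets the stream deterministically, so a fixed seed is
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import LumpedBodySpec, lumped_temperature
from .geometry import Mesh
from .solver import SimulationConfig, simulate

__all__ = [
    "ExperimentProtocol",
    "synth_drying_experiment",
    "synth_aluminum_heating",
    "synth_rh_profile",
]


@dataclass(frozen=True)
class ExperimentProtocol:
    """Sampling scheme and noise model of one drying experiment.

    Moisture is sampled at the listed minutes; temperature every
    temperature_interval_s seconds.  Default noise levels are of the
    order of the validation residuals of the fitted model (about 0.1
    kg/kg in moisture, 0.5 K in temperature).
    """

    moisture_sampling_min: tuple = (15, 30, 45, 60, 90, 120, 150, 180)
    temperature_interval_s: float = 30.0
    replicates: int = 3
    sigma_X: float = 0.1    # kg/kg
    sigma_T: float = 0.5    # K
    rh_band: tuple = (16.0, 23.0)  # %
    T_air_c: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if list(self.moisture_sampling_min) != sorted(self.moisture_sampling_min):
            raise ValueError("sampling times must be sorted")
        if self.sigma_X < 0 or self.sigma_T < 0:
            raise ValueError("noise levels must be non-negative")


def synth_drying_experiment(truth_cfg: SimulationConfig, mesh: Mesh,
                            protocol: ExperimentProtocol,
                            out_dir: str | Path | None = None
                            ) -> tuple[list[pd.DataFrame], dict]:
    """Simulate with truth parameters and emit noisy replicate curves.

    Returns (replicate data frames, truth sidecar dict).  With out_dir
    set, writes replicate_<k>.csv files and a truth.json sidecar
    recording the generating parameters.
    """
    curve = simulate(mesh, truth_cfg).curve
    t_X = np.asarray(protocol.moisture_sampling_min, dtype=float) * 60.0
    t_T = np.arange(0.0, truth_cfg.duration + 1e-9,
                    protocol.temperature_interval_s)
    X_true = np.interp(t_X, curve.times, curve.Xdb_avg)
    T_true = np.interp(t_T, curve.times, curve.T_probe)

    rng = np.random.default_rng(protocol.seed)
    streams = rng.spawn(protocol.replicates)
    reps = []
    for k in range(protocol.replicates):
        g = streams[k]
        x = X_true + g.normal(0.0, protocol.sigma_X, size=X_true.shape)
        Tn = T_true + g.normal(0.0, protocol.sigma_T, size=T_true.shape)
        df_x = pd.DataFrame({"time_s": t_X, "Xdb_avg": x})
        df_t = pd.DataFrame({"time_s": t_T, "T_probe_C": Tn - 273.15})
        df = pd.merge(df_t, df_x, on="time_s", how="outer").sort_values(
            "time_s", ignore_index=True)
        reps.append(df)

    truth = {
        "D_m2_s": truth_cfg.D,
        "h_m_m_s": truth_cfg.h_m,
        "h_T_W_m2K": truth_cfg.h_T,
        "T_air_K": truth_cfg.T_air if np.isscalar(truth_cfg.T_air) else "series",
        "RH_percent": truth_cfg.RH if np.isscalar(truth_cfg.RH) else "series",
        "X_db0": truth_cfg.X_db0,
        "T0_K": truth_cfg.T0,
        "protocol": asdict(protocol),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for k, df in enumerate(reps):
            df.to_csv(out / f"replicate_{k}.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return reps, truth


def synth_aluminum_heating(h_T_truth: float, body: LumpedBodySpec,
                           T_air: float, protocol: ExperimentProtocol,
                           T0: float = 298.15, duration: float = 3600.0,
                           replicate: int = 0) -> pd.DataFrame:
    """Noisy lumped-capacitance heating curve of the aluminum body.

    Evaluates the closed-form heating curve on the temperature-logging
    grid and adds Gaussian noise (sigma_T)."""
    t = np.arange(0.0, duration + 1e-9, protocol.temperature_interval_s)
    T = lumped_temperature(t, h_T_truth, body, T_air, T0)
    rng = np.random.default_rng(protocol.seed)
    g = rng.spawn(max(protocol.replicates, replicate + 1))[replicate]
    Tn = T + g.normal(0.0, protocol.sigma_T, size=T.shape)
    return pd.DataFrame({"time_s": t, "T_C": Tn - 273.15})


def synth_rh_profile(band: tuple[float, float], duration_s: float,
                     interval_s: float = 30.0, seed: int = 0,
                     smooth_window: int = 21) -> pd.DataFrame:
    """Smooth bounded random-walk humidity profile confined to band (%).

    Deterministic per seed; a degenerate band [x, x] yields a constant
    profile."""
    lo, hi = float(band[0]), float(band[1])
    if not (0.0 <= lo <= hi <= 100.0):
        raise ValueError("RH band must satisfy 0 <= lo <= hi <= 100")
    t = np.arange(0.0, duration_s + 1e-9, interval_s)
    if hi == lo:
        return pd.DataFrame({"time_s": t, "RH_percent": np.full(t.shape, lo)})
    rng = np.random.default_rng(seed)
    step = (hi - lo) * 0.08
    walk = np.cumsum(rng.normal(0.0, step, size=t.shape))
    walk += 0.5 * (lo + hi)
    # reflect into the band, then smooth (still inside by convexity) and
    # re-clip against roundoff
    span = hi - lo
    walk = lo + np.abs((walk - lo) % (2 * span) - span)
    if smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        walk = np.convolve(np.pad(walk, pad, mode="edge"), k, mode="valid")
    walk = np.clip(walk, lo, hi)
    return pd.DataFrame({"time_s": t, "RH_percent": walk})
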