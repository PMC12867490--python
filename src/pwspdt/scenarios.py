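"""Named scenario configurations and suite runner.

A scenario is one treatment simulation: a geometry, an oxygen regime
(surface and inlet pO2), an irradiance, an illumination delay and a
horizon.  A suite is a named family of scenarios sharing one threshold
calibration: the normoxia baseline is always run (or reused) first,
both thresholds are calibrated on it, and every member is then
evaluated against those thresholds, so cross-scenario comparisons are
meaningful by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .geometry import GeometryConfig, build_tissue_model
from .hemodynamics import FlowConfig
from .metrics import ScenarioResult, Thresholds, calibrate_thresholds, evaluate
from .optics import FluenceField, solve_fluence
from .pharmacokinetics import InfusionProfile
from .reaction_transport import OxygenBoundary, PhotochemParams, TransportSolver

__all__ = ["ScenarioConfig", "run_scenario", "run_suite", "percent_change", "SUITES"]


@dataclass
class ScenarioConfig:
    """Complete configuration of one treatment simulation."""

    name: str = "normoxia"
    surface_pO2: Optional[float] = 159.0  # mmHg (normoxia preset)
    inlet_pO2: float = 100.0  # mmHg
    irradiance: float = 100.0  # mW/cm^2
    illumination_delay: float = 0.0  # s
    horizon: float = 2400.0  # s
    lumen_diameter: float = 40.0  # um
    voxel_size: float = 10.0  # um (coarse grid default; 5 um = fine)
    dt: float = 2.5  # s
    output_every: float = 10.0  # s
    snapshot_times: Tuple[float, ...] = ()
    geometry_overrides: Dict = None
    params: PhotochemParams = None
    flow: FlowConfig = None
    infusion: InfusionProfile = None

    def __post_init__(self) -> None:
        if self.params is None:
            self.params = PhotochemParams()
        if self.flow is None:
            self.flow = FlowConfig()
        if self.infusion is None:
            self.infusion = InfusionProfile()
        if self.horizon <= 0 or self.dt <= 0:
            raise ValueError("horizon and dt must be positive")

    def geometry(self) -> GeometryConfig:
        overrides = dict(self.geometry_overrides or {})
        overrides.setdefault("lumen_diameter", self.lumen_diameter)
        overrides.setdefault("voxel_size", self.voxel_size)
        if overrides["voxel_size"] >= 5.0:
            overrides.setdefault("coarse_wall", True)
        return GeometryConfig(**overrides)

    def boundary(self) -> OxygenBoundary:
        return OxygenBoundary(surface_pO2=self.surface_pO2, inlet_pO2=self.inlet_pO2)


def run_scenario(
    config: ScenarioConfig, fluence: Optional[FluenceField] = None, progress=None
) -> ScenarioResult:
    """Run one scenario and return its recorded result (metrics unfilled)."""
    model = build_tissue_model(config.geometry())
    solver = TransportSolver(
        model,
        config.params,
        config.boundary(),
        flow=config.flow,
        infusion=config.infusion,
        irradiance=config.irradiance,
        illumination_delay=config.illumination_delay,
        dt=config.dt,
        fluence=fluence,
    )
    records, final_state, snapshots = solver.run(
        horizon=config.horizon,
        output_every=config.output_every,
        snapshot_times=config.snapshot_times,
        progress=progress,
    )
    return ScenarioResult(
        name=config.name,
        series=pd.DataFrame.from_records(records),
        config=config,
        final_ros_cum=final_state.ros_cum,
        snapshots=snapshots,
        voxel_volume=model.voxel_volume,
    )


#: canonical name for running one treatment simulation
run_simulation = run_scenario


def percent_change(metric_value: float, baseline_value: float) -> float:
    """Relative change vs baseline, in percent."""
    if baseline_value == 0:
        raise ZeroDivisionError("baseline value is zero")
    return 100.0 * (metric_value - baseline_value) / baseline_value


# suite name -> (list of member overrides, horizon)
SUITES: Dict[str, Tuple[List[Dict], float]] = {
    "oxygen_regimes": (
        [
            {"name": "normoxia", "surface_pO2": 159.0},
            {"name": "hypoxia", "surface_pO2": 79.5},
            {"name": "anoxia", "surface_pO2": 16.0},
        ],
        2400.0,
    ),
    "irradiance_sweep": (
        [{"name": f"P{p:g}", "irradiance": float(p)} for p in (100, 150, 200)],
        1600.0,
    ),
    "diameter_sweep": (
        [{"name": f"d{d}", "lumen_diameter": float(d)} for d in (40, 60, 80, 100)],
        1600.0,
    ),
    "vascular_po2_sweep": (
        [{"name": f"inlet{p}", "inlet_pO2": float(p)} for p in (100, 90, 80)],
        1600.0,
    ),
    "illumination_timing": (
        [{"name": f"delay{d}", "illumination_delay": float(d)} for d in (0, 600, 1200)],
        2400.0,
    ),
    "combined_light_oxygen": (
        [
            {"name": f"P{p:g}_{o}", "irradiance": float(p), "surface_pO2": s}
            for p in (100, 200)
            for o, s in (("normoxia", 159.0), ("anoxia", 16.0))
        ],
        2400.0,
    ),
}


def run_suite(
    suite_name: str,
    base_config: Optional[ScenarioConfig] = None,
    horizon: Optional[float] = None,
    progress=None,
) -> Tuple[pd.DataFrame, Dict[str, ScenarioResult], Thresholds]:
    """Run a named suite with a single baseline threshold calibration.

    Returns the aggregate comparison table (one row per member with
    outcome metrics and percent changes vs baseline), the individual
    results, and the calibrated thresholds.
    """
    if suite_name not in SUITES:
        raise KeyError(f"unknown suite {suite_name!r}; choose from {sorted(SUITES)}")
    members, default_horizon = SUITES[suite_name]
    horizon = default_horizon if horizon is None else horizon
    base = base_config if base_config is not None else ScenarioConfig()
    base = replace(base, horizon=horizon)

    # normoxia default baseline first: it anchors the threshold calibration
    baseline_cfg = replace(base, name="normoxia")
    fluence_cache: Dict[Tuple[float, float, float], FluenceField] = {}

    def fluence_for(cfg: ScenarioConfig) -> FluenceField:
        key = (cfg.voxel_size, cfg.lumen_diameter, cfg.irradiance)
        if key not in fluence_cache:
            fluence_cache[key] = solve_fluence(build_tissue_model(cfg.geometry()), cfg.irradiance)
        return fluence_cache[key]

    results: Dict[str, ScenarioResult] = {}
    baseline = run_scenario(baseline_cfg, fluence=fluence_for(baseline_cfg), progress=progress)
    thresholds = calibrate_thresholds(baseline)
    evaluate(baseline, thresholds)
    results[baseline.name] = baseline

    for overrides in members:
        cfg = replace(base, **overrides)
        if _is_baseline(cfg, baseline_cfg):
            results.setdefault(cfg.name, baseline)
            continue
        res = run_scenario(cfg, fluence=fluence_for(cfg), progress=progress)
        evaluate(res, thresholds)
        results[res.name] = res

    rows = []
    for overrides in members:
        name = overrides["name"]
        res = results[name]
        row = {
            "scenario": name,
            "damage_time_s": res.damage_time_s,
            "pain_onset_s": res.pain_onset_s,
            "pain_duration_s": res.pain_duration_s,
            "psc": res.psc,
            "therapeutic_zone_um3": res.therapeutic_zone_volume,
            "equilibration_time_s": res.equilibration_time_s,
        }
        for key in ("psc", "pain_duration_s", "damage_time_s"):
            b, v = getattr(baseline, _attr(key)), row[key]
            row[f"{key}_pct_change"] = (
                percent_change(v, b) if (v is not None and b not in (None, 0)) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows), results, thresholds


def _attr(key: str) -> str:
    return {"psc": "psc", "pain_duration_s": "pain_duration_s", "damage_time_s": "damage_time_s"}[
        key
    ]


def _is_baseline(cfg: ScenarioConfig, baseline: ScenarioConfig) -> bool:
    return (
        cfg.surface_pO2 == baseline.surface_pO2
        and cfg.inlet_pO2 == baseline.inlet_pO2
        and cfg.irradiance == baseline.irradiance
        and cfg.illumination_delay == baseline.illumination_delay
        and cfg.lumen_diameter == baseline.lumen_diameter
    )
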