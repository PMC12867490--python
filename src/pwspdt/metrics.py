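"""Treatment-outcome statistics: damage time, pain window, PSC, zones.

All four evaluation metrics are defined relative to two thresholds that
are *self-calibrated* on the normoxia baseline run:

* the **damage threshold** — the mean vessel-wall cumulative ROS after
  the standard 20 min (1200 s) treatment (0.222 mol/m³ at the
  reference calibration), whose first crossing defines the end of
  treatment ``t_threshold``;
* the **photochemical pain threshold** — the mean papillary-dermis ROS
  generation rate at the 10 min mark (9.413×10⁻⁵ mol/(m³·s) at the
  reference calibration), whose first crossing defines pain onset.

The phototherapeutic selectivity coefficient (PSC) is the ratio of the
volume-mean cumulative ROS in the vessel wall to that in the papillary
dermis, both evaluated at ``t_threshold``; the therapeutic zone is the
set of voxels whose cumulative ROS reaches 80% of the damage threshold.
Because both thresholds are calibrated from the simulation itself,
every metric is invariant under a global rescaling of the ROS fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Thresholds",
    "ScenarioResult",
    "calibrate_thresholds",
    "damage_time",
    "pain_onset_and_duration",
    "psc",
    "therapeutic_zone",
    "equilibration_time",
]


@dataclass
class Thresholds:
    damage_threshold: float  # mol/m^3, cumulative ROS in the vessel wall
    pain_threshold: float  # mol/(m^3 s), papillary ROS generation rate
    damage_fraction_for_zone: float = 0.8
    calibration_record: Dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.damage_threshold <= 0 or self.pain_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.damage_fraction_for_zone <= 1):
            raise ValueError("zone fraction must lie in (0, 1]")


@dataclass
class ScenarioResult:
    """Recorded time series and outcome metrics of one scenario run."""

    name: str
    series: pd.DataFrame  # region-mean time series, one row per output time
    config: Optional[object] = None
    final_ros_cum: Optional[np.ndarray] = None
    snapshots: Dict[float, np.ndarray] = dc_field(default_factory=dict)
    voxel_volume: float = float("nan")
    # outcome metrics (filled by evaluate/run_suite)
    damage_time_s: Optional[float] = None
    pain_onset_s: Optional[float] = None
    pain_duration_s: Optional[float] = None
    psc: Optional[float] = None
    therapeutic_zone_volume: Optional[float] = None
    equilibration_time_s: Optional[float] = None


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> Optional[float]:
    """First time y(t) >= level, linearly interpolated between samples."""
    if len(t) == 0:
        raise ValueError("empty series")
    above = y >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))


def _interp(series: pd.DataFrame, column: str, t: float) -> float:
    return float(np.interp(t, series["t"].values, series[column].values))


def calibrate_thresholds(
    baseline: ScenarioResult,
    damage_calibration_time: float = 1200.0,
    pain_calibration_time: float = 600.0,
) -> Thresholds:
    """Self-calibrate both thresholds on the normoxia baseline run.

    The damage threshold is the mean vessel-wall cumulative ROS at the
    end of the standard 20-min treatment; the pain threshold is the
    mean papillary ROS generation rate at the 10-min mark.
    """
    t_max = baseline.series["t"].max()
    if t_max < damage_calibration_time:
        raise ValueError("baseline horizon must reach the 1200 s calibration time")
    damage = _interp(baseline.series, "wall_ros_cum", damage_calibration_time)
    pain = _interp(baseline.series, "papillary_ros_rate", pain_calibration_time)
    return Thresholds(
        damage_threshold=damage,
        pain_threshold=pain,
        calibration_record={
            "scenario": baseline.name,
            "damage_time": damage_calibration_time,
            "pain_time": pain_calibration_time,
        },
    )


def damage_time(result: ScenarioResult, thresholds: Thresholds) -> Optional[float]:
    """First time the mean vessel-wall cumulative ROS reaches the damage
    threshold (None if never reached within the horizon)."""
    s = result.series
    return _first_crossing(s["t"].values, s["wall_ros_cum"].values, thresholds.damage_threshold)


def pain_onset_and_duration(
    result: ScenarioResult, thresholds: Thresholds
) -> Tuple[Optional[float], Optional[float]]:
    """(pain onset, pain duration): onset is the first crossing of the
    papillary ROS-rate pain threshold; the duration runs from onset to
    the damage time."""
    t_dmg = damage_time(result, thresholds)
    if t_dmg is None:
        raise ValueError("damage threshold not reached: pain duration undefined")
    s = result.series
    onset = _first_crossing(s["t"].values, s["papillary_ros_rate"].values, thresholds.pain_threshold)
    if onset is None:
        return None, 0.0
    return onset, t_dmg - onset


def psc(
    result: ScenarioResult, thresholds: Thresholds, denominator_region: str = "papillary"
) -> float:
    """Phototherapeutic selectivity coefficient at the damage time.

    Ratio of the volume-mean cumulative ROS in the vessel wall to that
    in the papillary dermis (override ``denominator_region`` to use a
    different nontarget compartment), both at ``t_threshold``.
    """
    t_dmg = damage_time(result, thresholds)
    if t_dmg is None:
        raise ValueError("damage threshold not reached: PSC undefined")
    numer = _interp(result.series, "wall_ros_cum", t_dmg)
    denom = _interp(result.series, f"{denominator_region}_ros_cum", t_dmg)
    if denom == 0:
        raise ZeroDivisionError("nontarget cumulative ROS is zero")
    return numer / denom


def therapeutic_zone(
    ros_cum_field: np.ndarray, thresholds: Thresholds, voxel_volume: float
) -> Tuple[np.ndarray, float]:
    """Voxel mask (and its volume, μm³) where the cumulative ROS has
    reached the damage state (80% of the damage threshold)."""
    mask = ros_cum_field >= thresholds.damage_fraction_for_zone * thresholds.damage_threshold
    return mask, float(mask.sum()) * voxel_volume


def equilibration_time(result: ScenarioResult) -> Optional[float]:
    """First time the epidermal mean cumulative ROS catches up with the
    vessel-wall mean (None if never within the horizon)."""
    s = result.series
    if len(s) == 0:
        raise ValueError("empty series")
    diff = s["epidermis_ros_cum"].values - s["wall_ros_cum"].values
    # ignore the trivial equality before any ROS is generated
    active = s["wall_ros_cum"].values > 0
    if not active.any():
        return None
    t = s["t"].values[active]
    return _first_crossing(t, diff[active], 0.0)


def evaluate(result: ScenarioResult, thresholds: Thresholds) -> ScenarioResult:
    """Fill all outcome metrics of a result in place (and return it)."""
    result.damage_time_s = damage_time(result, thresholds)
    if result.damage_time_s is not None:
        result.pain_onset_s, result.pain_duration_s = pain_onset_and_duration(result, thresholds)
        result.psc = psc(result, thresholds)
    result.equilibration_time_s = equilibration_time(result)
    if result.final_ros_cum is not None:
        _, vol = therapeutic_zone(result.final_ros_cum, thresholds, result.voxel_volume)
        result.therapeutic_zone_volume = vol
    return result
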