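"""Arteriolar-inlet photosensitizer input function and illumination timing.

Clinically, HMME (hematoporphyrin monomethyl ether) is infused as a
slow bolus over 20 minutes via a peristaltic pump.  The model drives
the vascular boundary with a parametric emulation of the resulting
blood-concentration curve: a monotone piecewise-cubic interpolation of
printed anchor concentrations during the infusion, followed by a
single-exponential washout (configurable half-life) afterwards.  This
inlet Dirichlet condition is the only photosensitizer source — there is
no transdermal uptake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["InfusionProfile", "inlet_concentration", "illumination_schedule"]

#: default (time s, concentration mol/m^3) anchors of the infusion ramp
DEFAULT_ANCHORS: Tuple[Tuple[float, float], ...] = (
    (0.0, 0.0),
    (300.0, 0.018),
    (600.0, 0.041),
    (900.0, 0.061),
    (1200.0, 0.067),
)


@dataclass
class InfusionProfile:
    infusion_duration: float = 1200.0  # s
    anchor_points: Tuple[Tuple[float, float], ...] = DEFAULT_ANCHORS
    post_infusion_half_life: float = 3600.0  # s
    _interp: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = np.array([a[0] for a in self.anchor_points])
        c = np.array([a[1] for a in self.anchor_points])
        if np.any(np.diff(t) <= 0):
            raise ValueError("anchor times must be strictly increasing")
        if np.any(c < 0) or np.any(np.diff(c) < 0):
            raise ValueError("anchor concentrations must be nonnegative and nondecreasing")
        if t[-1] != self.infusion_duration:
            raise ValueError("last anchor must sit at the infusion end")
        if self.post_infusion_half_life <= 0:
            raise ValueError("half-life must be positive")
        self._interp = PchipInterpolator(t, c)

    @property
    def final_concentration(self) -> float:
        return float(self.anchor_points[-1][1])


def inlet_concentration(profile: InfusionProfile, t) -> np.ndarray | float:
    """Photosensitizer concentration (mol/m³) at the arteriolar inlet.

    Monotone interpolation of the anchors during the infusion and
    exponential decay from the final anchor afterwards; continuous at
    the infusion end.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    td = profile.infusion_duration
    rate = math.log(2.0) / profile.post_infusion_half_life
    out = np.where(
        t_arr <= td,
        profile._interp(np.minimum(t_arr, td)),
        profile.final_concentration * np.exp(-rate * np.maximum(t_arr - td, 0.0)),
    )
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def illumination_schedule(delay_s: float, irradiance: float = 1.0) -> Callable[[float], float]:
    """Indicator-style irradiance schedule P(t).

    Returns a callable giving the incident irradiance: 0 before
    ``delay_s`` and ``irradiance`` afterwards (the stopping criterion
    is the caller's horizon).
    """
    if delay_s < 0:
        raise ValueError("delay must be nonnegative")

    def schedule(t: float) -> float:
        return irradiance if t >= delay_s else 0.0

    return schedule
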