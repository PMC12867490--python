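"""Prescribed intravascular velocity field and Poiseuille diameter scaling.

Blood flow is not solved; the lumen carries a prescribed axial plug
velocity (default 500 μm/s peak), optionally modulated by a sinusoidal
pulse.  When the vessel diameter is swept, the volumetric flow follows
the Poiseuille R⁴ law at fixed pressure drop, so the mean velocity
(flow / cross-section) scales with the square of the radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import TissueModel

__all__ = [
    "FlowConfig",
    "VelocityField",
    "poiseuille_flow",
    "scaled_peak_velocity",
    "build_velocity_field",
]


@dataclass
class FlowConfig:
    peak_velocity: float = 500.0  # um/s at the reference radius
    waveform: str = "steady"  # "steady" or "sinusoidal"
    pulse_frequency: float = 1.0  # Hz, used only if sinusoidal
    reference_radius: float = 20.0  # um

    def __post_init__(self) -> None:
        if self.peak_velocity <= 0:
            raise ValueError("peak velocity must be positive")
        if self.pulse_frequency <= 0:
            raise ValueError("pulse frequency must be positive")
        if self.waveform not in ("steady", "sinusoidal"):
            raise ValueError(f"unknown waveform {self.waveform!r}")

    def modulation(self, t: float) -> float:
        """Dimensionless waveform factor in [0, 1] at time t."""
        if self.waveform == "steady":
            return 1.0
        return max(0.0, math.sin(2.0 * math.pi * self.pulse_frequency * t))


@dataclass
class VelocityField:
    """Axial plug velocity, nonzero only in the vessel lumen."""

    u_axial: float  # um/s, x-directed
    lumen_mask: np.ndarray  # (nx, ny, nz) bool

    def vector_at(self, i: int, j: int, k: int) -> np.ndarray:
        if self.lumen_mask[i, j, k]:
            return np.array([self.u_axial, 0.0, 0.0])
        return np.zeros(3)


def poiseuille_flow(delta_p: float, radius: float, viscosity: float, length: float) -> float:
    """Poiseuille volumetric flow ΔP·π·R⁴/(8·η·L) through a cylinder."""
    if min(delta_p, radius, viscosity, length) < 0 or min(radius, viscosity, length) == 0:
        raise ValueError("radius, viscosity and length must be positive; ΔP nonnegative")
    return delta_p * math.pi * radius**4 / (8.0 * viscosity * length)


def scaled_peak_velocity(radius: float, reference_radius: float, reference_velocity: float) -> float:
    """Mean-velocity scaling under Poiseuille flow at fixed ΔP, η, L.

    Flow scales as R⁴ and the cross-section as R², so the velocity
    scales as (R/R_ref)².
    """
    if radius <= 0 or reference_radius <= 0:
        raise ValueError("radii must be positive")
    return reference_velocity * (radius / reference_radius) ** 2


def build_velocity_field(model: TissueModel, flow: FlowConfig, t: float = 0.0) -> VelocityField:
    """Plug velocity in the lumen at time t (zero everywhere else)."""
    radius = model.config.lumen_diameter / 2.0
    u = scaled_peak_velocity(radius, flow.reference_radius, flow.peak_velocity)
    return VelocityField(u_axial=u * flow.modulation(t), lumen_mask=model.lumen_mask())
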