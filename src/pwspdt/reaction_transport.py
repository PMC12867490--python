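"""Coupled oxygen / photosensitizer / ROS reaction–transport integrator.

Two scalar fields are integrated over the treatment on the voxel grid:

* dissolved oxygen ``Co`` (mol/m³) — diffusion (Do), plug advection in
  the lumen, a zero-order metabolic sink Γ1 in tissue voxels, and the
  photochemical sink Γ2;
* photosensitizer ``Cm`` (mol/m³) — diffusion (Dm), lumen advection, a
  time-ramped Dirichlet value at the arteriolar inlet face, and
  second-order photobleaching Γm.

The ROS generation rate (taken equal to the photochemical oxygen
consumption rate) is

    Π_ROS = κ · 2.303 ε Φ · Cm · ψ_mol · Co / (Co + β),

where ``ψ_mol = ψ λ / (N_A h c)`` converts the fluence rate into a
molar photon flux and κ is a single dimensionless calibration constant
fixed on the normoxia baseline (see docs/methods.md).  Photobleaching
shares the same photon-flux convention:  Γm = −κ_b Km f ψ_mol Cm².

Each species is advanced per global step ``dt`` with a Douglas ADI
(stabilizing-correction) scheme: the full transport operator — implicit
diffusion on all axes, implicit first-order upwind plug advection along
the lumen lines, and the Dirichlet face couplings (skin surface for
oxygen, arteriolar inlet for both species) — is applied explicitly in
the predictor together with the reaction sources, followed by one
implicit batched-tridiagonal correction per axis.  The fixed point of
the scheme satisfies the unsplit steady equation exactly, so steady
fields carry no splitting error.  Blood oxygen is dissolved-only (no
hemoglobin buffering), which makes the capillary content deplete
axially from the arteriolar inlet toward the venular outlet.

Oxygen boundary values are prescribed as partial pressures (mmHg) and
converted to dissolved concentrations with a Henry coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional

import numpy as np
from scipy.linalg import solve_banded

from .geometry import REGION_CODES, TissueModel
from .hemodynamics import FlowConfig, scaled_peak_velocity
from .optics import FluenceField, solve_fluence
from .pharmacokinetics import InfusionProfile, inlet_concentration

__all__ = [
    "PhotochemParams",
    "OxygenBoundary",
    "StateFields",
    "TransportSolver",
    "henry_concentration",
    "ros_generation_rate",
    "photobleaching_rate",
    "MOL_PHOTONS_PER_JOULE",
    "photon_molar_flux",
]

#: mol of 532 nm photons per joule: λ/(N_A·h·c)
MOL_PHOTONS_PER_JOULE = 532e-9 / (6.02214076e23 * 6.62607015e-34 * 2.99792458e8)

#: Henry coefficient back-derived from the boundary conversions
#: 159 mmHg -> 0.232 mol/m^3 and 100 mmHg -> 0.146 mol/m^3.
DEFAULT_HENRY_ALPHA = 1.459e-3  # mol/(m^3 mmHg)

#: dimensionless photon-conversion calibration constant; fixed so the
#: normoxia baseline's mean vessel-wall cumulative ROS at 1200 s equals
#: the 0.222 mol/m^3 damage dose on the default coarse grid.
DEFAULT_KAPPA = 8.793e-4

SURFACE_PO2_PRESETS = {"normoxia": 159.0, "hypoxia": 79.5, "anoxia": 16.0}


def henry_concentration(pO2_mmHg: float, alpha: float = DEFAULT_HENRY_ALPHA) -> float:
    """Dissolved-oxygen concentration (mol/m³) for a partial pressure."""
    if pO2_mmHg < 0:
        raise ValueError("partial pressure must be nonnegative")
    return alpha * pO2_mmHg


def photon_molar_flux(psi_mw_cm2) -> np.ndarray | float:
    """Molar photon flux (mol photons / m²·s) for a fluence rate in mW/cm²."""
    return np.asarray(psi_mw_cm2) * 10.0 * MOL_PHOTONS_PER_JOULE


@dataclass
class PhotochemParams:
    """Photochemical and transport constants of the HMME model."""

    Dm: float = 50.0  # photosensitizer diffusivity, um^2/s
    Do: float = 1500.0  # oxygen diffusivity, um^2/s
    beta: float = 0.0119  # kp/kot oxygen half-saturation, mol/m^3 (see methods)
    phi: float = 0.6  # singlet-oxygen quantum yield
    epsilon: float = 9252.0  # molar extinction at 532 nm, L/(mol cm)
    Km: float = 66.21  # photobleaching rate constant (unit closure via kappa_b)
    gamma1: float = 1.7e-3  # metabolic O2 consumption, mol/(m^3 s)
    oxygen_cutoff: float = 1e-4  # mol/m^3 (~0.07 mmHg) smooth shutoff of gamma1
    kappa: float = DEFAULT_KAPPA  # photon-conversion calibration constant
    kappa_b: Optional[float] = None  # bleaching conversion; defaults to kappa

    def __post_init__(self) -> None:
        if min(self.Dm, self.Do, self.beta, self.epsilon, self.Km, self.gamma1, self.kappa) < 0:
            raise ValueError("parameters must be nonnegative")
        if not (0 <= self.phi <= 1):
            raise ValueError("quantum yield must lie in [0, 1]")

    @property
    def bleach_kappa(self) -> float:
        return self.kappa if self.kappa_b is None else self.kappa_b

    @property
    def epsilon_si(self) -> float:
        """Molar extinction in m²/mol (base-10), for use with ln(10)=2.303."""
        return self.epsilon * 0.1


@dataclass
class OxygenBoundary:
    """Oxygen boundary partial pressures; ``surface_pO2=None`` closes the top."""

    surface_pO2: Optional[float] = 159.0  # mmHg
    inlet_pO2: float = 100.0  # mmHg
    henry_alpha: float = DEFAULT_HENRY_ALPHA

    def __post_init__(self) -> None:
        if self.surface_pO2 is not None and self.surface_pO2 < 0:
            raise ValueError("surface pO2 must be nonnegative")
        if self.inlet_pO2 < 0:
            raise ValueError("inlet pO2 must be nonnegative")

    @classmethod
    def preset(cls, name: str, **kwargs) -> "OxygenBoundary":
        return cls(surface_pO2=SURFACE_PO2_PRESETS[name], **kwargs)

    @property
    def surface_concentration(self) -> Optional[float]:
        if self.surface_pO2 is None:
            return None
        return henry_concentration(self.surface_pO2, self.henry_alpha)

    @property
    def inlet_concentration(self) -> float:
        return henry_concentration(self.inlet_pO2, self.henry_alpha)


def ros_generation_rate(Cm, Co, psi, params: PhotochemParams):
    """ROS generation (= photochemical O2 consumption) rate, mol/(m³·s)."""
    Cm = np.asarray(Cm, dtype=float)
    Co = np.asarray(Co, dtype=float)
    oxygen_factor = Co / (Co + params.beta)
    rate = (
        params.kappa
        * 2.303
        * params.epsilon_si
        * params.phi
        * Cm
        * photon_molar_flux(psi)
        * oxygen_factor
    )
    return rate if rate.ndim else float(rate)


def photobleaching_rate(Cm, Co, psi, params: PhotochemParams):
    """Photobleaching sink of the photosensitizer (≤ 0), mol/(m³·s)."""
    Cm = np.asarray(Cm, dtype=float)
    Co = np.asarray(Co, dtype=float)
    oxygen_factor = Co / (Co + params.beta)
    rate = -params.bleach_kappa * params.Km * oxygen_factor * photon_molar_flux(psi) * Cm**2
    return rate if rate.ndim else float(rate)


@dataclass
class StateFields:
    """Time-dependent fields of one simulation state."""

    Co: np.ndarray  # oxygen, mol/m^3
    Cm: np.ndarray  # photosensitizer, mol/m^3
    ros_rate: np.ndarray  # mol/(m^3 s)
    ros_cum: np.ndarray  # mol/m^3
    t: float = 0.0

    def copy(self) -> "StateFields":
        return StateFields(
            self.Co.copy(), self.Cm.copy(), self.ros_rate.copy(), self.ros_cum.copy(), self.t
        )


def _tridiag(n: int, mu: float) -> np.ndarray:
    """Banded (I + mu*A) for 1D zero-flux implicit diffusion."""
    ab = np.zeros((3, n))
    ab[0, 1:] = -mu
    ab[2, :-1] = -mu
    ab[1, :] = 1.0 + 2.0 * mu
    ab[1, 0] = 1.0 + mu
    ab[1, -1] = 1.0 + mu
    return ab


class TransportSolver:
    """Operator-split integrator on a fixed tissue model.

    Assembling a solver precomputes the fluence field, region indices
    and sweep matrices; ``run`` integrates a treatment and returns the
    recorded region time series together with the final state.
    """

    RECORD_REGIONS = {
        "wall": "vessel_wall",
        "papillary": "papillary_dermis",
        "epidermis": "epidermis",
        "reticular": "reticular_dermis",
        "sc": "stratum_corneum",
        "lumen": "vessel_lumen",
    }

    def __init__(
        self,
        model: TissueModel,
        params: PhotochemParams,
        boundary: OxygenBoundary,
        flow: Optional[FlowConfig] = None,
        infusion: Optional[InfusionProfile] = None,
        irradiance: float = 100.0,
        illumination_delay: float = 0.0,
        dt: float = 2.5,
        fluence: Optional[FluenceField] = None,
    ) -> None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.model = model
        self.params = params
        self.boundary = boundary
        self.flow = flow
        self.infusion = infusion
        self.irradiance = irradiance
        self.illumination_delay = illumination_delay
        self.dt = dt
        self.h = model.voxel_size
        self.shape = model.shape
        self.tissue_mask = ~model.lumen_mask()
        self.lumen_mask = model.lumen_mask()
        # lumen lines run the full x extent: identify their (y, z) columns
        self.lumen_lines = np.where(self.lumen_mask[0].ravel())[0]
        self._non_lumen_cols = np.setdiff1d(
            np.arange(self.shape[1] * self.shape[2]), self.lumen_lines
        )
        if irradiance > 0:
            self.fluence = fluence if fluence is not None else solve_fluence(model, irradiance)
            self.psi = self.fluence.psi
        else:
            self.fluence = None
            self.psi = np.zeros(self.shape)
        self._region_idx: Dict[str, np.ndarray] = {
            short: np.where(model.mask(label).ravel())[0]
            for short, label in self.RECORD_REGIONS.items()
        }

    # ---- implicit advection–diffusion ---------------------------------------
    #
    # Douglas ADI (stabilizing-correction) scheme: the predictor applies
    # the full unsplit operator explicitly, then one implicit tridiagonal
    # correction per axis.  Its fixed point satisfies the unsplit steady
    # equation exactly, so steady fields are independent of dt.  The
    # axial plug advection in the lumen is part of the x-axis operator
    # (first-order upwind, implicit), so the axial depletion of blood
    # oxygen along the capillary is resolved without splitting error.

    def _inlet_value(self, species: str, t: float) -> Optional[float]:
        if species == "Co":
            return self.boundary.inlet_concentration
        if self.infusion is not None:
            return float(inlet_concentration(self.infusion, t))
        return None

    def _courant(self, t: float, dt: float) -> float:
        """Implicit upwind Courant number u·dt/h of the lumen plug flow."""
        if self.flow is None or not self.lumen_lines.size:
            return 0.0
        radius = self.model.config.lumen_diameter / 2.0
        u = scaled_peak_velocity(radius, self.flow.reference_radius, self.flow.peak_velocity)
        return u * self.flow.modulation(t) * dt / self.h

    def _axis_lin(
        self, C: np.ndarray, axis: int, mu: float, species: str, nu: float
    ) -> np.ndarray:
        """Linear part of the scaled 1D operator dt·A_axis·C.

        For the x axis, lumen lines carry the upwind advection term and
        the inlet-face Dirichlet coupling in addition to diffusion.
        """
        out = np.zeros_like(C)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        d = mu * (C[tuple(hi)] - C[tuple(lo)])
        out[tuple(lo)] += d
        out[tuple(hi)] -= d
        first = [slice(None)] * 3
        first[axis] = 0
        if axis == 2 and species == "Co" and self.boundary.surface_concentration is not None:
            out[tuple(first)] -= 2.0 * mu * C[tuple(first)]
        if axis == 0 and self.lumen_lines.size and self._inlet_value(species, 0.0) is not None:
            flat_out = out.reshape(self.shape[0], -1)
            lines = C.reshape(self.shape[0], -1)[:, self.lumen_lines]
            # upwind advection −ν(C_i − C_{i−1}); the i=0 ghost is the
            # inlet reservoir (its constant part lives in _bc_source)
            if nu > 0:
                flat_out[1:, self.lumen_lines] -= nu * (lines[1:] - lines[:-1])
                flat_out[0, self.lumen_lines] -= nu * lines[0]
            flat_out[0, self.lumen_lines] -= 2.0 * mu * lines[0]
        return out

    def _bc_source(self, shape, mu: float, species: str, t_new: float, nu: float) -> np.ndarray:
        """Affine boundary terms dt·b of the transport operator."""
        b = np.zeros(shape)
        cs = self.boundary.surface_concentration
        if species == "Co" and cs is not None:
            b[:, :, 0] += 2.0 * mu * cs
        inlet = self._inlet_value(species, t_new)
        if inlet is not None and self.lumen_lines.size:
            face = b[0].ravel()
            face[self.lumen_lines] += (2.0 * mu + nu) * inlet
        return b

    def _axis_solve(
        self, R: np.ndarray, axis: int, mu: float, species: str, nu: float
    ) -> np.ndarray:
        """Solve (I − dt·A_axis)·X = R with batched tridiagonal solves."""
        Rm = np.moveaxis(R, axis, 0)
        n = Rm.shape[0]
        b = np.ascontiguousarray(Rm.reshape(n, -1))
        ab = _tridiag(n, mu)
        if axis == 2 and species == "Co" and self.boundary.surface_concentration is not None:
            ab[1, 0] += 2.0 * mu
        if axis == 0 and self.lumen_lines.size and self._inlet_value(species, 0.0) is not None:
            cols = self.lumen_lines
            ab_l = ab.copy()
            ab_l[1, :] += nu  # upwind advection diagonal
            ab_l[2, :-1] -= nu  # coupling to the upstream cell
            ab_l[1, 0] += 2.0 * mu  # inlet-face Dirichlet
            b[:, cols] = solve_banded((1, 1), ab_l, b[:, cols], check_finite=False)
            rest = self._non_lumen_cols
            b[:, rest] = solve_banded((1, 1), ab, b[:, rest], check_finite=False)
            return np.moveaxis(b.reshape(Rm.shape), 0, axis)
        x = solve_banded((1, 1), ab, b, overwrite_b=True, check_finite=False)
        return np.moveaxis(x.reshape(Rm.shape), 0, axis)

    def _diffuse(
        self,
        C: np.ndarray,
        D: float,
        species: str,
        t_new: float,
        dt: float,
        source: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """One Douglas ADI step, with the reaction source in the predictor.

        The fixed point satisfies the full unsplit steady equation
        ∇·(D∇C) − U·∇C + bc + source = 0, so steady fields carry no
        splitting error and do not depend on dt.
        """
        mu = dt * D / self.h**2
        nu = self._courant(t_new, dt)
        lin = [self._axis_lin(C, ax, mu, species, nu) for ax in range(3)]
        Y = C + lin[0] + lin[1] + lin[2] + self._bc_source(C.shape, mu, species, t_new, nu)
        if source is not None:
            Y += dt * source
        for ax in range(3):
            Y = self._axis_solve(Y - lin[ax], ax, mu, species, nu)
        # Douglas corrections can undershoot marginally at steep fronts
        return np.maximum(Y, 0.0)

    # ---- reaction ----------------------------------------------------------

    def _reaction_rates(self, state: StateFields, light_on: bool):
        """(ROS generation, metabolic O2 sink, bleaching sink) at a state.

        The zero-order metabolic sink Γ1 carries a smooth low-oxygen
        cutoff Co/(Co + c_eps) so it shuts off as oxygen depletes and
        the anoxic steady state is well-posed.
        """
        p = self.params
        co = np.maximum(state.Co, 0.0)
        cm = np.maximum(state.Cm, 0.0)
        oxygen_factor = co / (co + p.beta)
        psi_mol = photon_molar_flux(self.psi) if light_on else 0.0
        gen = p.kappa * 2.303 * p.epsilon_si * p.phi * cm * psi_mol * oxygen_factor
        metabolic = p.gamma1 * self.tissue_mask * co / (co + p.oxygen_cutoff)
        bleach = p.bleach_kappa * p.Km * oxygen_factor * psi_mol * cm**2
        return np.asarray(gen, dtype=float), metabolic, np.asarray(bleach, dtype=float)

    # ---- stepping ----------------------------------------------------------

    def light_on(self, t: float) -> bool:
        return self.irradiance > 0 and t >= self.illumination_delay

    def step(self, state: StateFields, dt: Optional[float] = None) -> StateFields:
        """Advance one operator-split step and return the new state."""
        dt = self.dt if dt is None else dt
        t_new = state.t + dt
        new = state.copy()
        gen, metabolic, bleach = self._reaction_rates(state, self.light_on(t_new))
        new.Co = self._diffuse(state.Co, self.params.Do, "Co", t_new, dt, source=-(gen + metabolic))
        new.Cm = self._diffuse(state.Cm, self.params.Dm, "Cm", t_new, dt, source=-bleach)
        new.ros_rate = gen
        new.ros_cum = state.ros_cum + gen * dt
        new.t = t_new
        if not (np.isfinite(new.Co).all() and np.isfinite(new.Cm).all()):
            raise RuntimeError(f"non-finite field after step to t={t_new}")
        return new

    # ---- initialization and full runs --------------------------------------

    def initial_state(self, t_relax: float = 3000.0, dt_relax: float = 5.0) -> StateFields:
        """Pre-illumination state: oxygen relaxed to its dark steady field.

        Oxygen is marched with the light off (diffusion + advection +
        cutoff metabolic sink) until the field stops changing; the
        photosensitizer starts at zero.
        """
        p = self.params
        Co0 = np.full(self.shape, self.boundary.inlet_concentration * 0.5)
        state = StateFields(Co0, np.zeros(self.shape), np.zeros(self.shape), np.zeros(self.shape))
        t = 0.0
        while t < t_relax:
            prev = state.Co
            pos = np.maximum(prev, 0.0)
            metabolic = p.gamma1 * self.tissue_mask * pos / (pos + p.oxygen_cutoff)
            Co = self._diffuse(prev, p.Do, "Co", t, dt_relax, source=-metabolic)
            state.Co = Co
            t += dt_relax
            if np.max(np.abs(Co - prev)) < 1e-10 * max(float(Co.max()), 1e-12) * dt_relax:
                break
        state.t = 0.0
        return state

    def region_means(self, field: np.ndarray) -> Dict[str, float]:
        flat = field.ravel()
        return {
            short: float(flat[idx].mean()) if idx.size else float("nan")
            for short, idx in self._region_idx.items()
        }

    def run(
        self,
        horizon: float = 2400.0,
        output_every: float = 10.0,
        snapshot_times: tuple = (),
        progress: Optional[Callable[[float], None]] = None,
    ):
        """Integrate from t = 0 and record region-mean time series.

        Returns ``(records, final_state, snapshots)`` where ``records``
        is a list of dicts (one per output time) with region means of
        the ROS rate, cumulative ROS, photosensitizer and oxygen.
        """
        state = self.initial_state()
        records = [self._record(state)]
        snapshots = {}
        n_steps = int(round(horizon / self.dt))
        every = max(1, int(round(output_every / self.dt)))
        snap_steps = {int(round(ts / self.dt)): ts for ts in snapshot_times}
        for istep in range(1, n_steps + 1):
            state = self.step(state)
            if istep % every == 0 or istep == n_steps:
                records.append(self._record(state))
            if istep in snap_steps:
                snapshots[snap_steps[istep]] = state.ros_cum.copy()
            if progress is not None:
                progress(state.t)
        return records, state, snapshots

    def _record(self, state: StateFields) -> Dict[str, float]:
        row: Dict[str, float] = {"t": state.t}
        for name, fieldarr in (
            ("ros_rate", state.ros_rate),
            ("ros_cum", state.ros_cum),
            ("cm", state.Cm),
            ("co", state.Co),
        ):
            for short, value in self.region_means(fieldarr).items():
                row[f"{short}_{name}"] = value
        return row


def step(
    state: StateFields,
    model: TissueModel,
    velocity,
    fluence: Optional[FluenceField],
    params: PhotochemParams,
    boundary: OxygenBoundary,
    dt: float,
    flow: Optional[FlowConfig] = None,
    infusion: Optional[InfusionProfile] = None,
) -> StateFields:
    """Functional single-step interface (thin wrapper over TransportSolver)."""
    solver = TransportSolver(
        model,
        params,
        boundary,
        flow=flow,
        infusion=infusion,
        irradiance=fluence.P_incident if fluence is not None else 0.0,
        dt=dt,
        fluence=fluence,
    )
    return solver.step(state, dt)
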