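"""Steady-state optical diffusion approximation for the 532 nm fluence field.

Light transport in scattering-dominated tissue is modeled with the
diffusion approximation.  Because the photon time scale is far below
every other dynamic in the problem and the absorption map is constant
over a treatment, the fluence rate ``ψ`` (mW/cm²) is solved once per
scenario as the steady state of

    −∇·(D ∇ψ) + μa ψ = 0,     D = 1 / (3 (μa + (1 − g) μs)),

with an inward photon-flux boundary condition ``(1 − r) P = −D ∂ψ/∂z``
on the skin surface and zero flux on the lateral and bottom faces
(symmetric-tiling assumption).  The speed-of-light factors of the
transient form cancel in steady state, so the solver works in the
unit-speed convention throughout.

Discretization: cell-centered finite volumes with harmonic-mean face
diffusivities; the symmetric positive-definite system is solved by
Jacobi-preconditioned conjugate gradients to a relative residual of
1e−10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import TissueModel

__all__ = [
    "OpticalProperties",
    "FluenceField",
    "optical_diffusion_coefficient",
    "internal_reflection_coefficient",
    "solve_fluence",
    "fluence_depth_profile",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of one tissue type (CGS-style units)."""

    mu_a: float  # absorption coefficient, cm^-1
    mu_s: float  # scattering coefficient, cm^-1
    g: float  # scattering anisotropy
    n: float  # refractive index

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("coefficients must be nonnegative")
        if not (0 <= self.g < 1):
            raise ValueError("anisotropy must lie in [0, 1)")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")


def optical_diffusion_coefficient(props: OpticalProperties, c_star: float = 1.0) -> float:
    """Optical diffusion coefficient ``c*/(3 (μa + (1 − g) μs))`` in cm.

    With ``c_star=1`` this is the unit-speed form used by the
    steady-state solver.
    """
    transport = props.mu_a + (1.0 - props.g) * props.mu_s
    if transport <= 0:
        raise ValueError("transport coefficient must be positive")
    return c_star / (3.0 * transport)


def internal_reflection_coefficient(n_tissue: float) -> float:
    """Normal-incidence Fresnel reflectance at the air–tissue interface."""
    if n_tissue < 1:
        raise ValueError("refractive index must be >= 1")
    return ((n_tissue - 1.0) / (n_tissue + 1.0)) ** 2


@dataclass
class FluenceField:
    """Steady fluence-rate field on the voxel grid."""

    model: TissueModel
    psi: np.ndarray  # (nx, ny, nz), mW/cm^2
    P_incident: float  # mW/cm^2
    r: float  # internal reflection coefficient
    _d_top: np.ndarray = None  # top-cell diffusion coefficient (um), per (x, y)

    def surface_value(self, i: int, j: int) -> float:
        """Fluence reconstructed at the z = 0 face of column (i, j)."""
        h = self.model.voxel_size
        flux = (1.0 - self.r) * self.P_incident
        return float(self.psi[i, j, 0] + flux * h / (2.0 * self._d_top[i, j]))


def _diffusion_map_um(model: TissueModel) -> np.ndarray:
    """Per-voxel unit-speed optical diffusion coefficient in μm."""
    mu_a = model.mu_a()  # cm^-1
    mu_tr = mu_a + (1.0 - model.anisotropy()) * model.mu_s()
    return 1e4 / (3.0 * mu_tr)


def _assemble(model: TissueModel) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray, float]:
    nx, ny, nz = model.shape
    h = model.voxel_size
    mu_a_um = model.mu_a() * 1e-4  # 1/um
    if not np.any(mu_a_um > 0):
        raise ValueError("all-zero absorption with closed boundaries: singular system")
    D = _diffusion_map_um(model)
    n = nx * ny * nz
    idx = np.arange(n).reshape(nx, ny, nz)
    diag = mu_a_um.ravel().astype(float)
    rows, cols, vals = [], [], []
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        D_lo, D_hi = D[tuple(sl_lo)], D[tuple(sl_hi)]
        d_face = 2.0 * D_lo * D_hi / (D_lo + D_hi) / h**2  # harmonic mean
        i_lo = idx[tuple(sl_lo)].ravel()
        i_hi = idx[tuple(sl_hi)].ravel()
        w = d_face.ravel()
        rows += [i_lo, i_hi]
        cols += [i_hi, i_lo]
        vals += [-w, -w]
        np.add.at(diag, i_lo, w)
        np.add.at(diag, i_hi, w)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    r = internal_reflection_coefficient(float(model.refractive_index()[0, 0, 0]))
    # unit-irradiance source on the top face: influx (1 - r) * 1 / h per cell
    b = np.zeros((nx, ny, nz))
    b[:, :, 0] = (1.0 - r) / h
    return A, b.ravel(), D[:, :, 0], r


def solve_fluence(model: TissueModel, P_incident: float, rtol: float = 1e-10) -> FluenceField:
    """Solve the steady diffusion approximation for incident irradiance P.

    The solution is computed for unit irradiance and scaled, so the
    field is exactly linear in ``P_incident``.
    """
    if P_incident <= 0:
        raise ValueError("incident irradiance must be positive")
    A, b, d_top, r = _assemble(model)
    M = sp.diags(1.0 / A.diagonal())
    psi, info = spla.cg(A, b, M=M, rtol=rtol, maxiter=20000)
    if info != 0:
        raise RuntimeError(f"fluence solve did not converge (info={info})")
    psi = np.maximum(psi, 0.0).reshape(model.shape) * P_incident
    return FluenceField(model=model, psi=psi, P_incident=P_incident, r=r, _d_top=d_top)


def fluence_depth_profile(field: FluenceField, x: float, y: float):
    """Normalized vertical fluence profile through the point (x, y).

    Returns ``(depth_um, psi_over_surface)`` where the normalization is
    the fluence reconstructed at the z = 0 surface of that column, so
    the profile starts at (0, 1).
    """
    model = field.model
    h = model.voxel_size
    nx, ny, nz = model.shape
    i, j = int(x // h), int(y // h)
    if not (0 <= i < nx and 0 <= j < ny):
        raise ValueError("coordinates outside domain")
    psi0 = field.surface_value(i, j)
    depths = np.concatenate([[0.0], model.cell_centers(2)])
    values = np.concatenate([[psi0], field.psi[i, j, :]]) / psi0
    return depths, values
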