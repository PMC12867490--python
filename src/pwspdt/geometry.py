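"""Voxelized multilayer skin domain with embedded capillaries.

The simulated tissue block is a layered skin slab — a 110 μm epidermis
(10 μm stratum corneum on top) over a 700 μm dermis split into a 100 μm
papillary layer and a reticular remainder — with two parallel x-axis
aligned capillaries embedded in the dermis to mimic a port-wine-stain
vascular plexus.  Every voxel carries exactly one region label; optical
and transport properties are looked up per label.

Coordinate convention: ``z = 0`` at the air–skin surface, increasing
downward; fields are cell-centered on a uniform voxel grid; the
arteriolar inlet is the ``x = 0`` face of each lumen and the venular
outlet the ``x = Lx`` face.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "REGIONS",
    "REGION_CODES",
    "OPTICAL_TABLE",
    "GeometryConfig",
    "TissueModel",
    "build_tissue_model",
    "region_volume",
]

#: region name -> integer label code
REGION_CODES: Dict[str, int] = {
    "stratum_corneum": 0,
    "epidermis": 1,
    "papillary_dermis": 2,
    "reticular_dermis": 3,
    "vessel_wall": 4,
    "vessel_lumen": 5,
}
REGIONS = tuple(REGION_CODES)

# Optical properties at 532 nm per region: (mu_a cm^-1, mu_s cm^-1, g, n).
# The vessel wall is dermal tissue; the lumen is whole blood.
OPTICAL_TABLE: Dict[str, Tuple[float, float, float, float]] = {
    "stratum_corneum": (181.0, 2200.0, 0.925, 1.45),
    "epidermis": (1.1, 184.4, 0.774, 1.4),
    "papillary_dermis": (2.6, 184.4, 0.774, 1.4),
    "reticular_dermis": (2.6, 184.4, 0.774, 1.4),
    "vessel_wall": (2.6, 184.4, 0.774, 1.4),
    "vessel_lumen": (206.2, 500.0, 0.98, 1.33),
}


@dataclass
class GeometryConfig:
    """Geometric parameters of the tissue block (all lengths in μm).

    Defaults reproduce the reference lesion geometry: 40 μm lumen
    diameter, 5 μm wall, vessel centers at 360 μm depth spaced 250 μm
    apart, in a 500 × 500 × 810 μm domain.  ``coarse_wall=True`` permits
    voxels at least as large as the wall thickness, assigning the wall
    to the nearest shell of voxels around the lumen (fast / test mode).
    """

    domain_size: Tuple[float, float, float] = (500.0, 500.0, 810.0)
    voxel_size: float = 5.0
    layer_thicknesses: Tuple[float, float, float] = (10.0, 100.0, 100.0)
    #: thickness of stratum corneum, viable epidermis, papillary dermis;
    #: the reticular dermis fills the remaining depth.
    lumen_diameter: float = 40.0
    wall_thickness: float = 5.0
    center_depth: float = 360.0
    spacing: float = 250.0
    count: int = 2
    coarse_wall: bool = False

    def __post_init__(self) -> None:
        if self.voxel_size <= 0 or any(s <= 0 for s in self.domain_size):
            raise ValueError("all lengths must be positive")
        if any(t <= 0 for t in self.layer_thicknesses):
            raise ValueError("layer thicknesses must be positive")
        sc, ve, _pap = self.layer_thicknesses
        if abs(sc + ve - 110.0) > 1e-9:
            raise ValueError("epidermal sublayers must total 110 um")
        h = self.voxel_size
        depth = self.domain_size[2]
        bounds = np.cumsum(self.layer_thicknesses)
        for b in bounds:
            if min(b % h, h - b % h) > h / 2 + 1e-9:
                raise ValueError(f"voxel size {h} does not resolve layer boundary {b}")
        if self.count > 0:
            if h > self.wall_thickness and not self.coarse_wall:
                raise ValueError(
                    "voxel_size >= wall_thickness: vessel wall unresolvable "
                    "(set coarse_wall=True for nearest-shell assignment)"
                )
            r_out = self.lumen_diameter / 2 + self.wall_thickness
            if self.center_depth - r_out < bounds[2] or self.center_depth + r_out > depth:
                raise ValueError("capillary not fully contained in the dermis")
            ly = self.domain_size[1]
            span = (self.count - 1) * self.spacing
            if span + 2 * r_out > ly:
                raise ValueError("capillaries extend beyond the lateral domain")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(int(round(s / self.voxel_size)) for s in self.domain_size)

    def vessel_centers_y(self) -> np.ndarray:
        """y coordinates of the vessel axes, centered in the domain."""
        ly = self.domain_size[1]
        span = (self.count - 1) * self.spacing
        return ly / 2 - span / 2 + self.spacing * np.arange(self.count)


@dataclass
class TissueModel:
    """Labeled voxel grid with per-region material properties."""

    config: GeometryConfig
    labels: np.ndarray  # (nx, ny, nz) int8 region codes
    optical_table: Dict[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(OPTICAL_TABLE)
    )

    @property
    def voxel_size(self) -> float:
        return self.config.voxel_size

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    def mask(self, label: str) -> np.ndarray:
        if label not in REGION_CODES:
            raise KeyError(f"unknown region label: {label!r}")
        return self.labels == REGION_CODES[label]

    def lumen_mask(self) -> np.ndarray:
        return self.mask("vessel_lumen")

    def property_field(self, index: int) -> np.ndarray:
        """Per-voxel optical property by column of the optical table."""
        lut = np.empty(len(REGION_CODES))
        for name, code in REGION_CODES.items():
            lut[code] = self.optical_table[name][index]
        return lut[self.labels]

    def mu_a(self) -> np.ndarray:
        return self.property_field(0)

    def mu_s(self) -> np.ndarray:
        return self.property_field(1)

    def anisotropy(self) -> np.ndarray:
        return self.property_field(2)

    def refractive_index(self) -> np.ndarray:
        return self.property_field(3)

    def cell_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return (np.arange(n) + 0.5) * self.voxel_size


def build_tissue_model(config: GeometryConfig) -> TissueModel:
    """Label every voxel of the grid by skin layer or vessel compartment.

    Layers are assigned by the depth of the voxel center; lumen voxels
    are those whose centers lie within the lumen radius of a vessel
    axis, wall voxels within lumen radius + wall thickness.
    """
    nx, ny, nz = config.shape
    h = config.voxel_size
    zc = (np.arange(nz) + 0.5) * h
    sc, ve, pap = config.layer_thicknesses
    layer = np.full(nz, REGION_CODES["reticular_dermis"], dtype=np.int8)
    layer[zc < sc + ve + pap] = REGION_CODES["papillary_dermis"]
    layer[zc < sc + ve] = REGION_CODES["epidermis"]
    layer[zc < sc] = REGION_CODES["stratum_corneum"]
    labels = np.broadcast_to(layer[None, None, :], (nx, ny, nz)).copy()

    if config.count > 0:
        yc = (np.arange(ny) + 0.5) * h
        r_lumen = config.lumen_diameter / 2
        r_outer = r_lumen + config.wall_thickness
        dist2 = np.full((ny, nz), np.inf)
        for y0 in config.vessel_centers_y():
            d2 = (yc[:, None] - y0) ** 2 + (zc[None, :] - config.center_depth) ** 2
            dist2 = np.minimum(dist2, d2)
        wall = dist2 <= r_outer**2
        lumen = dist2 <= r_lumen**2
        if config.coarse_wall and not np.any(wall & ~lumen):
            # nearest-shell fallback: one-voxel ring around the lumen
            from scipy.ndimage import binary_dilation

            wall = binary_dilation(lumen)
        labels[:, wall & ~lumen] = REGION_CODES["vessel_wall"]
        labels[:, lumen] = REGION_CODES["vessel_lumen"]
    return TissueModel(config=config, labels=labels)


def region_volume(model: TissueModel, label: str) -> float:
    """Volume of a labeled region in μm³ (voxel count × voxel volume)."""
    return float(model.mask(label).sum()) * model.voxel_volume
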