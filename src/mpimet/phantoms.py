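"""Digital iron-concentration phantoms.

All phantoms live on the scanner grid defined by a :class:`ScannerConfig`:
world coordinates in millimetres, origin at the field-of-view center, voxel
centers addressed. Concentration maps store micrograms of iron *per voxel*,
so total iron mass is simply the array sum; every generator conserves the
requested mass to well under 0.1% (bilinear point splatting is exact, disk
and region fills distribute mass uniformly over the support).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .forward import ScannerConfig

__all__ = [
    "VoxelPhantom",
    "make_point_sources",
    "make_shine_through_phantom",
    "make_tumor_phantom",
    "make_calibration_ladder",
    "ellipse_mask",
]


@dataclass
class VoxelPhantom:
    """Nonnegative iron-concentration map with physical voxel spacing.

    concentration: 2D (ny, nx) or 3D (nz, ny, nx) array of ugFe per voxel.
    spacing: mm per axis, in the same axis order as the array.
    origin: mm world offset of voxel (0, ..., 0)'s center.
    """

    concentration: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = None

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.concentration.ndim not in (2, 3):
            raise ValueError("concentration must be a 2D or 3D array")
        if np.any(self.concentration < 0):
            raise ValueError("concentration must be nonnegative everywhere")
        if not np.all(np.isfinite(self.concentration)):
            raise ValueError("concentration must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.concentration.ndim:
            raise ValueError("spacing must give one pitch per array axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on every axis")
        if self.origin is None:
            # centered grid: world origin at the array center
            self.origin = tuple(
                -(n - 1) / 2.0 * s
                for n, s in zip(self.concentration.shape, self.spacing)
            )
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def total_mass(self) -> float:
        """Total iron mass in ugFe."""
        return float(self.concentration.sum())

    @property
    def shape(self) -> tuple[int, ...]:
        return self.concentration.shape


def _grid_coords(config: ScannerConfig):
    x, y = config.voxel_centers()
    xx, yy = np.meshgrid(x, y)
    return xx, yy


def _check_inside_fov(pos, config: ScannerConfig, margin: float = 0.0) -> None:
    for p, f in zip(pos, config.fov):
        if abs(p) + margin > f / 2.0:
            raise ValueError(
                f"position {tuple(pos)} mm (margin {margin} mm) lies outside "
                f"the field of view {config.fov} mm"
            )


def make_point_sources(positions, masses, config: ScannerConfig) -> VoxelPhantom:
    """Phantom of ideal point sources.

    Each source's mass (ugFe) is splatted bilinearly onto the four voxels
    around its (x, y) position, preserving both total mass and center of
    mass; positions outside the FOV are rejected.
    """
    positions = [tuple(float(c) for c in p) for p in positions]
    masses = [float(m) for m in masses]
    if len(positions) != len(masses):
        raise ValueError("positions and masses must have equal length")
    if any(m < 0 for m in masses):
        raise ValueError("masses must be nonnegative")
    nx, ny = config.grid
    dx, dy = config.spacing
    conc = np.zeros((ny, nx))
    for (px, py), m in zip(positions, masses):
        _check_inside_fov((px, py), config)
        fx = px / dx + (nx - 1) / 2.0
        fy = py / dy + (ny - 1) / 2.0
        ix, iy = int(np.floor(fx)), int(np.floor(fy))
        ix = min(max(ix, 0), nx - 2)
        iy = min(max(iy, 0), ny - 2)
        wx, wy = fx - ix, fy - iy
        conc[iy, ix] += m * (1 - wx) * (1 - wy)
        conc[iy, ix + 1] += m * wx * (1 - wy)
        conc[iy + 1, ix] += m * (1 - wx) * wy
        conc[iy + 1, ix + 1] += m * wx * wy
    return VoxelPhantom(conc, spacing=(config.spacing[1], config.spacing[0]))


def _disk_mask(config: ScannerConfig, center, diameter: float) -> np.ndarray:
    xx, yy = _grid_coords(config)
    r = diameter / 2.0
    mask = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= r**2
    if not mask.any():
        # sub-voxel well: fall back to the nearest voxel so mass is conserved
        idx = np.unravel_index(
            np.argmin((xx - center[0]) ** 2 + (yy - center[1]) ** 2), xx.shape
        )
        mask = np.zeros_like(xx, dtype=bool)
        mask[idx] = True
    return mask


def make_shine_through_phantom(center_mass: float = 300.0,
                               satellite_mass: float = 30.0,
                               n_satellites: int = 6,
                               spacing_increment: float = 2.5,
                               well_diameter: float = 1.5,
                               config: ScannerConfig | None = None) -> VoxelPhantom:
    """Dynamic-range test phantom: central well plus radial satellite wells.

    A central disk of ``well_diameter`` at the FOV center holds
    ``center_mass`` ugFe; satellite k (k = 1..n) sits on the +x ray at radius
    ``k * spacing_increment`` with ``satellite_mass`` ugFe each. Defaults give
    the 300 ug / 6 x 30 ug, 1.5 mm well, 2.5 mm increment layout (a 10x
    concentration step between center and satellites).
    """
    if config is None:
        config = ScannerConfig()
    if center_mass < 0 or satellite_mass < 0:
        raise ValueError("masses must be nonnegative")
    if well_diameter <= 0:
        raise ValueError("well_diameter must be > 0")
    if n_satellites < 0:
        raise ValueError("n_satellites must be >= 0")
    farthest = n_satellites * spacing_increment
    _check_inside_fov((farthest, 0.0), config, margin=well_diameter / 2.0)
    nx, ny = config.grid
    conc = np.zeros((ny, nx))

    def fill(center, mass):
        mask = _disk_mask(config, center, well_diameter)
        conc[mask] += mass / mask.sum()

    fill((0.0, 0.0), center_mass)
    for k in range(1, n_satellites + 1):
        fill((k * spacing_increment, 0.0), satellite_mass)
    return VoxelPhantom(conc, spacing=(config.spacing[1], config.spacing[0]))


def ellipse_mask(config: ScannerConfig, radii=(20.0, 15.0), center=(0.0, 0.0)) -> np.ndarray:
    """Filled elliptical region mask (a convenient closed tumor boundary)."""
    xx, yy = _grid_coords(config)
    return ((xx - center[0]) / radii[0]) ** 2 + ((yy - center[1]) / radii[1]) ** 2 <= 1.0


def make_tumor_phantom(mode: str, fill_mass_mg: float, geometry: np.ndarray,
                       rim_width: float = 3.0,
                       spacing: tuple[float, ...] | None = None,
                       config: ScannerConfig | None = None) -> VoxelPhantom:
    """Fillable tumor phantom: uniform interior ("hollow") or annular rim.

    Parameters
    ----------
    mode : {"hollow", "rim"}
        "hollow" fills the whole closed region; "rim" fills only a shell of
        width ``rim_width`` mm just inside the boundary (an immune-excluded
        phenotype with tracer-laden macrophages confined to the margin).
    fill_mass_mg : float
        Tracer load in mgFe, distributed uniformly over the support.
    geometry : bool array
        Closed (filled) region mask on the scanner grid.
    """
    if mode not in ("hollow", "rim"):
        raise ValueError("mode must be 'hollow' or 'rim'")
    if fill_mass_mg < 0:
        raise ValueError("fill_mass_mg must be nonnegative")
    geometry = np.asarray(geometry, dtype=bool)
    if not geometry.any():
        raise ValueError("geometry mask is empty")
    if spacing is None:
        if config is None:
            config = ScannerConfig()
        spacing = (config.spacing[1], config.spacing[0])
    interior = ndimage.binary_fill_holes(geometry)
    if mode == "hollow":
        support = interior
    else:
        if rim_width <= 0:
            raise ValueError("rim mode requires rim_width > 0")
        n_erode = max(1, round(rim_width / min(spacing)))
        core = ndimage.binary_erosion(interior, iterations=n_erode)
        if not core.any():
            raise ValueError(
                f"rim_width {rim_width} mm exceeds the inscribed radius of the "
                "geometry; no core remains"
            )
        support = interior & ~core
    conc = np.zeros(geometry.shape)
    conc[support] = fill_mass_mg * 1e3 / support.sum()  # mg -> ug
    return VoxelPhantom(conc, spacing=spacing)


def make_calibration_ladder(masses_mg, config: ScannerConfig | None = None,
                            positions=None, sample_diameter: float = 5.0):
    """One compact sample phantom per mass, at distinct FOV positions.

    Emulates a signal-vs-iron calibration ladder (e.g. 0 to 1 mgFe in nine
    steps): each mass becomes a sub-centimetre disk, by default spread along
    the x axis so samples never overlap. Returns a list of VoxelPhantom in
    input order. ``masses_mg`` in mgFe; phantoms store ugFe.
    """
    if config is None:
        config = ScannerConfig()
    masses_mg = [float(m) for m in masses_mg]
    if any(m < 0 for m in masses_mg):
        raise ValueError("masses must be nonnegative")
    n = len(masses_mg)
    if positions is None:
        if n == 1:
            positions = [(0.0, 0.0)]
        else:
            span = 0.8 * config.fov[0]
            xs = np.linspace(-span / 2.0, span / 2.0, n)
            positions = [(float(x), 0.0) for x in xs]
    positions = [tuple(float(c) for c in p) for p in positions]
    if len(positions) != n:
        raise ValueError("need one position per mass")
    if len(set(positions)) != n:
        raise ValueError("calibration sample positions must be distinct")
    phantoms = []
    nx, ny = config.grid
    for (pos, m) in zip(positions, masses_mg):
        _check_inside_fov(pos, config, margin=sample_diameter / 2.0)
        mask = _disk_mask(config, pos, sample_diameter)
        conc = np.zeros((ny, nx))
        conc[mask] = m * 1e3 / mask.sum()
        phantoms.append(VoxelPhantom(conc, spacing=(config.spacing[1], config.spacing[0])))
    return phantoms
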