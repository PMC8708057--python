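"""ETDRS-grid thickness mapping and the CFT / CFV / TRV features.

The ETDRS grid divides the macula into 9 sectors: a central 1-mm-diameter
disc, an inner ring (1-3 mm) of four quadrants and an outer ring (3-6 mm) of
four quadrants.  From a retinal thickness map centred on the fovea we report:

* CFT — central foveal thickness: mean thickness over the central disc (um);
* CFV — central foveal volume: mean thickness x central disc area (mm^3);
* TRV — total retinal volume: sum of the 9 sector volumes (mm^3), i.e. the
  volume over the full pi * 3^2 = 28.3 mm^2 grid footprint.

Sector volume follows the device convention mean thickness x sector area
rather than voxel summation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import ScanGeometry
from .segment import BoundaryPair

__all__ = [
    "ThicknessMap",
    "ETDRSFeatures",
    "SECTOR_NAMES",
    "build_thickness_map",
    "etdrs_features",
    "sector_area",
]

# central disc, inner ring quadrants, outer ring quadrants
SECTOR_NAMES = (
    "central",
    "inner_superior",
    "inner_nasal",
    "inner_inferior",
    "inner_temporal",
    "outer_superior",
    "outer_nasal",
    "outer_inferior",
    "outer_temporal",
)
GRID_DIAMETERS_MM = (1.0, 3.0, 6.0)


@dataclass
class ThicknessMap:
    """En-face retinal thickness in micrometres on an isotropic grid.

    Rows run along the slow axis (B-scan index direction), columns along the
    fast axis; ``px_per_mm`` is the grid resolution and ``center`` the fovea
    position in (row, col) grid coordinates.
    """

    grid: np.ndarray
    px_per_mm: float
    center: tuple[float, float]
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        if self.grid.ndim != 2:
            raise ValueError("thickness grid must be 2-D")
        if np.nanmin(self.grid) < 0:
            raise ValueError("thickness must be >= 0")
        r, c = self.center
        if not (0 <= r < self.grid.shape[0] and 0 <= c < self.grid.shape[1]):
            raise ValueError(f"center {self.center} outside grid {self.grid.shape}")


def build_thickness_map(
    boundaries: list[BoundaryPair | None],
    geometry: ScanGeometry,
    grid_px_per_mm: float = 50.0,
) -> ThicknessMap:
    """Grid per-scan ILM/RPE separations onto an isotropic en-face map.

    Thickness at (scan i, column j) is ``(rpe - ilm) * axial_um_per_px``;
    invalid columns are linearly interpolated within their scan, scans with
    no boundaries (``None``) are dropped, and the scattered rows are
    bilinearly interpolated onto a ``depth_mm x width_mm`` grid at
    ``grid_px_per_mm``.
    """
    rows = []
    ys = []
    positions = geometry.bscan_positions_mm()
    for i, bp in enumerate(boundaries):
        if bp is None:
            continue
        t = bp.thickness_px() * geometry.axial_um_per_px
        cols = np.arange(t.size)
        good = np.isfinite(t)
        if good.sum() < 2:
            continue
        t = np.interp(cols, cols[good], t[good])
        rows.append(t)
        ys.append(positions[i])
    if len(rows) < 2:
        raise ValueError("need valid boundaries on at least 2 B-scans")
    n_cols = rows[0].size
    xs = np.linspace(0.0, geometry.width_mm, n_cols)
    interp = RegularGridInterpolator(
        (np.asarray(ys), xs), np.vstack(rows), bounds_error=False, fill_value=None
    )
    ny = max(int(round(geometry.depth_mm * grid_px_per_mm)) + 1, 2)
    nx = max(int(round(geometry.width_mm * grid_px_per_mm)) + 1, 2)
    gy = np.linspace(0.0, geometry.depth_mm, ny)
    gx = np.linspace(0.0, geometry.width_mm, nx)
    yy, xx = np.meshgrid(gy, gx, indexing="ij")
    grid = interp(np.stack([yy.ravel(), xx.ravel()], axis=-1)).reshape(ny, nx)
    grid = np.clip(grid, 0.0, None)
    px_per_mm = (ny - 1) / geometry.depth_mm
    center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    return ThicknessMap(grid=grid, px_per_mm=px_per_mm, center=center, geometry=geometry)


@dataclass
class ETDRSFeatures:
    cft_um: float
    cfv_mm3: float
    trv_mm3: float
    sector_volumes_mm3: dict[str, float]
    sector_mean_um: dict[str, float]


def sector_area(inner_diam_mm: float, outer_diam_mm: float, n_wedges: int = 1) -> float:
    """Area in mm^2 of one wedge of the annulus between two diameters."""
    if not outer_diam_mm > inner_diam_mm >= 0:
        raise ValueError(
            f"need outer > inner >= 0, got inner={inner_diam_mm}, outer={outer_diam_mm}"
        )
    if n_wedges < 1:
        raise ValueError("n_wedges must be >= 1")
    r_in = inner_diam_mm / 2.0
    r_out = outer_diam_mm / 2.0
    return float(np.pi * (r_out**2 - r_in**2) / n_wedges)


def _sector_masks(tmap: ThicknessMap, center: tuple[float, float]):
    ny, nx = tmap.grid.shape
    rr, cc = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    dy = (rr - center[0]) / tmap.px_per_mm
    dx = (cc - center[1]) / tmap.px_per_mm
    r = np.hypot(dx, dy)
    # angle from the +col axis; quadrants split at +/-45 degrees.  Rows grow
    # along the slow axis, so -dy points "superior" on the en-face map.
    ang = np.degrees(np.arctan2(-dy, dx))
    d_c, d_i, d_o = GRID_DIAMETERS_MM
    quadrants = {
        "superior": (ang >= 45) & (ang < 135),
        "nasal": (ang >= -45) & (ang < 45),
        "inferior": (ang >= -135) & (ang < -45),
        "temporal": (ang >= 135) | (ang < -135),
    }
    masks = {"central": r <= d_c / 2}
    inner = (r > d_c / 2) & (r <= d_i / 2)
    outer = (r > d_i / 2) & (r <= d_o / 2)
    for q, qm in quadrants.items():
        masks[f"inner_{q}"] = inner & qm
        masks[f"outer_{q}"] = outer & qm
    return masks, r


def etdrs_features(
    tmap: ThicknessMap, center: tuple[float, float] | None = None
) -> ETDRSFeatures:
    """Extract CFT, CFV, TRV and the 9 sector volumes from a thickness map.

    ``center`` is a (row, col) grid position of the fovea; by default the
    grid centre (the raster is assumed approximately fovea-centred).  If the
    6-mm grid extends beyond the map, truncated sectors average over the
    available pixels (with a warning) but keep their nominal en-face area.
    """
    center = center if center is not None else tmap.center
    r0, c0 = center
    ny, nx = tmap.grid.shape
    if not (0 <= r0 < ny and 0 <= c0 < nx):
        raise ValueError(f"center {center} outside grid of shape {tmap.grid.shape}")
    masks, r = _sector_masks(tmap, center)

    # does a full 3-mm-radius disc fit around the centre?
    margin_px = 3.0 * tmap.px_per_mm
    if min(r0, ny - 1 - r0, c0, nx - 1 - c0) < margin_px - 1e-9:
        warnings.warn(
            "ETDRS 6-mm grid extends beyond the thickness map; "
            "truncated sectors use available pixels only",
            stacklevel=2,
        )

    d_c, d_i, d_o = GRID_DIAMETERS_MM
    areas = {"central": sector_area(0.0, d_c)}
    for q in ("superior", "nasal", "inferior", "temporal"):
        areas[f"inner_{q}"] = sector_area(d_c, d_i, 4)
        areas[f"outer_{q}"] = sector_area(d_i, d_o, 4)

    sector_mean = {}
    sector_vol = {}
    for name in SECTOR_NAMES:
        m = masks[name]
        if not m.any():
            raise ValueError(f"sector {name!r} contains no grid pixels")
        mean_um = float(tmap.grid[m].mean())
        sector_mean[name] = mean_um
        sector_vol[name] = mean_um / 1000.0 * areas[name]

    cft = sector_mean["central"]
    cfv = sector_vol["central"]
    trv = float(sum(sector_vol.values()))
    return ETDRSFeatures(
        cft_um=cft,
        cfv_mm3=cfv,
        trv_mm3=trv,
        sector_volumes_mm3=sector_vol,
        sector_mean_um=sector_mean,
    )
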