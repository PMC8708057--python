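"""Physical scan geometry for a raster OCT acquisition.

A macular raster scan covers a ``width_mm`` x ``depth_mm`` en-face rectangle
(fast x slow axis) with ``n_bscans`` uniformly spaced B-scans.  Each B-scan is
a depth x lateral image whose pixel pitch is given in micrometres per pixel.
Raster files carry no physical metadata, so the geometry always travels in a
sidecar config (YAML or JSON) and is never inferred from pixels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["ScanGeometry"]


@dataclass(frozen=True)
class ScanGeometry:
    """En-face extent, B-scan count and pixel scales of a raster scan.

    Parameters
    ----------
    width_mm : float
        En-face fast-axis (lateral) extent. Default 9 mm.
    depth_mm : float
        En-face slow-axis extent covered by the B-scan positions. Default 6 mm.
    n_bscans : int
        Number of uniformly spaced B-scans. Default 25.
    axial_um_per_px : float
        Axial (depth, image-row) pixel pitch in micrometres.
    lateral_um_per_px : float
        Lateral (image-column) pixel pitch in micrometres.
    spacing_mm : float or None
        Inter-B-scan spacing h. ``None`` (default) derives
        ``depth_mm / (n_bscans - 1)``; pass a value to override, e.g. to force
        a vendor-reported spacing that disagrees with the en-face extent.
    """

    width_mm: float = 9.0
    depth_mm: float = 6.0
    n_bscans: int = 25
    axial_um_per_px: float = 3.87
    lateral_um_per_px: float = 9000.0 / 512.0
    spacing_mm: float | None = None

    def __post_init__(self) -> None:
        for name in ("width_mm", "depth_mm", "axial_um_per_px", "lateral_um_per_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_bscans < 2:
            raise ValueError(f"n_bscans must be >= 2, got {self.n_bscans}")
        if self.spacing_mm is not None and self.spacing_mm <= 0:
            raise ValueError(f"spacing_mm override must be > 0, got {self.spacing_mm}")

    @property
    def bscan_spacing_mm(self) -> float:
        """Resolved inter-B-scan spacing h in mm."""
        if self.spacing_mm is not None:
            return self.spacing_mm
        return self.depth_mm / (self.n_bscans - 1)

    @property
    def axial_mm_per_px(self) -> float:
        return self.axial_um_per_px / 1000.0

    @property
    def lateral_mm_per_px(self) -> float:
        return self.lateral_um_per_px / 1000.0

    @property
    def pixel_area_mm2(self) -> float:
        """In-plane (B-scan) area of one pixel in mm^2."""
        return self.axial_mm_per_px * self.lateral_mm_per_px

    @property
    def en_face_area_mm2(self) -> float:
        """Scanned en-face rectangle area in mm^2 (9 x 6 -> 54)."""
        return self.width_mm * self.depth_mm

    def bscan_positions_mm(self):
        """Slow-axis position of every B-scan, starting at 0."""
        import numpy as np

        return np.arange(self.n_bscans) * self.bscan_spacing_mm

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScanGeometry":
        """Load from a YAML or JSON sidecar config."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
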