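"""Raster I/O: B-scan stacks, binary masks, overlays and result tables.

B-scans arrive as 8-bit grayscale raster files (PNG/TIFF), one file per
B-scan, ordered along the slow axis.  File ordering is lexicographic with
natural-number sorting, so ``scan_2.png`` sorts before ``scan_10.png``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import ScanGeometry

__all__ = [
    "BScanStack",
    "ResultRecord",
    "natural_sort_key",
    "load_stack",
    "save_stack",
    "load_mask",
    "save_mask",
    "write_overlay",
    "write_report",
    "read_report",
]

# ITU-R BT.601 luma weights, used to collapse accidental RGB exports.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class BScanStack:
    """A stack of co-registered B-scans plus its physical geometry.

    ``images`` is an ``(n_bscans, H, W)`` uint8 array ordered along the slow
    axis; row 0 of every B-scan is the vitreous (anterior) side.
    """

    images: np.ndarray
    geometry: ScanGeometry
    eye_id: str = ""

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 3:
            raise ValueError(f"images must be (n, H, W), got shape {self.images.shape}")
        if self.images.dtype != np.uint8:
            if self.images.min() < 0 or self.images.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.images = self.images.astype(np.uint8)

    @property
    def n_bscans(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self):
        return self.images.shape

    def __iter__(self):
        return iter(self.images)


@dataclass
class ResultRecord:
    """Per-eye quantification summary written to the result table."""

    eye_id: str
    areas_mm2: list[float] = field(default_factory=list)
    edema_volume_mm3: float = 0.0
    cft_um: float = float("nan")
    cfv_mm3: float = float("nan")
    trv_mm3: float = float("nan")
    qc_noise: float = float("nan")
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.edema_volume_mm3 < 0:
            raise ValueError("edema volume must be >= 0")
        if any(a < 0 for a in self.areas_mm2):
            raise ValueError("per-scan areas must be >= 0")


_NUM_RE = re.compile(r"(\d+)")


def natural_sort_key(path: str | Path):
    """Sort key treating digit runs as numbers: scan_2 < scan_10."""
    parts = _NUM_RE.split(str(path))
    return [int(p) if p.isdigit() else p for p in parts]


def _read_gray(path: str | Path) -> np.ndarray:
    try:
        img = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"unreadable raster file: {path}") from exc
    img = np.asarray(img)
    if img.ndim == 3:  # RGB(A) -> luminance
        img = img[..., :3].astype(float) @ _LUMA
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if img.ndim != 2:
        raise IOError(f"{path}: expected a 2-D grayscale image, got shape {img.shape}")
    if img.dtype != np.uint8:
        if img.max() > 255:
            raise IOError(f"{path}: not an 8-bit image (max {img.max()})")
        img = img.astype(np.uint8)
    return img


def load_stack(
    paths: Sequence[str | Path] | str | Path,
    geometry: ScanGeometry,
    eye_id: str = "",
    sort: bool = False,
) -> BScanStack:
    """Load an ordered list of raster files into a :class:`BScanStack`.

    ``paths`` may also be a directory, in which case every ``.png``/``.tif``/
    ``.tiff`` file in it is taken in natural sort order.  The file count must
    equal ``geometry.n_bscans``.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        directory = Path(paths)
        paths = [
            p
            for p in directory.iterdir()
            if p.suffix.lower() in {".png", ".tif", ".tiff"}
        ]
        sort = True
    paths = list(paths)
    if sort:
        paths = sorted(paths, key=natural_sort_key)
    if len(paths) < 2:
        raise ValueError(f"need at least 2 B-scan files, got {len(paths)}")
    if len(paths) != geometry.n_bscans:
        raise ValueError(
            f"file count {len(paths)} does not match geometry.n_bscans "
            f"{geometry.n_bscans}"
        )
    images = [_read_gray(p) for p in paths]
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent B-scan dimensions: {sorted(shapes)}")
    return BScanStack(np.stack(images), geometry, eye_id=eye_id)


def save_stack(stack: BScanStack, directory: str | Path, prefix: str = "bscan") -> list[Path]:
    """Write every B-scan as ``<prefix>_<i>.png``; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = len(str(stack.n_bscans - 1))
    paths = []
    for i, img in enumerate(stack.images):
        p = directory / f"{prefix}_{i:0{width}d}.png"
        iio.imwrite(p, img)
        paths.append(p)
    return paths


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask raster; any nonzero pixel counts as foreground."""
    return _read_gray(path) > 0


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def write_overlay(
    image: np.ndarray,
    mask: np.ndarray,
    path: str | Path,
    color: tuple[int, int, int] = (255, 0, 0),
) -> np.ndarray:
    """Overlay ``mask`` on a grayscale B-scan in a solid color (default red).

    Unmasked pixels keep their grayscale value in all three channels; masked
    pixels are replaced by ``color``.  Returns the RGB array written.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, bool)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    rgb = np.repeat(image[..., None], 3, axis=-1).astype(np.uint8)
    rgb[mask] = np.asarray(color, np.uint8)
    iio.imwrite(Path(path), rgb)
    return rgb


_REPORT_COLUMNS = [
    "eye_id",
    "edema_volume_mm3",
    "cft_um",
    "cfv_mm3",
    "trv_mm3",
    "qc_noise",
    "qc_pass",
    "areas_mm2",
]


def write_report(records: Iterable[ResultRecord], path: str | Path) -> pd.DataFrame:
    """Write result records to CSV (one row per eye, ``areas_mm2`` as a
    ``;``-joined list).  Numeric fields keep >= 6 significant digits so a
    read-back reproduces the values."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    rows = []
    for r in records:
        rows.append(
            {
                "eye_id": r.eye_id,
                "edema_volume_mm3": r.edema_volume_mm3,
                "cft_um": r.cft_um,
                "cfv_mm3": r.cfv_mm3,
                "trv_mm3": r.trv_mm3,
                "qc_noise": r.qc_noise,
                "qc_pass": r.qc_pass,
                "areas_mm2": ";".join(format(a, ".8g") for a in r.areas_mm2),
            }
        )
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.8g")
    return df


def read_report(path: str | Path) -> list[ResultRecord]:
    df = pd.read_csv(path, keep_default_na=False, na_values=["nan", ""])
    out = []
    for _, row in df.iterrows():
        areas = (
            [float(a) for a in str(row["areas_mm2"]).split(";")]
            if str(row["areas_mm2"])
            else []
        )
        out.append(
            ResultRecord(
                eye_id=str(row["eye_id"]),
                areas_mm2=areas,
                edema_volume_mm3=float(row["edema_volume_mm3"]),
                cft_um=float(row["cft_um"]),
                cfv_mm3=float(row["cfv_mm3"]),
                trv_mm3=float(row["trv_mm3"]),
                qc_noise=float(row["qc_noise"]),
                qc_pass=bool(row["qc_pass"] in (True, "True", "true", 1, "1")),
            )
        )
    return out
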