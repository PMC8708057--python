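"""Retinal boundary detection and intraretinal fluid segmentation.

The retina is delimited per A-scan (image column) by the inner limiting
membrane (ILM, first bright transition scanning down from the vitreous) and
the retinal pigment epithelium (RPE, first dark transition scanning up from
the choroid).  Fluid pockets appear as near-zero-intensity regions between
the two boundaries after SNR balancing; they are extracted by thresholding,
cleaned by a binary opening, and size-filtered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .geometry import ScanGeometry

__all__ = [
    "BoundaryPair",
    "EdemaSegmentation",
    "BoundaryDetectionError",
    "detect_boundaries",
    "segment_edema",
    "region_areas",
]


class BoundaryDetectionError(RuntimeError):
    """Raised when too few A-scans yield a usable ILM/RPE pair."""


@dataclass
class BoundaryPair:
    """Per-column ILM and RPE row positions (sub-pixel) with validity flags."""

    ilm: np.ndarray
    rpe: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.ilm = np.asarray(self.ilm, float)
        self.rpe = np.asarray(self.rpe, float)
        self.valid = np.asarray(self.valid, bool)
        if not (self.ilm.shape == self.rpe.shape == self.valid.shape):
            raise ValueError("ilm, rpe and valid must share one shape")
        bad = self.valid & ~(self.ilm < self.rpe)
        if bad.any():
            raise ValueError("ilm must lie above rpe on every valid column")

    @property
    def n_cols(self) -> int:
        return self.ilm.size

    def thickness_px(self) -> np.ndarray:
        """Retinal thickness per column in pixels (NaN where invalid)."""
        t = self.rpe - self.ilm
        return np.where(self.valid, t, np.nan)

    def roi_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels strictly between ILM and RPE."""
        rows = np.arange(shape[0])[:, None]
        return self.valid[None, :] & (rows > self.ilm[None, :]) & (rows < self.rpe[None, :])


def _run_centroid(signal: np.ndarray, start: int) -> float:
    """Gradient-weighted centroid of the supra-threshold run starting at
    ``start`` (sub-pixel edge centre of a smoothed step)."""
    end = start
    while end < signal.size and signal[end] > 0:
        end += 1
    w = signal[start:end]
    idx = np.arange(start, end)
    return float((idx * w).sum() / w.sum())


def detect_boundaries(
    image: np.ndarray,
    gradient_threshold: float = 0.05,
    axial_smooth: int = 5,
    median_width: int = 15,
) -> BoundaryPair:
    """Locate the ILM and RPE on a balanced B-scan.

    Per column, the axial profile is boxcar-smoothed over ``axial_smooth``
    rows and differentiated.  The ILM is the first run of rows from the top
    where the gradient exceeds ``gradient_threshold``; the RPE the first run
    from the bottom where it falls below the negative threshold.  Each run is
    reduced to its gradient-weighted centroid, boundaries are median-smoothed
    across ``median_width`` columns, and invalid columns are filled by linear
    interpolation.

    Raises
    ------
    BoundaryDetectionError
        If fewer than half of the columns yield a valid ILM < RPE pair.
    """
    image = np.asarray(image, float)
    n_rows, n_cols = image.shape
    prof = ndimage.uniform_filter1d(image, axial_smooth, axis=0, mode="reflect")
    grad = np.gradient(prof, axis=0)

    ilm = np.full(n_cols, np.nan)
    rpe = np.full(n_cols, np.nan)
    up = grad > gradient_threshold
    down = grad < -gradient_threshold
    for c in range(n_cols):
        if up[:, c].any():
            start = int(up[:, c].argmax())
            ilm[c] = _run_centroid(np.where(up[:, c], grad[:, c], 0.0), start)
        if down[:, c].any():
            # first run scanning from the bottom
            rev = down[::-1, c]
            start_rev = int(rev.argmax())
            sig = np.where(rev, -grad[::-1, c], 0.0)
            rpe[c] = n_rows - 1 - _run_centroid(sig, start_rev)
    valid = np.isfinite(ilm) & np.isfinite(rpe) & (ilm < rpe)
    if valid.sum() < 0.5 * n_cols:
        raise BoundaryDetectionError(
            f"only {int(valid.sum())}/{n_cols} columns produced a valid "
            f"ILM/RPE pair"
        )

    cols = np.arange(n_cols)
    for arr in (ilm, rpe):
        arr[~valid] = np.interp(cols[~valid], cols[valid], arr[valid])
        arr[:] = ndimage.median_filter(arr, size=median_width, mode="nearest")
    # interpolation + smoothing fills every column; re-check ordering
    return BoundaryPair(ilm=ilm, rpe=rpe, valid=ilm < rpe)


@dataclass
class EdemaSegmentation:
    """Binary fluid mask plus its connected-component labelling."""

    mask: np.ndarray
    labels: np.ndarray
    dark_threshold: float
    min_component_px: int

    @property
    def n_components(self) -> int:
        return int(self.labels.max())

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def segment_edema(
    image: np.ndarray,
    boundaries: BoundaryPair,
    dark_threshold: float = 0.1,
    min_component_px: int = 25,
    opening_radius: int = 2,
) -> EdemaSegmentation:
    """Segment fluid pixels inside the retinal ROI of a balanced B-scan.

    Pixels darker than ``dark_threshold`` (on the [0, 1] balanced scale)
    strictly between ILM and RPE are thresholded, opened with a disk of
    ``opening_radius`` px, and components smaller than ``min_component_px``
    are dropped.
    """
    image = np.asarray(image, float)
    if not boundaries.valid.any():
        raise ValueError("boundaries contain no valid columns")
    roi = boundaries.roi_mask(image.shape)
    raw = (image < dark_threshold) & roi
    if opening_radius > 0:
        raw = morphology.opening(raw, morphology.disk(opening_radius))
        raw &= roi
    mask = raw
    if min_component_px > 1:
        # drop components with fewer than min_component_px pixels
        mask = morphology.remove_small_objects(raw, max_size=min_component_px - 1)
    labels = measure.label(mask, connectivity=2)
    return EdemaSegmentation(
        mask=mask,
        labels=labels,
        dark_threshold=dark_threshold,
        min_component_px=min_component_px,
    )


def region_areas(seg: EdemaSegmentation, geometry: ScanGeometry) -> float:
    """Fluid cross-section area of one B-scan in mm^2 (pixel count x pixel
    area)."""
    return seg.n_pixels * geometry.pixel_area_mm2
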