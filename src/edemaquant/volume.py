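"""Trapezoidal integration of per-B-scan fluid areas and the per-eye pipeline.

The fluid volume of an eye is estimated from the serial cross-section areas
A_1..A_n of the segmented pockets, integrated along the slow axis with the
trapezoidal rule:

    V = h/2 * (A_1 + A_n + 2 * sum_{i=2}^{n-1} A_i)

with h the inter-B-scan spacing in mm and the areas in mm^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import etdrs as _etdrs
from .geometry import ScanGeometry
from .io_formats import BScanStack, ResultRecord
from .preprocess import (
    SNRParams,
    Window,
    estimate_snr_params,
    median_despeckle,
    quality_gate,
    snr_balance,
    wiener_denoise,
)
from .segment import BoundaryDetectionError, detect_boundaries, region_areas, segment_edema

__all__ = [
    "AreaProfile",
    "VolumeResult",
    "PipelineParams",
    "QualityGateError",
    "trapezoid_volume",
    "quantify_stack",
]

log = logging.getLogger(__name__)


class QualityGateError(RuntimeError):
    """Raised when a stack exceeds the noise ceiling and no override is set."""


@dataclass
class AreaProfile:
    """Ordered per-B-scan fluid areas A_1..A_n (mm^2) with spacing h (mm)."""

    areas: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, float)
        if self.areas.ndim != 1 or self.areas.size < 2:
            raise ValueError("need a 1-D profile of at least 2 areas")
        if (self.areas < 0).any():
            raise ValueError("areas must be >= 0")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be > 0")

    @property
    def n(self) -> int:
        return self.areas.size


def trapezoid_volume(profile: AreaProfile) -> float:
    """Integrate an area profile into a volume (mm^3) by the trapezoidal
    rule; endpoints carry weight h/2, interior scans weight h."""
    return float(np.trapezoid(profile.areas, dx=profile.spacing_mm))


@dataclass
class PipelineParams:
    """Everything the per-eye pipeline needs besides the images."""

    wiener_window: tuple[int, int] = (5, 5)
    median_window: tuple[int, int] = (15, 15)
    dark_threshold: float = 0.1
    min_component_px: int = 25
    opening_radius: int = 2
    gradient_threshold: float = 0.05
    noise_ceiling: float = 90.0
    noise_window: Window | None = None
    signal_window: Window | None = None
    skip_quality_gate: bool = False
    compute_etdrs: bool = True
    etdrs_grid_px_per_mm: float = 50.0


@dataclass
class VolumeResult:
    """Edema volume plus the inputs that produced it."""

    edema_volume_mm3: float
    profile: AreaProfile
    snr_params: SNRParams
    params: PipelineParams
    invalid_scans: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.edema_volume_mm3 < 0:
            raise ValueError("volume must be >= 0")


def _fill_invalid(areas: np.ndarray) -> np.ndarray:
    """Linearly interpolate NaN areas from valid neighbours (edges: nearest)."""
    bad = ~np.isfinite(areas)
    if not bad.any():
        return areas
    if bad.all():
        raise BoundaryDetectionError("boundary detection failed on every B-scan")
    idx = np.arange(areas.size)
    out = areas.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], areas[~bad])
    return out


def quantify_stack(
    stack: BScanStack,
    params: PipelineParams | None = None,
) -> tuple[VolumeResult, ResultRecord]:
    """Run the full per-eye pipeline on a B-scan stack.

    Wiener denoise -> scan-average SNR parameters -> per-scan balancing ->
    median despeckle -> ILM/RPE detection -> fluid segmentation -> areas ->
    trapezoidal volume.  Scans whose boundary detection fails are marked
    invalid and their areas linearly interpolated from neighbours.  When
    ``params.compute_etdrs`` is set, the detected boundaries additionally
    yield an ETDRS feature set (CFT/CFV/TRV) on the same record.
    """
    params = params or PipelineParams()
    geometry = stack.geometry
    qc = quality_gate(stack, ceiling=params.noise_ceiling, noise_window=params.noise_window)
    if not qc.passed and not params.skip_quality_gate:
        raise QualityGateError(
            f"max per-scan noise {qc.max_noise:.2f} exceeds ceiling "
            f"{qc.ceiling:.2f}"
        )

    denoised = np.stack(
        [wiener_denoise(img, params.wiener_window) for img in stack.images]
    )
    snr = estimate_snr_params(
        denoised, noise_window=params.noise_window, signal_window=params.signal_window
    )

    areas = np.full(stack.n_bscans, np.nan)
    invalid: list[int] = []
    boundaries = []
    for i, img in enumerate(denoised):
        balanced = snr_balance(img, snr)
        despeckled = median_despeckle(balanced, params.median_window)
        try:
            bp = detect_boundaries(
                despeckled, gradient_threshold=params.gradient_threshold
            )
        except BoundaryDetectionError:
            log.warning("boundary detection failed on B-scan %d; interpolating", i)
            invalid.append(i)
            boundaries.append(None)
            continue
        boundaries.append(bp)
        seg = segment_edema(
            despeckled,
            bp,
            dark_threshold=params.dark_threshold,
            min_component_px=params.min_component_px,
            opening_radius=params.opening_radius,
        )
        areas[i] = region_areas(seg, geometry)

    areas = _fill_invalid(areas)
    profile = AreaProfile(areas=areas, spacing_mm=geometry.bscan_spacing_mm)
    volume = trapezoid_volume(profile)
    result = VolumeResult(
        edema_volume_mm3=volume,
        profile=profile,
        snr_params=snr,
        params=params,
        invalid_scans=invalid,
    )

    cft = cfv = trv = float("nan")
    if params.compute_etdrs:
        try:
            tmap = _etdrs.build_thickness_map(
                boundaries, geometry, grid_px_per_mm=params.etdrs_grid_px_per_mm
            )
            feats = _etdrs.etdrs_features(tmap)
            cft, cfv, trv = feats.cft_um, feats.cfv_mm3, feats.trv_mm3
        except ValueError:
            log.warning("ETDRS feature extraction failed; features set to NaN")

    record = ResultRecord(
        eye_id=stack.eye_id,
        areas_mm2=[float(a) for a in areas],
        edema_volume_mm3=volume,
        cft_um=cft,
        cfv_mm3=cfv,
        trv_mm3=trv,
        qc_noise=qc.max_noise,
        qc_pass=qc.passed,
    )
    return result, record
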