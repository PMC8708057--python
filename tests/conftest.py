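"""Shared fixtures: a coarse phantom geometry that keeps filter windows and
pocket sizes physically sensible while running fast."""

from __future__ import annotations

import numpy as np
import pytest

from edemaquant import Ellipsoid, PhantomSpec, ScanGeometry


@pytest.fixture
def fast_geometry() -> ScanGeometry:
    """9 x 6 mm raster at a coarse pixel pitch (200 x 256 px B-scans)."""
    return ScanGeometry(
        width_mm=9.0,
        depth_mm=6.0,
        n_bscans=25,
        axial_um_per_px=12.0,
        lateral_um_per_px=9000.0 / 256.0,
    )


@pytest.fixture
def fast_spec(fast_geometry) -> PhantomSpec:
    """Pocket-free layered retina: band rows [60, 160] of a 200-row scan."""
    return PhantomSpec(
        geometry=fast_geometry, n_rows=200, ilm_row=60.0, rpe_row=160.0, seed=0
    )


def centered_pocket(
    a_mm: float = 1.0, b_mm: float = 1.2, c_mm: float = 0.3, z_mm: float = 1.32
) -> Ellipsoid:
    """An ellipsoid centred laterally and on the middle B-scan of the fast
    phantom's retinal band (band spans 0.72-1.92 mm axially)."""
    return Ellipsoid(
        center_x_mm=4.5, center_y_mm=3.0, center_z_mm=z_mm, a_mm=a_mm, b_mm=b_mm, c_mm=c_mm
    )


@pytest.fixture
def pocket_spec(fast_spec) -> PhantomSpec:
    from dataclasses import replace

    return replace(fast_spec, pockets=(centered_pocket(),))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
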