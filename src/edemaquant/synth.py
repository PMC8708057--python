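"""Synthetic phantoms and cohorts with analytic ground truth.

``generate_phantom`` rasterises a layered-retina B-scan stack: a dark
vitreous above an ILM surface, a bright retinal band down to an RPE surface,
dark choroid below, and ellipsoidal fluid pockets inside the band.  OCT-like
degradation is applied as multiplicative speckle followed by salt-and-pepper
impulses.  The pocket volume and per-scan cross-section areas are analytic
(ellipsoid slices), so volume recovery can be checked against a value that is
independent of any rasterisation.

``generate_cohort`` draws a synthetic per-eye feature table shaped like a
treated diabetic-retinopathy cohort: log-normal edema volumes per response
group and tomography features linearly coupled to edema volume, so the
regression-threshold and group-comparison statistics can be exercised with
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ScanGeometry
from .io_formats import BScanStack

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "generate_cohort",
    "DEFAULT_GROUP_EFFECTS",
    "DEFAULT_FEATURE_COUPLING",
    "NO_EDEMA_EFFECTS",
]


@dataclass(frozen=True)
class Ellipsoid:
    """An axis-aligned ellipsoidal fluid pocket in scan coordinates (mm).

    ``x`` runs along the lateral (fast) axis, ``y`` along the slow axis,
    ``z`` axially from the top of the B-scan.  ``a, b, c`` are the semi-axes
    along x, y, z.
    """

    center_x_mm: float
    center_y_mm: float
    center_z_mm: float
    a_mm: float
    b_mm: float
    c_mm: float

    def __post_init__(self) -> None:
        if min(self.a_mm, self.b_mm, self.c_mm) <= 0:
            raise ValueError("ellipsoid semi-axes must be > 0")

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.a_mm * self.b_mm * self.c_mm

    def slice_area_mm2(self, y_mm: float) -> float:
        """Analytic cross-section area of the slice at slow-axis position y:
        pi * a * c * (1 - d^2/b^2) for |d| < b, else 0."""
        d = y_mm - self.center_y_mm
        if abs(d) >= self.b_mm:
            return 0.0
        return float(np.pi * self.a_mm * self.c_mm * (1.0 - (d / self.b_mm) ** 2))

    def bbox(self):
        return (
            (self.center_x_mm - self.a_mm, self.center_x_mm + self.a_mm),
            (self.center_y_mm - self.b_mm, self.center_y_mm + self.b_mm),
            (self.center_z_mm - self.c_mm, self.center_z_mm + self.c_mm),
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Layered-retina phantom description.

    Boundary surfaces are flat rows with an optional lateral tilt and an
    optional Gaussian foveal dip of the ILM; intensities are 8-bit means
    before noise.
    """

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    n_rows: int = 496
    ilm_row: float = 100.0
    rpe_row: float = 350.0
    tilt_px: float = 0.0
    foveal_dip_px: float = 0.0
    foveal_dip_sigma_mm: float = 0.75
    vitreous_intensity: float = 10.0
    retina_intensity: float = 180.0
    fluid_intensity: float = 10.0
    pockets: tuple[Ellipsoid, ...] = ()
    speckle_sigma: float = 0.0
    salt_pepper_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vitreous_intensity", "retina_intensity", "fluid_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be in [0, 255], got {v}")
        if not self.fluid_intensity < self.retina_intensity:
            raise ValueError("fluid_intensity must be darker than retina_intensity")
        if not 0 < self.ilm_row < self.rpe_row < self.n_rows:
            raise ValueError("need 0 < ilm_row < rpe_row < n_rows")
        object.__setattr__(self, "pockets", tuple(self.pockets))
        self._validate_pockets()

    @property
    def n_cols(self) -> int:
        g = self.geometry
        return int(round(g.width_mm / g.lateral_mm_per_px))

    def boundary_rows(self):
        """(ilm, rpe) row positions per column for one B-scan."""
        g = self.geometry
        x_mm = (np.arange(self.n_cols) + 0.5) * g.lateral_mm_per_px
        frac = x_mm / g.width_mm
        ilm = self.ilm_row + self.tilt_px * frac
        rpe = self.rpe_row + self.tilt_px * frac
        if self.foveal_dip_px:
            cx = g.width_mm / 2.0
            ilm = ilm + self.foveal_dip_px * np.exp(
                -((x_mm - cx) ** 2) / (2.0 * self.foveal_dip_sigma_mm**2)
            )
        return ilm, rpe

    def _validate_pockets(self) -> None:
        g = self.geometry
        ax_mm = g.axial_mm_per_px
        for p in self.pockets:
            (x0, x1), (y0, y1), (z0, z1) = p.bbox()
            if x0 < 0 or x1 > g.width_mm or y0 < 0 or y1 > g.depth_mm:
                raise ValueError(f"pocket {p} extends beyond the en-face scan area")
            # axial containment checked at the pocket centre column
            ilm, rpe = self.boundary_rows()
            col = min(int(p.center_x_mm / g.lateral_mm_per_px), self.n_cols - 1)
            if z0 <= ilm[col] * ax_mm or z1 >= rpe[col] * ax_mm:
                raise ValueError(
                    f"pocket {p} is not strictly inside the retinal band "
                    f"({ilm[col] * ax_mm:.3f}-{rpe[col] * ax_mm:.3f} mm axially)"
                )
        # conservative non-overlap check: bounding boxes must be disjoint
        for i, p in enumerate(self.pockets):
            for q in self.pockets[i + 1 :]:
                if all(
                    lo1 < hi2 and lo2 < hi1
                    for (lo1, hi1), (lo2, hi2) in zip(p.bbox(), q.bbox())
                ):
                    raise ValueError(f"pockets overlap (bounding boxes): {p} / {q}")


@dataclass
class GroundTruth:
    """Noise-free truth for a phantom: per-scan masks, analytic slice areas
    and the exact total ellipsoid volume."""

    fluid_masks: np.ndarray
    analytic_areas_mm2: np.ndarray
    analytic_volume_mm3: float
    boundary_rows: tuple[np.ndarray, np.ndarray]


def generate_phantom(spec: PhantomSpec) -> tuple[BScanStack, GroundTruth]:
    """Rasterise a phantom spec into a B-scan stack plus its ground truth.

    Deterministic for a fixed ``spec.seed``; speckle is multiplicative
    Gaussian ``(1 + sigma * n)`` applied before the salt-and-pepper
    impulses; ground truth is computed before any noise.
    """
    g = spec.geometry
    rng = np.random.default_rng(spec.seed)
    h, w = spec.n_rows, spec.n_cols
    ilm, rpe = spec.boundary_rows()
    rows = np.arange(h)[:, None]
    retina = (rows >= ilm[None, :]) & (rows <= rpe[None, :])
    base = np.where(retina, spec.retina_intensity, spec.vitreous_intensity)

    x_mm = (np.arange(w) + 0.5) * g.lateral_mm_per_px
    z_mm = (np.arange(h) + 0.5) * g.axial_mm_per_px
    positions = g.bscan_positions_mm()

    images = np.empty((g.n_bscans, h, w), dtype=np.uint8)
    masks = np.zeros((g.n_bscans, h, w), dtype=bool)
    areas = np.zeros(g.n_bscans)
    for i, y in enumerate(positions):
        img = base.copy()
        for p in spec.pockets:
            d = y - p.center_y_mm
            if abs(d) >= p.b_mm:
                continue
            scale = np.sqrt(1.0 - (d / p.b_mm) ** 2)
            ax, cz = p.a_mm * scale, p.c_mm * scale
            ell = ((x_mm[None, :] - p.center_x_mm) / ax) ** 2 + (
                (z_mm[:, None] - p.center_z_mm) / cz
            ) ** 2 <= 1.0
            img = np.where(ell, spec.fluid_intensity, img)
            masks[i] |= ell
            areas[i] += p.slice_area_mm2(y)
        if spec.speckle_sigma > 0:
            img = img * (1.0 + spec.speckle_sigma * rng.standard_normal(img.shape))
        if spec.salt_pepper_fraction > 0:
            n_imp = int(round(spec.salt_pepper_fraction * img.size))
            if n_imp:
                flat = rng.choice(img.size, size=n_imp, replace=False)
                vals = np.where(rng.random(n_imp) < 0.5, 0.0, 255.0)
                img = img.astype(float)
                img.ravel()[flat] = vals
        images[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    gt = GroundTruth(
        fluid_masks=masks,
        analytic_areas_mm2=areas,
        analytic_volume_mm3=float(sum(p.volume_mm3 for p in spec.pockets)),
        boundary_rows=(ilm, rpe),
    )
    return BScanStack(images, g, eye_id=f"phantom-{spec.seed}"), gt


# ---------------------------------------------------------------------------
# synthetic cohorts

# Per-response-group edema-volume medians (mm^3) and CDVA medians (logMAR) of
# a treated DR cohort; EV is log-normal around the stated median.
DEFAULT_GROUP_EFFECTS: dict[str, dict[str, float]] = {
    "responder": {"n": 60, "ev_median": 3.65, "ev_sigma_log": 0.5, "cdva_median": 0.30},
    "non-responder": {"n": 63, "ev_median": 3.93, "ev_sigma_log": 0.5, "cdva_median": 0.48},
    "recurrent": {"n": 26, "ev_median": 4.675, "ev_sigma_log": 0.5, "cdva_median": 0.60},
    "treatment-naive": {"n": 29, "ev_median": 1.604, "ev_sigma_log": 0.5, "cdva_median": 0.477},
}

# feature = intercept + slope * EV + N(0, noise_sd); the intercepts are the
# zero-edema feature levels, the slope/noise pairs set moderate (CFT, CFV)
# and stronger (TRV) correlations with EV.
DEFAULT_FEATURE_COUPLING: dict[str, tuple[float, float, float]] = {
    "cft_um": (386.06, 12.5, 69.0),
    "cfv_mm3": (0.30, 0.012, 0.064),
    "trv_mm3": (9.06, 0.45, 1.26),
}

# eyes without detectable fluid: EV = 0, features at their no-edema levels
NO_EDEMA_EFFECTS: dict[str, float] = {
    "n": 19,
    "cft_um": 395.0,
    "cft_sd": 40.0,
    "cfv_mm3": 0.31,
    "cfv_sd": 0.03,
    "trv_mm3": 10.1,
    "trv_sd": 1.0,
    "cdva_median": 0.3,
}

_GRADE_WEIGHTS = {"mild NPDR": 7, "moderate NPDR": 44, "severe NPDR": 53, "PDR": 74}


def _group_sizes(n_eyes: int | None, effects: dict[str, dict[str, float]]) -> dict[str, int]:
    base = {g: int(e["n"]) for g, e in effects.items()}
    if n_eyes is None:
        return base
    total = sum(base.values())
    exact = {g: n_eyes * n / total for g, n in base.items()}
    sizes = {g: int(np.floor(v)) for g, v in exact.items()}
    rem = n_eyes - sum(sizes.values())
    for g in sorted(exact, key=lambda g: exact[g] - sizes[g], reverse=True)[:rem]:
        sizes[g] += 1
    return sizes


def generate_cohort(
    n_eyes: int | None = None,
    group_effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    feature_coupling: dict[str, tuple[float, float, float]] | None = None,
    include_no_edema: bool = False,
) -> pd.DataFrame:
    """Draw a synthetic per-eye cohort table.

    Edema volumes are log-normal around each response group's median;
    CFT/CFV/TRV follow ``intercept + slope * EV + noise``; CDVA is normal
    around the group median.  ``n_eyes`` rescales the default group sizes
    proportionally; ``include_no_edema`` appends a zero-EV arm.
    """
    effects = group_effects or DEFAULT_GROUP_EFFECTS
    coupling = feature_coupling or DEFAULT_FEATURE_COUPLING
    for g, e in effects.items():
        if e.get("ev_median", 0) < 0 or e.get("ev_sigma_log", 0) < 0 or e.get("n", 0) < 1:
            raise ValueError(f"invalid effect spec for group {g!r}: {e}")
    rng = np.random.default_rng(seed)
    sizes = _group_sizes(n_eyes, effects)
    grades = list(_GRADE_WEIGHTS)
    gw = np.array(list(_GRADE_WEIGHTS.values()), float)
    gw /= gw.sum()

    rows = []
    eye = 0
    for group, e in effects.items():
        n = sizes[group]
        ev = np.exp(
            np.log(max(e["ev_median"], 1e-12))
            + e["ev_sigma_log"] * rng.standard_normal(n)
        )
        cdva = e["cdva_median"] + 0.2 * rng.standard_normal(n)
        feats = {
            name: icpt + slope * ev + sd * rng.standard_normal(n)
            for name, (icpt, slope, sd) in coupling.items()
        }
        grade = rng.choice(grades, size=n, p=gw)
        age = rng.integers(38, 80, size=n)
        for i in range(n):
            rows.append(
                {
                    "eye_id": f"eye{eye:04d}",
                    "dr_grade": grade[i],
                    "response_group": group,
                    "cdva_logmar": float(cdva[i]),
                    "ev_mm3": float(ev[i]),
                    "cft_um": float(feats["cft_um"][i]),
                    "cfv_mm3": float(max(feats["cfv_mm3"][i], 0.0)),
                    "trv_mm3": float(max(feats["trv_mm3"][i], 0.0)),
                    "age_years": int(age[i]),
                }
            )
            eye += 1
    if include_no_edema:
        ne = NO_EDEMA_EFFECTS
        n = int(ne["n"])
        grade = rng.choice(grades, size=n, p=gw)
        for i in range(n):
            rows.append(
                {
                    "eye_id": f"eye{eye:04d}",
                    "dr_grade": grade[i],
                    "response_group": "no-edema",
                    "cdva_logmar": float(ne["cdva_median"] + 0.2 * rng.standard_normal()),
                    "ev_mm3": 0.0,
                    "cft_um": float(ne["cft_um"] + ne["cft_sd"] * rng.standard_normal()),
                    "cfv_mm3": float(max(ne["cfv_mm3"] + ne["cfv_sd"] * rng.standard_normal(), 0.0)),
                    "trv_mm3": float(max(ne["trv_mm3"] + ne["trv_sd"] * rng.standard_normal(), 0.0)),
                    "age_years": int(rng.integers(38, 80)),
                }
            )
            eye += 1
    return pd.DataFrame(rows)
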