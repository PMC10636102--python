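"""Deterministic synthetic data: head phantoms and LMS-distributed cohorts.

The head phantom is an ellipsoidal "head" containing two shallow crescent
"temporalis" structures of known thickness placed laterally at a known
axial landmark slice.  The crescents are annulus sectors of a large-radius
circle: the sagitta of so shallow an arc is a fraction of a voxel, so the
convex-hull minimum Feret width of the truth mask equals the requested
thickness — and this is *verified* at build time against the angle-sweep
oracle rather than assumed.

Two z-coded wedge structures (disks whose radius grows/shrinks linearly
with distance from the landmark) plus a bright ridge at the landmark slice
make the axial position signal learnable by a slice-offset regressor from
maximum-intensity projections.

Cohorts for growth-chart fitting are sampled from known sex-specific
L/M/S age curves (Box-Cox normal), optionally in study blocks with additive
offsets for leave-one-study-out checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from itmt.imaging_io import BinaryMask, Volume3D
from itmt.morphometry import feret_angle_sweep, mask_corner_points


@dataclass
class PhantomSpec:
    """Construction parameters for one synthetic head volume.

    Thickness values are in mm and must be representable at the grid
    spacing; a fixed seed yields bit-identical output.
    """

    shape: tuple[int, int, int] = (128, 128, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    thickness_left_mm: float = 8.0
    thickness_right_mm: float = 12.0
    target_slice_index: int = 44
    intensity_background: float = 0.0
    intensity_brain: float = 100.0
    intensity_landmark: float = 135.0
    intensity_muscle: float = 160.0
    muscle_halflength_mm: float = 15.0
    muscle_halfheight_mm: float = 10.0
    noise_sigma: float = 0.0
    blur_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        if not (0 < self.target_slice_index < nz - 1):
            raise ValueError("target slice must be interior")
        for t in (self.thickness_left_mm, self.thickness_right_mm):
            if t <= 0:
                raise ValueError("thickness must be positive")
            if t < self.spacing[0]:
                raise ValueError(
                    f"thickness {t} mm not representable at spacing {self.spacing[0]} mm"
                )
            if t > 0.2 * nx * self.spacing[0]:
                raise ValueError("thickness too large relative to head")


def _crescent_mask_2d(
    shape_xy: tuple[int, int],
    inner_x_mm: float,
    thickness_mm: float,
    cy_mm: float,
    halflength_mm: float,
    spacing_xy: tuple[float, float],
    side: str,
    arc_radius_mm: float = 300.0,
) -> np.ndarray:
    """Rasterize one shallow crescent (annulus sector) on an axial slice.

    The circle centre sits ``arc_radius_mm`` medially from the inner muscle
    edge, so the arc bulges laterally with sagitta << 1 voxel.
    """
    nx, ny = shape_xy
    sx, sy = spacing_xy
    x = (np.arange(nx) + 0.5)[:, None] * sx  # pixel centres, mm
    y = (np.arange(ny) + 0.5)[None, :] * sy
    if side == "left":
        cx = inner_x_mm + arc_radius_mm
    else:
        cx = inner_x_mm - arc_radius_mm
    d = np.sqrt((x - cx) ** 2 + (y - cy_mm) ** 2)
    band = (d <= arc_radius_mm) & (d >= arc_radius_mm - thickness_mm)
    return band & (np.abs(y - cy_mm) <= halflength_mm)


def _build_crescent_with_verified_thickness(
    shape_xy, inner_x_mm, thickness_mm, cy_mm, halflength_mm, spacing_xy, side
) -> np.ndarray:
    """Phase-search the band placement until the rasterized min Feret width
    matches the requested thickness within half a voxel."""
    sx = spacing_xy[0]
    for phase in np.arange(0.0, 1.0, 0.1) * sx:
        mask = _crescent_mask_2d(
            shape_xy, inner_x_mm + phase, thickness_mm, cy_mm, halflength_mm, spacing_xy, side
        )
        if not mask.any():
            continue
        w_min, _ = feret_angle_sweep(mask_corner_points(mask, spacing_xy), step_deg=0.5)
        if abs(w_min - thickness_mm) <= 0.5 * sx:
            return mask
    raise ValueError(
        f"thickness {thickness_mm} mm unrepresentable at spacing {sx} mm "
        "(no rasterization phase verified within half a voxel)"
    )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[Volume3D, BinaryMask, BinaryMask, int]:
    """Build one head phantom; returns (volume, left truth, right truth, target index).

    Noise and blur are applied *after* the truth masks are extracted, so the
    ground truth is exact regardless of the corruption level.
    """
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    rng = np.random.default_rng(spec.seed)
    z0 = spec.target_slice_index

    vol = np.full(spec.shape, spec.intensity_background, dtype=np.float64)

    # head ellipsoid
    cx, cy, cz = (nx * sx / 2, ny * sy / 2, nz * sz / 2)
    x = (np.arange(nx) + 0.5)[:, None, None] * sx
    y = (np.arange(ny) + 0.5)[None, :, None] * sy
    z = (np.arange(nz) + 0.5)[None, None, :] * sz
    a, b, c = 0.42 * nx * sx, 0.46 * ny * sy, 0.44 * nz * sz
    head = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
    # smooth deterministic intra-brain modulation: real T1w tissue is
    # heterogeneous, not a single intensity spike
    texture = 1.0 + 0.125 * (
        np.sin(2.6 * np.pi * x / (nx * sx) + 0.7)
        + np.sin(3.4 * np.pi * y / (ny * sy) + 1.1)
    ) + 0.0 * z
    vol[head] = (spec.intensity_brain * texture)[head]

    # z-coded wedges: disk radius varies linearly with signed distance to z0
    zz = (np.arange(nz) + 0.5) * sz
    z0_mm = (z0 + 0.5) * sz
    for y_off, slope in ((+30.0, +0.3), (-30.0, -0.3)):
        radius = 6.0 + slope * (zz - z0_mm)  # mm, per-slice
        for k in range(nz):
            if radius[k] <= 0.5 or not head[:, :, k].any():
                continue
            disk = ((x[:, :, 0] - cx) ** 2 + (y[:, :, 0] - (cy + y_off)) ** 2) <= radius[k] ** 2
            vol[:, :, k][disk & head[:, :, k]] = spec.intensity_landmark

    # bright ridge marking the landmark level
    ridge = ((x[:, :, 0] - cx) / 14.0) ** 2 + ((y[:, :, 0] - cy) / 8.0) ** 2 <= 1.0
    for k in (z0 - 1, z0, z0 + 1):
        vol[:, :, k][ridge & head[:, :, k]] = spec.intensity_landmark + 15.0

    # bilateral shallow crescents, thickness verified at the target slice
    inner_left = cx - 0.36 * nx * sx
    inner_right = cx + 0.36 * nx * sx
    left2d = _build_crescent_with_verified_thickness(
        (nx, ny), inner_left, spec.thickness_left_mm, cy, spec.muscle_halflength_mm, (sx, sy), "left"
    )
    right2d = _build_crescent_with_verified_thickness(
        (nx, ny), inner_right, spec.thickness_right_mm, cy, spec.muscle_halflength_mm, (sx, sy), "right"
    )
    half_z = max(1, int(round(spec.muscle_halfheight_mm / sz)))
    left3d = np.zeros(spec.shape, dtype=bool)
    right3d = np.zeros(spec.shape, dtype=bool)
    for k in range(max(0, z0 - half_z), min(nz, z0 + half_z + 1)):
        left3d[:, :, k] = left2d
        right3d[:, :, k] = right2d
    vol[left3d] = spec.intensity_muscle
    vol[right3d] = spec.intensity_muscle

    # corruption after truth extraction
    if spec.blur_sigma > 0:
        vol = ndimage.gaussian_filter(vol, sigma=spec.blur_sigma)
    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)

    volume = Volume3D(data=vol, spacing=spec.spacing)
    return (
        volume,
        BinaryMask(left3d.astype(np.uint8), spacing=spec.spacing),
        BinaryMask(right3d.astype(np.uint8), spacing=spec.spacing),
        z0,
    )


# ---------------------------------------------------------------------------
# synthetic cohorts from known LMS curves


@dataclass
class LMSCurves:
    """True generating curves: Box-Cox power L(t), median M(t) [mm], CV S(t)."""

    L: Callable[[np.ndarray], np.ndarray]
    M: Callable[[np.ndarray], np.ndarray]
    S: Callable[[np.ndarray], np.ndarray]


def linear_lms(l0: float = 1.0, m0: float = 6.0, m_slope: float = 0.3, s0: float = 0.12) -> LMSCurves:
    """L constant, M linear in age, S constant — the canonical test curves."""
    return LMSCurves(
        L=lambda t: np.full_like(np.asarray(t, dtype=float), l0),
        M=lambda t: m0 + m_slope * np.asarray(t, dtype=float),
        S=lambda t: np.full_like(np.asarray(t, dtype=float), s0),
    )


def default_true_curves() -> dict[str, LMSCurves]:
    """Per-sex generating curves for the synthetic study conditions.

    Males run slightly thicker with a steeper age slope, mirroring the
    qualitative sex difference in temporalis growth.
    """
    return {
        "M": linear_lms(1.0, 6.3, 0.32, 0.12),
        "F": linear_lms(1.0, 6.0, 0.28, 0.12),
    }


def sample_bccg(L, M, S, rng: np.random.Generator) -> np.ndarray:
    """Draw y ~ BCCG(L, M, S): y = M (1 + L S z)^(1/L), z standard normal."""
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    z = rng.standard_normal(np.broadcast_shapes(L.shape, M.shape, S.shape))
    out = np.empty_like(z)
    small = np.abs(L) < 1e-8
    out[small] = (M * np.exp(S * z))[small] if small.any() else 0.0
    base = 1.0 + L * S * z
    # redraw the (negligible) mass outside the Box-Cox support
    bad = (~small) & (base <= 0)
    while bad.any():
        z[bad] = rng.standard_normal(bad.sum())
        base = 1.0 + L * S * z
        bad = (~small) & (base <= 0)
    ns = ~small
    out[ns] = (M * base ** (1.0 / np.where(small, 1.0, L)))[ns]
    return out


def generate_cohort(
    n: int,
    sex_ratio: float = 0.5,
    age_range: tuple[float, float] = (4.0, 30.0),
    true_lms: dict[str, LMSCurves] | None = None,
    seed: int = 0,
    n_studies: int = 1,
    study_offsets_mm: list[float] | None = None,
) -> pd.DataFrame:
    """Sample a cohort table (subject_id, study_id, age_years, sex, tmt_mm).

    Ages are uniform on ``age_range``; sex is 'M' with probability
    ``sex_ratio``; TMT is drawn from the per-sex BCCG curves.  Study blocks
    (with optional additive mm offsets on M) support leave-one-study-out
    robustness checks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    curves = true_lms if true_lms is not None else default_true_curves()
    for sex, cv in curves.items():
        m = cv.M(np.linspace(*age_range, 10))
        s = cv.S(np.linspace(*age_range, 10))
        if np.any(m <= 0) or np.any(s <= 0):
            raise ValueError(f"invalid curves for sex {sex}: M and S must stay positive")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    sexes = np.where(rng.uniform(size=n) < sex_ratio, "M", "F")
    studies = rng.integers(0, n_studies, size=n)
    offsets = np.zeros(n_studies) if study_offsets_mm is None else np.asarray(study_offsets_mm, float)
    if offsets.size != n_studies:
        raise ValueError("study_offsets_mm length must equal n_studies")
    tmt = np.empty(n)
    for sex in ("M", "F"):
        idx = sexes == sex
        if not idx.any():
            continue
        cv = curves[sex]
        tmt[idx] = sample_bccg(
            cv.L(ages[idx]), cv.M(ages[idx]) + offsets[studies[idx]], cv.S(ages[idx]), rng
        )
    return pd.DataFrame(
        {
            "subject_id": [f"subj{i:05d}" for i in range(n)],
            "study_id": [f"study{j}" for j in studies],
            "age_years": ages,
            "sex": sexes,
            "tmt_mm": tmt,
        }
    )
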