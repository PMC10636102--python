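"""NIfTI volume I/O and the deterministic T1w preprocessing chain.

All volumes are carried in canonical RAS orientation with voxel spacing in
mm.  The preprocessing chain applied before both downstream models is:

    resample to isotropic -> median filter -> Otsu foreground ->
    z-score over foreground -> robust percentile rescale to [0, 1]

Each stage is exposed on its own so it can be tested against an independent
oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)


@dataclass
class Volume3D:
    """A 3D scalar image with mm spacing, canonically RAS-oriented.

    ``data`` is indexed (x, y, z) in RAS voxel order; ``spacing`` gives mm
    per voxel along each axis; ``affine`` (optional) maps voxel indices to
    world mm coordinates.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = "RAS"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires 3D data, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "Volume3D":
        return replace(self, data=data)


@dataclass
class BinaryMask:
    """A {0,1} mask on the same grid as its parent volume (2D or 3D)."""

    data: np.ndarray
    spacing: tuple[float, ...] = field(default=(1.0, 1.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.data = self.data.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("mask spacing must be positive")

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


def load_volume(path) -> Volume3D:
    """Load a NIfTI-1/2 file and return it reoriented to canonical RAS.

    Raises ``ValueError`` for non-3D images (e.g. 4D fMRI) and for data
    containing NaN/inf.
    """
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(
        data=np.ascontiguousarray(data, dtype=np.float64),
        spacing=spacing,
        orientation="RAS",
        affine=np.array(img.affine),
    )


def save_volume(vol: Volume3D, path) -> None:
    """Write a volume as NIfTI; spacing is stored in the affine diagonal."""
    if vol.affine is not None:
        affine = vol.affine
    else:
        affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def resample_isotropic(vol: Volume3D, target_mm: float = 1.0) -> Volume3D:
    """Resample to an isotropic grid by trilinear interpolation.

    Output dimensions are ``round(dim * spacing / target_mm)`` per axis.
    Resampling at the input spacing is an identity up to float error.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if any(d < 2 for d in vol.shape):
        raise ValueError(f"degenerate volume dims {vol.shape}; need >=2 voxels per axis")
    out_shape = tuple(
        max(2, int(round(d * s / target_mm))) for d, s in zip(vol.shape, vol.spacing)
    )
    if out_shape == vol.shape and all(abs(s - target_mm) < 1e-12 for s in vol.spacing):
        return replace(vol, spacing=(target_mm,) * 3)
    zoom = [o / i for o, i in zip(out_shape, vol.shape)]
    data = ndimage.zoom(vol.data.astype(np.float64), zoom, order=1, mode="nearest", grid_mode=True)
    # grid_mode=True treats voxels as cells so the physical field-of-view is kept
    assert data.shape == out_shape
    affine = None
    if vol.affine is not None:
        scale = np.diag([target_mm / s for s in vol.spacing] + [1.0])
        affine = vol.affine @ scale
    return Volume3D(data=data, spacing=(target_mm,) * 3, orientation=vol.orientation, affine=affine)


def zscore_normalize(vol: Volume3D, mask: BinaryMask | None = None) -> Volume3D:
    """Standardize intensities to mean 0 / std 1 over ``mask`` (or everywhere).

    The same affine map is applied to voxels outside the mask.
    """
    region = vol.data[mask.data] if mask is not None else vol.data
    if mask is not None and region.size < 2:
        raise ValueError("mask must contain at least 2 foreground voxels")
    mu = float(np.mean(region))
    sd = float(np.std(region))
    if sd == 0.0:
        raise ValueError("constant image: zero variance over normalization region")
    return vol.with_data((vol.data - mu) / sd)


def median_filter3d(vol: Volume3D, radius_vox: int = 1) -> Volume3D:
    """Median filter with a cubic (2r+1)^3 window and nearest-border padding."""
    if radius_vox < 1:
        raise ValueError("radius_vox must be >= 1")
    size = 2 * int(radius_vox) + 1
    return vol.with_data(ndimage.median_filter(vol.data, size=size, mode="nearest"))


def otsu_threshold(vol: Volume3D, nbins: int = 256) -> tuple[float, BinaryMask]:
    """Otsu's threshold maximizing inter-class variance over histogram bins.

    Candidate cuts are the interior bin edges of an ``nbins`` histogram over
    the intensity range; ties break toward the lower threshold.  Foreground
    is ``data > threshold``.
    """
    data = np.sort(vol.data.ravel().astype(np.float64))
    lo, hi = float(data[0]), float(data[-1])
    if lo == hi:
        raise ValueError("constant image: Otsu threshold undefined")
    edges = np.linspace(lo, hi, nbins + 1)
    cuts = edges[1:-1]                               # interior bin edges as candidates
    csum = np.concatenate(([0.0], np.cumsum(data)))
    n0 = np.searchsorted(data, cuts, side="right")   # class 0: data <= cut
    n1 = data.size - n0
    valid = (n0 > 0) & (n1 > 0)
    between = np.full(cuts.size, -np.inf)
    m0 = csum[n0[valid]] / n0[valid]
    m1 = (csum[-1] - csum[n0[valid]]) / n1[valid]
    between[valid] = n0[valid] * n1[valid] * (m0 - m1) ** 2
    j = int(np.argmax(between))                      # first max -> lower threshold on ties
    threshold = float(cuts[j])
    fg = BinaryMask((vol.data > threshold).astype(np.uint8), spacing=vol.spacing)
    return threshold, fg


def rescale_intensity(
    vol: Volume3D,
    p_lo: float = 0.5,
    p_hi: float = 99.5,
    mask: BinaryMask | None = None,
) -> Volume3D:
    """Robust linear rescale: the p_lo/p_hi percentiles map to 0/1, clipped.

    Percentiles are computed over ``mask`` (typically the Otsu foreground)
    when given, otherwise over the whole volume.
    """
    if not p_lo < p_hi:
        raise ValueError("require p_lo < p_hi")
    region = vol.data[mask.data] if mask is not None else vol.data
    lo, hi = np.percentile(region, [p_lo, p_hi])
    if hi == lo:
        raise ValueError("degenerate percentiles: p_lo and p_hi values coincide")
    return vol.with_data(np.clip((vol.data - lo) / (hi - lo), 0.0, 1.0))


def preprocess(
    vol: Volume3D,
    target_mm: float = 1.0,
    median_radius: int = 1,
    nbins: int = 256,
    p_lo: float = 0.5,
    p_hi: float = 99.5,
) -> Volume3D:
    """Full preprocessing chain applied before slice selection / segmentation.

    Order: isotropic resample, median filter, Otsu foreground extraction,
    z-score over the foreground (background would bias the statistics),
    percentile rescale to [0, 1].
    """
    v = resample_isotropic(vol, target_mm)
    log.info("preprocess: resampled %s -> %s at %.3g mm", vol.shape, v.shape, target_mm)
    v = median_filter3d(v, median_radius)
    log.info("preprocess: median filtered (r=%d)", median_radius)
    thr, fg = otsu_threshold(v, nbins=nbins)
    log.info("preprocess: Otsu threshold %.4g, foreground %d voxels", thr, fg.n_foreground)
    v = zscore_normalize(v, mask=fg)
    # rescale anchors use whole-volume percentiles: anchoring on foreground
    # percentiles would pin the darkest tissue to the background value and
    # destroy the background/foreground gap, making the chain unstable under
    # re-application
    v = rescale_intensity(v, p_lo=p_lo, p_hi=p_hi, mask=None)
    log.info("preprocess: z-scored over foreground and rescaled to [0,1]")
    return v
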