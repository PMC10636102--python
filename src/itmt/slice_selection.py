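"""Axial slice selection at the superior orbital roof.

A regressor predicts, from a maximum-intensity-projection (MIP) slab
centred on a candidate slice, the signed mm offset of the landmark slice
from that candidate (label = target_z - candidate_z in world mm).  At
inference the candidate band is swept and each candidate implies a target
index; the rounded median of the implied targets is the prediction, which
tolerates up to half the candidates being wrong.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.neural_network import MLPRegressor

from itmt.imaging_io import Volume3D

log = logging.getLogger(__name__)


@dataclass
class MIPSlice:
    """One maximum-intensity-projection slab, resized to the model input."""

    image: np.ndarray
    center_index: int
    thickness_mm: float
    offset_label_mm: float | None = None  # target_z - candidate_z; training only

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")


@dataclass
class SlicePrediction:
    target_index: int
    per_candidate: list[tuple[int, float]]  # (candidate index, predicted offset mm)
    dispersion_mm: float


def compute_mip(
    vol: Volume3D,
    center_index: int,
    thickness_mm: float = 5.0,
    input_size: int = 256,
) -> MIPSlice:
    """Pixelwise maximum over an axial slab of the given thickness, resized.

    The slab spans ``round(thickness_mm / spacing_z)`` slices (at least 1)
    centred on ``center_index`` and must lie inside the volume.
    """
    sz = vol.spacing[2]
    n_slices = max(1, int(round(thickness_mm / sz)))
    half_lo = (n_slices - 1) // 2
    half_hi = n_slices - 1 - half_lo
    lo, hi = center_index - half_lo, center_index + half_hi
    if lo < 0 or hi >= vol.shape[2]:
        raise ValueError(
            f"slab [{lo}, {hi}] around index {center_index} outside volume of depth {vol.shape[2]}"
        )
    mip = vol.data[:, :, lo : hi + 1].max(axis=2)
    if mip.shape != (input_size, input_size):
        mip = resize(mip, (input_size, input_size), order=1, preserve_range=True, anti_aliasing=False)
    return MIPSlice(image=mip.astype(np.float64), center_index=int(center_index), thickness_mm=float(thickness_mm))


def build_offset_dataset(
    vol: Volume3D,
    target_index: int,
    offsets_mm: list[float],
    thickness_mm: float = 5.0,
    input_size: int = 256,
    augment: int = 0,
    rng: np.random.Generator | None = None,
) -> list[MIPSlice]:
    """Labelled MIP slices at candidate positions displaced from the target.

    Each offset o places a candidate at ``target + o/spacing_z`` voxels and
    labels it with target_z - candidate_z (so the label at the target itself
    is 0 and labels are antisymmetric about it).  ``augment`` adds that many
    jittered copies per slice (small rotations and in-plane shifts).
    """
    if len(offsets_mm) == 0:
        raise ValueError("offsets_mm must be non-empty")
    sz = vol.spacing[2]
    out: list[MIPSlice] = []
    rng = rng if rng is not None else np.random.default_rng(0)
    for off in offsets_mm:
        cand = int(round(target_index + off / sz))
        mip = compute_mip(vol, cand, thickness_mm, input_size)
        label = (target_index - cand) * sz
        mip.offset_label_mm = float(label)
        out.append(mip)
        for _ in range(augment):
            img = _augment_image(mip.image, rng)
            out.append(
                MIPSlice(image=img, center_index=cand, thickness_mm=thickness_mm, offset_label_mm=float(label))
            )
    return out


def _augment_image(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Training-time jitter: up to 10-degree rotation and small shifts."""
    from scipy.ndimage import rotate, shift

    angle = rng.uniform(-10.0, 10.0)
    dy, dx = rng.uniform(-0.05, 0.05, size=2) * np.array(img.shape)
    out = rotate(img, angle, reshape=False, order=1, mode="nearest")
    return shift(out, (dy, dx), order=1, mode="nearest")


class SliceRegressor:
    """Contract for slice-offset regressors.

    ``fit`` consumes labelled MIP slices; ``predict_offset`` maps one MIP
    image to the signed mm offset of the landmark slice.  Predictions must
    be deterministic given a fixed trained state.
    """

    def fit(self, dataset: list[MIPSlice], **config):  # pragma: no cover - interface
        raise NotImplementedError

    def predict_offset(self, image: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class OracleSliceRegressor(SliceRegressor):
    """Test double that returns pre-computed offsets keyed by candidate index."""

    def __init__(self, offsets_by_index: dict[int, float]):
        self.offsets_by_index = dict(offsets_by_index)
        self._pending: list[int] = []

    def fit(self, dataset, **config):
        return self

    def predict_offset_at(self, index: int) -> float:
        return self.offsets_by_index[index]

    def predict_offset(self, image) -> float:  # pragma: no cover - index-keyed oracle
        raise RuntimeError("oracle is index-keyed; use predict_target_slice which passes indices")


class MLPSliceRegressor(SliceRegressor, BaseEstimator, RegressorMixin):
    """Reference slice-offset regressor: a small MLP on downsampled MIPs.

    Trained with the Adam optimizer on mean-squared-error loss.  MIP images
    are downsampled to ``feature_size`` squared and standardized before the
    dense layers; the loss curve is retained for training diagnostics.
    """

    def __init__(
        self,
        feature_size: int = 32,
        hidden: int = 64,
        epochs: int = 30,
        batch_size: int = 64,
        lr: float = 1e-3,
        seed: int = 0,
    ):
        self.feature_size = feature_size
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def _features(self, image: np.ndarray) -> np.ndarray:
        small = resize(
            np.asarray(image, dtype=np.float64),
            (self.feature_size, self.feature_size),
            order=1,
            preserve_range=True,
            anti_aliasing=False,
        )
        # per-image standardization: MRI intensities are in arbitrary units,
        # so only the spatial pattern should carry the offset signal
        small = (small - small.mean()) / (small.std() + 1e-8)
        return small.ravel()

    def fit(self, dataset: list[MIPSlice], **config):
        if len(dataset) == 0:
            raise ValueError("empty training dataset")
        X = np.stack([self._features(s.image) for s in dataset])
        y = np.array([s.offset_label_mm for s in dataset], dtype=float)
        if np.any([s.offset_label_mm is None for s in dataset]):
            raise ValueError("dataset contains unlabelled slices")
        self.x_mean_ = X.mean(axis=0)
        self.x_scale_ = X.std(axis=0) + 1e-8
        Xs = (X - self.x_mean_) / self.x_scale_
        self.net_ = MLPRegressor(
            hidden_layer_sizes=(self.hidden,),
            solver="adam",
            max_iter=self.epochs,
            batch_size=min(self.batch_size, len(dataset)),
            learning_rate_init=self.lr,
            random_state=self.seed,
            shuffle=True,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warning expected at few epochs
            self.net_.fit(Xs, y)
        self.loss_curve_ = list(self.net_.loss_curve_)
        if not np.all(np.isfinite(self.loss_curve_)):
            raise RuntimeError(f"divergent training loss: {self.loss_curve_[-5:]}")
        log.info("slice regressor: loss %.4g -> %.4g over %d epochs",
                 self.loss_curve_[0], self.loss_curve_[-1], len(self.loss_curve_))
        return self

    def predict_offset(self, image: np.ndarray) -> float:
        xs = (self._features(image) - self.x_mean_) / self.x_scale_
        return float(self.net_.predict(xs[None, :])[0])

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, str(path))

    @staticmethod
    def load(path) -> "MLPSliceRegressor":
        import joblib

        return joblib.load(str(path))


def predict_target_slice(
    vol: Volume3D,
    model: SliceRegressor,
    search_band: range | None = None,
    stride: int = 1,
    thickness_mm: float = 5.0,
    input_size: int = 256,
    dispersion_warn_mm: float = 4.0,
) -> SlicePrediction:
    """Sweep the candidate band; each candidate implies a target index.

    implied target = candidate + predicted_offset / spacing_z; the final
    index is the rounded median of implied targets, with a robust spread
    (scaled MAD, mm) reported and a warning logged beyond the craniocaudal
    tolerance.
    """
    nz = vol.shape[2]
    sz = vol.spacing[2]
    if search_band is None:
        search_band = range(nz // 3, 2 * nz // 3)  # central third
    candidates = list(search_band)[::stride]
    if len(candidates) == 0:
        raise ValueError("empty search band")
    per_candidate: list[tuple[int, float]] = []
    implied: list[float] = []
    for i in candidates:
        if isinstance(model, OracleSliceRegressor):
            off = model.predict_offset_at(i)
        else:
            mip = compute_mip(vol, i, thickness_mm, input_size)
            off = model.predict_offset(mip.image)
        per_candidate.append((i, float(off)))
        implied.append(i + off / sz)
    implied_arr = np.asarray(implied)
    med = float(np.median(implied_arr))
    dispersion = float(1.4826 * np.median(np.abs(implied_arr - med)) * sz)
    target = int(np.clip(round(med), 0, nz - 1))
    if dispersion > dispersion_warn_mm:
        log.warning(
            "slice selection dispersion %.2f mm exceeds %.1f mm tolerance", dispersion, dispersion_warn_mm
        )
    return SlicePrediction(target_index=target, per_candidate=per_candidate, dispersion_mm=dispersion)


def slice_mae(pred_indices, true_indices, spacing_z: float) -> float:
    """Median absolute slice-localization error in mm."""
    pred = np.asarray(pred_indices, dtype=float)
    true = np.asarray(true_indices, dtype=float)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("need equal-length non-empty index lists")
    return float(np.median(np.abs(pred - true)) * spacing_z)
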