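"""Convenience routines to train the reference (toy) models on phantoms."""

from __future__ import annotations

import logging

import numpy as np

from itmt.config import PipelineConfig
from itmt.imaging_io import preprocess
from itmt.phantom import PhantomSpec, generate_phantom
from itmt.segmentation import FilterBankSegmenter, fit_toy_segmenter
from itmt.slice_selection import MLPSliceRegressor, build_offset_dataset

log = logging.getLogger(__name__)


def make_training_phantoms(n: int, seed: int = 0, noise_sigma: float | None = None):
    """Preprocessed phantoms with truth, varied in thickness, landmark level
    and (by default) noise level, emulating heterogeneous scan quality."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = PhantomSpec(
            thickness_left_mm=float(rng.uniform(6.0, 14.0)),
            thickness_right_mm=float(rng.uniform(6.0, 14.0)),
            target_slice_index=int(rng.integers(40, 52)),
            noise_sigma=float(rng.uniform(0.0, 3.0)) if noise_sigma is None else noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, left, right, z0 = generate_phantom(spec)
        out.append((preprocess(vol), left, right, z0))
    return out


def train_toy_models(
    n_phantoms: int = 4,
    seed: int = 0,
    config: PipelineConfig | None = None,
    offsets_mm=None,
    augment: int = 0,
) -> tuple[MLPSliceRegressor, FilterBankSegmenter]:
    """Train the slice regressor and the segmenter on synthetic phantoms."""
    cfg = config or PipelineConfig()
    phantoms = make_training_phantoms(n_phantoms, seed=seed)
    if offsets_mm is None:
        offsets_mm = list(np.arange(-18.0, 18.5, 1.0))
    rng = np.random.default_rng(seed + 1)

    dataset = []
    for volp, _, _, z0 in phantoms:
        dataset.extend(
            build_offset_dataset(
                volp,
                z0,
                offsets_mm,
                thickness_mm=cfg.slice_selection.thickness_mm,
                input_size=cfg.slice_selection.input_size,
                augment=augment,
                rng=rng,
            )
        )
    ss = cfg.slice_selection
    regressor = MLPSliceRegressor(
        epochs=ss.epochs, batch_size=ss.batch_size, lr=ss.lr, seed=ss.seed
    ).fit(dataset)

    slices, masks = [], []
    for volp, left, right, z0 in phantoms:
        for dz in (-2, 0, 2):
            k = z0 + dz
            slices.append(volp.data[:, :, k])
            masks.append((left.data[:, :, k] | right.data[:, :, k]).astype(np.uint8))
    seg = FilterBankSegmenter(
        input_size=cfg.segmentation.input_size,
        epochs=cfg.segmentation_train.epochs,
        lr=cfg.segmentation_train.lr,
        tversky=cfg.segmentation.tversky,
        seed=cfg.segmentation_train.seed,
    )
    fit_toy_segmenter(seg, slices, masks)
    log.info("toy models trained: regressor final MSE %.4g, segmenter Dice %.3f",
             regressor.loss_curve_[-1], seg.train_dice_)
    return regressor, seg
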