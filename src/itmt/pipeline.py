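"""End-to-end orchestration: preprocess -> slice -> segment -> measure -> centile."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from itmt.config import PipelineConfig
from itmt.growth_charts import CentileModel, value_to_centile
from itmt.imaging_io import Volume3D, load_volume, preprocess
from itmt.morphometry import measure_muscle_pair
from itmt.segmentation import Segmenter, segment_muscles
from itmt.slice_selection import SliceRegressor, predict_target_slice

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for failure records."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SubjectResult:
    subject_id: str
    slice_index: int
    slice_dispersion_mm: float
    measurement: dict
    centile: float | None
    warnings: list[str]
    provenance: dict
    timings_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "slice_index": self.slice_index,
            "slice_dispersion_mm": self.slice_dispersion_mm,
            "measurement": self.measurement,
            "centile": self.centile,
            "warnings": self.warnings,
            "provenance": self.provenance,
            "timings_s": self.timings_s,
        }

    def to_json(self, path=None) -> str:
        blob = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob


def _stage(name: str, fn, timings: dict):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:  # noqa: BLE001 - converted into a structured record
        raise StageError(name, exc) from exc
    timings[name] = round(time.perf_counter() - t0, 4)
    log.info("stage %-12s %.2fs", name, timings[name])
    return out


def run_measure(
    volume,
    slice_model: SliceRegressor,
    seg_model: Segmenter,
    config: PipelineConfig | None = None,
    subject_id: str = "subject",
    age: float | None = None,
    sex: str | None = None,
    chart: CentileModel | None = None,
    out_path=None,
) -> SubjectResult:
    """Measure one subject; ``volume`` is a path or a Volume3D.

    The centile is attached only when chart, age and sex are all supplied
    (and the chart's sex matches).  Stage failures raise ``StageError``.
    """
    cfg = config or PipelineConfig()
    timings: dict = {}
    warnings: list[str] = []

    if isinstance(volume, Volume3D):
        vol = volume
    else:
        vol = _stage("load", lambda: load_volume(volume), timings)

    pp = cfg.preprocess
    vol_p = _stage(
        "preprocess",
        lambda: preprocess(vol, pp.target_mm, pp.median_radius, pp.nbins, pp.p_lo, pp.p_hi),
        timings,
    )

    ss = cfg.slice_selection
    band = range(*ss.band) if ss.band is not None else None
    pred = _stage(
        "slice_selection",
        lambda: predict_target_slice(
            vol_p, slice_model, band, ss.stride, ss.thickness_mm, ss.input_size, ss.dispersion_warn_mm
        ),
        timings,
    )
    if pred.dispersion_mm > ss.dispersion_warn_mm:
        warnings.append(f"slice dispersion {pred.dispersion_mm:.2f} mm exceeds {ss.dispersion_warn_mm} mm")

    sides = _stage(
        "segmentation",
        lambda: segment_muscles(vol_p.data[:, :, pred.target_index], seg_model, cfg.segmentation),
        timings,
    )
    warnings.extend(sides.flags)

    meas = _stage(
        "morphometry",
        lambda: measure_muscle_pair(
            sides.left, sides.right, vol_p.spacing[:2], slice_index=pred.target_index
        ),
        timings,
    )

    centile = None
    if chart is not None and age is not None and sex is not None:
        if chart.sex != sex:
            raise StageError("centile", ValueError(f"chart sex {chart.sex} != subject sex {sex}"))
        centile = _stage(
            "centile", lambda: float(value_to_centile(chart, age, meas.tmt_mean_mm)), timings
        )

    result = SubjectResult(
        subject_id=subject_id,
        slice_index=pred.target_index,
        slice_dispersion_mm=pred.dispersion_mm,
        measurement=meas.to_dict(),
        centile=centile,
        warnings=warnings,
        provenance={"config_hash": cfg.hash(), "seed": cfg.seed, "itmt_version": _version()},
        timings_s=timings,
    )
    if out_path is not None:
        result.to_json(out_path)
    return result


def _version() -> str:
    from itmt import __version__

    return __version__


def run_batch(
    manifest: pd.DataFrame,
    slice_model: SliceRegressor,
    seg_model: Segmenter,
    config: PipelineConfig | None = None,
    chart_by_sex: dict[str, CentileModel] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the pipeline per manifest row; failures are isolated per row.

    Manifest columns: subject_id, path (or volume), optional study_id, age_years, sex.
    Returns (results table ready for chart fitting, failure records).
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    rows, failures = [], []
    for _, rec in manifest.iterrows():
        age = rec.get("age_years")
        sex = rec.get("sex")
        chart = (chart_by_sex or {}).get(sex) if sex is not None else None
        try:
            res = run_measure(
                rec.get("volume", rec.get("path")),
                slice_model,
                seg_model,
                config,
                subject_id=str(rec["subject_id"]),
                age=age,
                sex=sex,
                chart=chart,
            )
            rows.append(
                {
                    "subject_id": res.subject_id,
                    "study_id": rec.get("study_id", "study0"),
                    "age_years": age,
                    "sex": sex,
                    "tmt_mm": res.measurement["tmt_mean_mm"],
                    "csa_left_mm2": res.measurement["csa_left_mm2"],
                    "csa_right_mm2": res.measurement["csa_right_mm2"],
                    "slice_index": res.slice_index,
                    "centile": res.centile,
                    "n_warnings": len(res.warnings),
                }
            )
        except StageError as exc:
            failures.append({"subject_id": str(rec["subject_id"]), "stage": exc.stage, "error": str(exc.cause)})
            log.error("subject %s failed at %s: %s", rec["subject_id"], exc.stage, exc.cause)
    return pd.DataFrame(rows), failures
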