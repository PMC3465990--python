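"""End-to-end orchestration: per-pair grading pipeline and cohort runs.

``run_pair`` executes the stage chain on one registered FFA + color pair:
preprocessing, vessel segmentation, optic-disc localization, exudate
detection, FAZ segmentation, microaneurysm detection, feature assembly and
(optionally) grading.  ``run_cohort`` extracts features for a manifest of
pairs, trains the cascade and reports the repeated-split evaluation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .enhance import clahe, illumination_equalize
from .exudates import ExudateResult, detect_exudates
from .faz import FazResult, define_roi, segment_faz
from .features import (
    FEATURE_NAMES,
    CascadeModel,
    FeatureVector,
    extract_features,
    predict_grade,
    repeated_split_protocol,
    train_cascade,
)
from .microaneurysms import MaResult, detect_mas
from .optic_disc import OpticDisc, detect_od
from .vessels import build_filter_bank, segment_vessels

logger = logging.getLogger("curvegrade")

__all__ = ["GradeReport", "run_pair", "run_pair_arrays", "run_cohort", "load_image"]


def load_image(path, color: bool = False) -> np.ndarray:
    """Read an 8-bit PNG/TIFF/JPEG as floats in [0, 1]."""
    import imageio.v3 as iio

    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"image not found: {path}")
    arr = iio.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.max() > 1.0:
        arr = arr / 255.0
    if color:
        if arr.ndim == 2:
            raise ValueError(f"{path} is grayscale; expected RGB")
        return np.clip(arr[..., :3], 0.0, 1.0)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return np.clip(arr, 0.0, 1.0)


@dataclass
class GradeReport:
    """Per-pair results: stage summaries, features, optional grade."""

    od_center: Tuple[float, float]
    od_radius: float
    vessel_area: int
    faz_area: int
    faz_distance_variance: float
    ma_total: int
    ma_in_faz: int
    exudate_area: int
    features: FeatureVector
    predicted_grade: Optional[int]
    config_hash: str
    seed: int
    version: str = __version__
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    masks: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def to_json_dict(self) -> Dict:
        return {
            "od": {"center": list(self.od_center), "radius": self.od_radius,
                   "area": int(np.sum(self.masks["od"])) if "od" in self.masks else None},
            "vessel_area": self.vessel_area,
            "faz": {"area": self.faz_area, "distance_variance": self.faz_distance_variance},
            "microaneurysms": {"total": self.ma_total, "in_faz": self.ma_in_faz},
            "exudate_area": self.exudate_area,
            "features": dict(zip(FEATURE_NAMES, self.features.as_array().tolist())),
            "predicted_grade": self.predicted_grade,
            "provenance": {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "stage_seconds": self.stage_seconds,
            },
        }


def run_pair_arrays(
    ffa: np.ndarray,
    color: np.ndarray,
    config: PipelineConfig | None = None,
    model: CascadeModel | None = None,
) -> GradeReport:
    """Run the grading pipeline on in-memory images (registered pair)."""
    config = config or PipelineConfig()
    ffa = np.asarray(ffa, dtype=float)
    color = np.asarray(color, dtype=float)
    if color.ndim != 3 or color.shape[:2] != ffa.shape:
        raise ValueError("FFA and color image shapes differ (pair must be registered)")

    times: Dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, *a):
                times[name] = round(time.perf_counter() - self_.t0, 3)
                logger.info("stage %-14s %6.2fs", name, times[name])

        return _T()

    # Geometry stages (vessels, optic disc) run on the contrast-enhanced
    # image; photometric stages (FAZ darkness, lesion brightness) run on the
    # original-scale images — local histogram equalization would destroy the
    # absolute fluorescence cues their thresholds measure.
    ep = config.enhance.to_params()
    with timed("enhance"):
        ffa_p = illumination_equalize(clahe(ffa, ep), ep)

    with timed("vessels"):
        bank = build_filter_bank(
            config.vessels.sigma, config.vessels.length, config.vessels.step_deg
        )
        vessel_mask, exclusion_mask = segment_vessels(
            ffa_p, config.vessels.to_params(), bank, with_exclusion=True
        )

    with timed("optic_disc"):
        od = detect_od(ffa_p, vessel_mask, config.optic_disc.to_params())

    with timed("exudates"):
        ex = detect_exudates(color, od, config.exudates.to_params(), ep)

    with timed("faz"):
        roi = define_roi(
            od, ffa_p.shape, config.faz.macula_side, config.faz.to_params()
        )
        faz = segment_faz(vessel_mask, ffa, roi, config.faz.to_params())

    with timed("microaneurysms"):
        ma = detect_mas(ffa, exclusion_mask, faz, od, config.microaneurysms.to_params())

    fv = extract_features(ex, ma, vessel_mask, faz)
    grade = predict_grade(model, fv) if model is not None else None

    return GradeReport(
        od_center=od.center,
        od_radius=od.radius,
        vessel_area=int(vessel_mask.sum()),
        faz_area=faz.area,
        faz_distance_variance=faz.distance_variance,
        ma_total=ma.total_count,
        ma_in_faz=ma.count_in_faz,
        exudate_area=ex.total_area,
        features=fv,
        predicted_grade=grade,
        config_hash=config.hash(),
        seed=config.seed,
        stage_seconds=times,
        masks={"vessels": vessel_mask, "od": od.mask, "faz": faz.mask,
               "microaneurysms": ma.mask, "exudates": ex.mask},
    )


def run_pair(
    ffa_path,
    color_path,
    config: PipelineConfig | None = None,
    model: CascadeModel | None = None,
    out_dir=None,
) -> GradeReport:
    """Run the pipeline on an image pair from disk; optionally write the
    JSON report and mask overlays under ``out_dir``."""
    ffa = load_image(ffa_path, color=False)
    color = load_image(color_path, color=True)
    report = run_pair_arrays(ffa, color, config, model)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: GradeReport, out_dir) -> None:
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=2))
    for name, mask in report.masks.items():
        iio.imwrite(out / f"{name}.png", (mask.astype(np.uint8) * 255))


def run_cohort(
    manifest_csv,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> Dict:
    """Extract features for every pair in a manifest CSV (columns
    ffa, color, label), train the cascade, run the repeated-split protocol
    and return {features, labels, model, evaluation}."""
    config = config or PipelineConfig()
    manifest = pd.read_csv(manifest_csv)
    required = {"ffa", "color", "label"}
    if manifest.empty:
        raise ValueError("manifest is empty")
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    rows: List[np.ndarray] = []
    labels: List[int] = []
    for _, rec in manifest.iterrows():
        report = run_pair(rec["ffa"], rec["color"], config)
        rows.append(report.features.as_array())
        labels.append(int(rec["label"]))
    X = np.asarray(rows)
    y = np.asarray(labels)

    model = train_cascade(X, y, seed=config.seed, C=config.svm.C)
    evaluation = repeated_split_protocol(
        X, y,
        train_frac=config.svm.train_frac,
        n_repeats=config.svm.n_repeats,
        seed=config.seed,
        C=config.svm.C,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(X, columns=[f"F{i+1}" for i in range(6)])
        df["label"] = y
        df.to_csv(out / "features.csv", index=False)
        import joblib

        joblib.dump(model, out / "model.joblib")
        (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
    return {"features": X, "labels": y, "model": model, "evaluation": evaluation}
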