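"""End-to-end orchestration: cohort -> feature table -> cross-validated
classification, mirroring the full analysis chain on synthetic data."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import (
    ConfusionMatrix,
    CVResult,
    PipelineConfig,
    confusion,
    confusion_rates,
    patient_loocv,
    sens_spec,
    stratify,
)
from .dr_features import InversionConfig, extract_dr_features
from .preprocess import filter_eligibility, iqr_outlier_removal
from .synthetic import Cohort, PhantomLUT, default_lut
from .trf_features import FitConfig, extract_trf_features
from .types import FEATURE_COLUMNS

__all__ = ["extract_features", "run_classification", "ClassificationOutput"]

log = logging.getLogger(__name__)


def extract_features(cohort: Cohort, lut: PhantomLUT | None = None,
                     trf_cfg: FitConfig | None = None,
                     dr_cfg: InversionConfig | None = None,
                     progress: bool = False) -> pd.DataFrame:
    """Stream every region through both feature extractors.

    Measurements are simulated on the fly from the cohort's per-cell
    seeds, so memory stays flat regardless of cohort size.  Regions with
    flagged extractions keep their rows (NaN features + flag text).
    """
    lut = lut or default_lut()
    rows = []
    for i, (roi, trf, dr) in enumerate(cohort.iter_measurements()):
        if progress and i % 200 == 0:
            log.info("extracting features: region %d", i)
        tf = extract_trf_features(trf, trf_cfg)
        df_feat = extract_dr_features(dr, lut, dr_cfg)
        rows.append({
            "patient_id": roi.patient_id,
            "sample": roi.sample_kind,
            "row": roi.row,
            "col": roi.col,
            "p_tumor": roi.composition.p_tumor,
            "p_fibro": roi.composition.p_fibro,
            "p_adipose": roi.composition.p_adipose,
            "label": roi.composition.label,
            "single_observer": True,
            "i_collagen": tf.i_collagen,
            "i_fad": tf.i_fad,
            "tau_collagen": tf.tau_collagen,
            "tau_nadh": tf.tau_nadh,
            "tau_fad": tf.tau_fad,
            "dr_520": df_feat.dr_520,
            "dr_560": df_feat.dr_560,
            "mua_540": df_feat.mua_540,
            "mua_560": df_feat.mua_560,
            "mua_576": df_feat.mua_576,
            "mus_540": df_feat.mus_540,
            "mus_560": df_feat.mus_560,
            "mus_576": df_feat.mus_576,
            "flags": ";".join(tf.flags + df_feat.flags),
        })
    return pd.DataFrame(rows)


@dataclass
class ClassificationOutput:
    subset: str
    cv: CVResult
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    rates: dict[str, float]
    n_records: int


def run_classification(features: pd.DataFrame, subset: str = "total",
                       cfg: PipelineConfig | None = None,
                       apply_eligibility: bool = True,
                       apply_iqr: bool = True) -> ClassificationOutput:
    """Eligibility -> IQR screen -> subset stratification -> patient LOOCV.

    The IQR screen runs once on the eligible feature table (it defines
    the working dataset), before subsetting and cross-validation.
    """
    cfg = cfg or PipelineConfig()
    df = features
    finite = np.isfinite(df[FEATURE_COLUMNS].to_numpy(float)).all(axis=1)
    if (~finite).any():
        log.info("dropping %d records with flagged/non-finite features", int((~finite).sum()))
        df = df[finite]
    if apply_eligibility:
        df = filter_eligibility(df)
    if apply_iqr:
        df = iqr_outlier_removal(df)
    df = stratify(df, subset)
    cv = patient_loocv(df, cfg)
    cm = confusion(cv)
    sens, spec = sens_spec(cm)
    return ClassificationOutput(subset, cv, cm, sens, spec, confusion_rates(cm), len(df))
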