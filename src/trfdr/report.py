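"""Summary artifacts: composition accounting, posterior-vs-composition
records, and misclassification breakdowns.

Every function here is a pure function of its input table, so any
reported percentage can be recomputed from the emitted records alone.
Percentages are rounded half-up to integers (raw fractions are always
available alongside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CVResult
from .types import LABEL_TUMOR

__all__ = [
    "round_half_up",
    "CompositionSummary",
    "summarize_composition",
    "posterior_composition_records",
    "misclassification_breakdown",
]

_TISSUE_COLS = {"tumor": "p_tumor", "fibroglandular": "p_fibro", "adipose": "p_adipose"}


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _pct(count: int, total: int) -> int:
    return round_half_up(100.0 * count / total) if total else 0


@dataclass
class CompositionSummary:
    """Counts and dataset percentages mirroring the composition table.

    ``bands`` holds, per tissue, counts of regions containing that tissue
    stratified into low (0 < p < 25), medium (25 <= p < 75) and
    high (p >= 75) area percentage.
    """

    n_patients: int
    n_rois: int
    counts: dict[str, int]
    percents: dict[str, int]
    bands: dict[str, dict[str, int]]
    band_percents: dict[str, dict[str, int]]
    cooccurrence_percents: dict[str, int]


def summarize_composition(records: pd.DataFrame) -> CompositionSummary:
    """Full composition accounting for an eligible record set."""
    n = len(records)
    is_tumor = records["label"] == LABEL_TUMOR
    hom = records[["p_tumor", "p_fibro", "p_adipose"]].max(axis=1) == 100

    counts = {
        "tumor": int(is_tumor.sum()),
        "no_tumor": int((~is_tumor).sum()),
        "homogeneous": int(hom.sum()),
        "heterogeneous": int((~hom).sum()),
        "homogeneous_tumor": int((hom & (records["p_tumor"] == 100)).sum()),
        "homogeneous_fibroglandular": int((hom & (records["p_fibro"] == 100)).sum()),
        "homogeneous_adipose": int((hom & (records["p_adipose"] == 100)).sum()),
        "heterogeneous_tumor": int((~hom & is_tumor).sum()),
        "heterogeneous_no_tumor": int((~hom & ~is_tumor).sum()),
    }
    percents = {k: _pct(v, n) for k, v in counts.items()}

    bands = {}
    band_percents = {}
    for tissue, col in _TISSUE_COLS.items():
        p = records[col]
        bands[tissue] = {
            "low": int(((p > 0) & (p < 25)).sum()),
            "medium": int(((p >= 25) & (p < 75)).sum()),
            "high": int((p >= 75).sum()),
        }
        band_percents[tissue] = {k: _pct(v, n) for k, v in bands[tissue].items()}

    cooc = {
        "tumor_with_any_fibroglandular": _pct(
            int((is_tumor & (records["p_fibro"] > 0)).sum()), counts["tumor"]
        ),
        "tumor_with_any_adipose": _pct(
            int((is_tumor & (records["p_adipose"] > 0)).sum()), counts["tumor"]
        ),
        "no_tumor_with_any_fibroglandular": _pct(
            int((~is_tumor & (records["p_fibro"] > 0)).sum()), counts["no_tumor"]
        ),
        "no_tumor_with_any_adipose": _pct(
            int((~is_tumor & (records["p_adipose"] > 0)).sum()), counts["no_tumor"]
        ),
    }
    n_patients = records["patient_id"].nunique() if "patient_id" in records.columns else 0
    return CompositionSummary(n_patients, n, counts, percents, bands, band_percents, cooc)


def _band_tag(p: int) -> str:
    # quartile color bands used by the posterior/composition overlay
    if p < 25:
        return "0-25"
    if p < 50:
        return "25-50"
    if p < 75:
        return "50-75"
    return "75-100"


def posterior_composition_records(cv: CVResult) -> pd.DataFrame:
    """Held-out records ordered by increasing tumor-area percentage.

    Ties are broken by patient id and grid position for determinism.
    Each record carries quartile band tags for the three tissue
    percentages, the posterior, truth, and prediction.
    """
    df = cv.frame.copy()
    sort_cols = [c for c in ("p_tumor", "patient_id", "sample", "row", "col")
                 if c in df.columns]
    df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    for tissue, col in _TISSUE_COLS.items():
        df[f"band_{tissue}"] = df[col].map(_band_tag)
    df["correct"] = df["label"] == df["prediction"]
    return df


def misclassification_breakdown(cv: CVResult) -> pd.DataFrame:
    """Per-outcome composition-band fractions.

    For each outcome (tp, fn, fp, tn) and tissue, the fraction of those
    records whose tissue-area percentage is low (< 25, including 0),
    medium (25 to < 75) or high (>= 75).  Bands are exhaustive, so the
    three fractions sum to 1 within each (outcome, tissue) group.
    """
    df = cv.frame
    truth = df["label"] == LABEL_TUMOR
    pred = df["prediction"] == LABEL_TUMOR
    outcomes = {
        "tp": truth & pred,
        "fn": truth & ~pred,
        "fp": ~truth & pred,
        "tn": ~truth & ~pred,
    }
    rows = []
    for outcome, mask in outcomes.items():
        sub = df[mask]
        for tissue, col in _TISSUE_COLS.items():
            p = sub[col].to_numpy() if len(sub) else np.array([])
            total = len(sub)
            fractions = {
                "low": float((p < 25).mean()) if total else float("nan"),
                "medium": float(((p >= 25) & (p < 75)).mean()) if total else float("nan"),
                "high": float((p >= 75).mean()) if total else float("nan"),
            }
            for band, frac in fractions.items():
                rows.append({
                    "outcome": outcome,
                    "tissue": tissue,
                    "band": band,
                    "fraction": frac,
                    "n": total,
                })
    return pd.DataFrame(rows)
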