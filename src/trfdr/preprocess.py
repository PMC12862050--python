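"""Eligibility filtering, IQR outlier removal, log10 + standardization,
and PCA over the 13-feature table.

Records are rows of a pandas DataFrame with the composition/key columns
plus the 13 feature columns of :data:`trfdr.types.FEATURE_COLUMNS`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import FEATURE_COLUMNS

__all__ = [
    "filter_eligibility",
    "iqr_outlier_removal",
    "log10_standardize",
    "Standardization",
    "PCAModel",
    "fit_pca",
    "project",
    "cumulative_variance",
]

log = logging.getLogger(__name__)


def filter_eligibility(records: pd.DataFrame, *, return_counts: bool = False):
    """Apply the three inclusion rules, preserving row order.

    1. composition percentages sum to 100;
    2. single-observer annotation (column ``single_observer``; rows pass
       if the column is absent);
    3. the record's patient contributes both a tumor-labeled and a
       no-tumor-labeled region somewhere in their sample pair.

    Removal counts per rule are logged; pass ``return_counts=True`` to get
    them back as a dict alongside the filtered frame.
    """
    df = records
    counts = {}

    sums = df[["p_tumor", "p_fibro", "p_adipose"]].sum(axis=1)
    keep = sums == 100
    counts["composition_sum"] = int((~keep).sum())
    df = df[keep]

    if "single_observer" in df.columns:
        keep = df["single_observer"].astype(bool)
        counts["multi_observer"] = int((~keep).sum())
        df = df[keep]
    else:
        counts["multi_observer"] = 0

    labels_per_patient = df.groupby("patient_id")["label"].nunique()
    paired = set(labels_per_patient[labels_per_patient >= 2].index)
    keep = df["patient_id"].isin(paired)
    counts["unpaired_patient"] = int((~keep).sum())
    df = df[keep]

    for rule, n in counts.items():
        if n:
            log.info("eligibility: removed %d records (%s)", n, rule)
    if return_counts:
        return df, counts
    return df


def iqr_outlier_removal(records: pd.DataFrame, columns=None,
                        factor: float = 1.5) -> pd.DataFrame:
    """Single-pass per-feature IQR screen.

    Quartiles use linear interpolation between order statistics (numpy's
    default).  A record is removed if ANY feature falls outside
    ``[Q1 - factor*IQR, Q3 + factor*IQR]``.  Bounds are computed once on
    the input set (no re-iteration).
    """
    if len(records) < 4:
        raise ValueError("need at least 4 records for quartile estimation")
    columns = list(columns) if columns is not None else FEATURE_COLUMNS
    X = records[columns].to_numpy(float)
    q1 = np.quantile(X, 0.25, axis=0)
    q3 = np.quantile(X, 0.75, axis=0)
    iqr = q3 - q1
    lo = q1 - factor * iqr
    hi = q3 + factor * iqr
    keep = ((X >= lo) & (X <= hi)).all(axis=1)
    log.info("IQR screen removed %d of %d records", int((~keep).sum()), len(records))
    return records[keep]


@dataclass
class Standardization:
    """Per-feature log10 mean/sd fitted on a training set."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray


def log10_standardize(matrix, stats: Standardization | None = None,
                      columns=None) -> tuple[np.ndarray, Standardization]:
    """x -> (log10 x - mean) / sd per feature.

    When ``stats`` is None the statistics are fitted on the input (the
    training set) and returned for reuse on held-out rows.
    """
    if isinstance(matrix, pd.DataFrame):
        columns = list(columns) if columns is not None else [
            c for c in FEATURE_COLUMNS if c in matrix.columns
        ]
        X = matrix[columns].to_numpy(float)
    else:
        X = np.asarray(matrix, float)
        columns = list(columns) if columns is not None else [
            f"f{i}" for i in range(X.shape[1])
        ]
    if np.any(~np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if np.any(X <= 0):
        rows, cols = np.nonzero(X <= 0)
        raise ValueError(
            f"nonpositive feature for log10: record {rows[0]}, feature {columns[cols[0]]}"
        )
    L = np.log10(X)
    if stats is None:
        mean = L.mean(axis=0)
        sd = L.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [columns[i] for i in np.nonzero(sd == 0)[0]]
            raise ValueError(f"zero variance feature(s): {bad}")
        stats = Standardization(columns, mean, sd)
    return (L - stats.mean) / stats.sd, stats


@dataclass
class PCAModel:
    """Loadings (columns = components) and variance fractions from an
    eigendecomposition of the sample covariance of standardized data."""

    loadings: np.ndarray          # (n_features, n_features), orthonormal columns
    variance_fractions: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(X: np.ndarray) -> PCAModel:
    """PCA by covariance eigendecomposition.

    Components are ordered by decreasing variance; each loading column's
    sign is fixed so its largest-magnitude entry is positive, making
    loading tables reproducible across runs.
    """
    X = np.asarray(X, float)
    if np.any(~np.isfinite(X)):
        raise ValueError("non-finite input to PCA")
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least as many rows ({n}) as features ({p})")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(p):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return PCAModel(eigvecs, eigvals / eigvals.sum())


def project(X: np.ndarray, model: PCAModel, k: int) -> np.ndarray:
    """Scores on the first k components: X @ loadings[:, :k]."""
    if not 1 <= k <= model.n_components:
        raise ValueError(f"k={k} outside [1, {model.n_components}]")
    return np.asarray(X, float) @ model.loadings[:, :k]


def cumulative_variance(model: PCAModel, k: int) -> float:
    """Sum of the first k variance fractions."""
    if not 1 <= k <= model.n_components:
        raise ValueError(f"k={k} outside [1, {model.n_components}]")
    return float(model.variance_fractions[:k].sum())
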