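"""Weighted logistic regression with patient leave-one-out cross-validation.

The class weights follow w_class = 0.5 * n_samples / n_class, so that
n_tumor * w_tumor + n_no_tumor * w_no_tumor == n_samples exactly.  The
model itself is plain weighted logistic regression fitted by iteratively
reweighted least squares; no regularization except a tiny ridge fallback
on singular normal equations (always logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocess import fit_pca, iqr_outlier_removal, log10_standardize, project
from .types import FEATURE_COLUMNS, LABEL_NO_TUMOR, LABEL_TUMOR

__all__ = [
    "compute_class_weights",
    "ClassWeights",
    "LogisticConfig",
    "LogisticModel",
    "fit_weighted_logistic",
    "predict_posterior",
    "decide",
    "PipelineConfig",
    "CVResult",
    "patient_loocv",
    "stratify",
    "ConfusionMatrix",
    "confusion",
    "sens_spec",
    "confusion_rates",
    "threshold_sweep",
    "SUBSETS",
]

log = logging.getLogger(__name__)

SUBSETS = ("total", "heterogeneous_only", "low", "medium", "high")


def compute_class_weights(n_samples: int, n_class: int) -> float:
    """w_class = 0.5 * n_samples / n_class."""
    if n_class == 0:
        raise ValueError("class has no samples")
    if not 0 < n_class <= n_samples:
        raise ValueError("need 0 < n_class <= n_samples")
    return 0.5 * n_samples / n_class


@dataclass(frozen=True)
class ClassWeights:
    w_tumor: float
    w_no_tumor: float

    @classmethod
    def from_counts(cls, n_tumor: int, n_no_tumor: int) -> "ClassWeights":
        n = n_tumor + n_no_tumor
        return cls(compute_class_weights(n, n_tumor), compute_class_weights(n, n_no_tumor))

    def check_identity(self, n_tumor: int, n_no_tumor: int) -> bool:
        """n1*w1 + n0*w0 == n, verified in exact rational arithmetic."""
        n = n_tumor + n_no_tumor
        total = n_tumor * Fraction(n, 2 * n_tumor) + n_no_tumor * Fraction(n, 2 * n_no_tumor)
        return total == n


@dataclass
class LogisticConfig:
    tol: float = 1e-8
    max_iter: int = 100
    ridge: float = 1e-8           # applied only on singular normal equations
    max_coef_norm: float = 1e3    # separation guard


@dataclass
class LogisticModel:
    intercept: float
    coefficients: np.ndarray
    converged: bool
    n_iter: int
    grad_norm: float
    separation: bool = False
    ridge_used: bool = False


def _neg_loglik(beta, D, y, w):
    eta = D @ beta
    # log(1 + exp(-|eta|)) formulation avoids overflow
    return float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))


def fit_weighted_logistic(X: np.ndarray, y: np.ndarray, sample_weight=None,
                          cfg: LogisticConfig | None = None) -> LogisticModel:
    """Maximize the weighted log-likelihood by IRLS with step halving.

    Perfect separation is detected when the coefficient norm exceeds
    ``max_coef_norm``; the fit stops there with the norm capped and the
    model flagged rather than diverging.
    """
    cfg = cfg or LogisticConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.any(~np.isfinite(X)):
        raise ValueError("non-finite design matrix")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)

    D = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(D.shape[1])
    ridge_used = False
    separation = False
    nll = _neg_loglik(beta, D, y, w)
    it = 0
    grad_norm = np.inf
    for it in range(1, cfg.max_iter + 1):
        p = expit(D @ beta)
        grad = D.T @ (w * (y - p))
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm <= cfg.tol:
            break
        W = np.clip(w * p * (1.0 - p), 1e-12, None)
        H = (D * W[:, None]).T @ D
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            ridge_used = True
            log.warning("singular normal equations; adding ridge %g", cfg.ridge)
            step = np.linalg.solve(H + cfg.ridge * np.eye(H.shape[0]), grad)
        # damped Newton: halve until the objective does not increase
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            cand_nll = _neg_loglik(cand, D, y, w)
            if cand_nll <= nll + 1e-14:
                break
            t *= 0.5
        beta = beta + t * step
        nll = _neg_loglik(beta, D, y, w)
        norm = float(np.linalg.norm(beta))
        if norm > cfg.max_coef_norm:
            separation = True
            beta *= cfg.max_coef_norm / norm
            log.warning("apparent separation: coefficient norm capped at %g",
                        cfg.max_coef_norm)
            break
    p = expit(D @ beta)
    grad_norm = float(np.max(np.abs(D.T @ (w * (y - p)))))
    converged = grad_norm <= cfg.tol and not separation
    return LogisticModel(float(beta[0]), beta[1:].copy(), converged, it,
                         grad_norm, separation, ridge_used)


def predict_posterior(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    """Posterior tumor probability for each row."""
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != model.coefficients.size:
        raise ValueError(
            f"expected {model.coefficients.size} features, got shape {X.shape}"
        )
    return expit(model.intercept + X @ model.coefficients)


def decide(p, threshold: float = 0.5, tie_is_tumor: bool = True):
    """Tumor iff p >= threshold (tie predicts tumor by default)."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("posterior probabilities must be in [0, 1]")
    pred = (p >= threshold) if tie_is_tumor else (p > threshold)
    out = np.where(pred, LABEL_TUMOR, LABEL_NO_TUMOR)
    return out if out.ndim else str(out)


@dataclass
class PipelineConfig:
    """Per-fold preprocessing + model settings for cross-validation."""

    n_pcs: int = 4
    leakage_mode: str = "fold"    # "fold": fit stats/PCA on training fold; "global"
    weight_mode: str = "fold"     # "fold": Eq.-1 weights on training fold; "global"
    threshold: float = 0.5
    tie_is_tumor: bool = True
    apply_iqr: bool = False       # IQR screen is normally applied before CV
    logistic: LogisticConfig = field(default_factory=LogisticConfig)


@dataclass
class CVResult:
    """Concatenated held-out predictions plus per-fold metadata."""

    frame: pd.DataFrame           # posterior, prediction, label, composition, keys
    folds: list[dict]


def _prepare_xy(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    y = (df["label"] == LABEL_TUMOR).to_numpy(float)
    return df[FEATURE_COLUMNS], y


def patient_loocv(dataset: pd.DataFrame, cfg: PipelineConfig | None = None) -> CVResult:
    """Leave one patient out; fit preprocessing + weights + model on the
    rest; predict the held-out patient's regions.

    Folds whose training data contain a single class are skipped with an
    error record in the fold metadata.
    """
    cfg = cfg or PipelineConfig()
    patients = list(dict.fromkeys(dataset["patient_id"]))
    if len(patients) < 2:
        raise ValueError("need at least 2 patients for LOOCV")
    if cfg.apply_iqr:
        dataset = iqr_outlier_removal(dataset)

    global_stats = global_pca = None
    if cfg.leakage_mode == "global":
        Xs, global_stats = log10_standardize(dataset[FEATURE_COLUMNS])
        global_pca = fit_pca(Xs)
    elif cfg.leakage_mode != "fold":
        raise ValueError(f"unknown leakage mode {cfg.leakage_mode!r}")

    if cfg.weight_mode == "global":
        n1 = int((dataset["label"] == LABEL_TUMOR).sum())
        n0 = len(dataset) - n1
        global_weights = ClassWeights.from_counts(n1, n0)
    elif cfg.weight_mode != "fold":
        raise ValueError(f"unknown weight mode {cfg.weight_mode!r}")

    pieces = []
    folds = []
    for pid in patients:
        test = dataset[dataset["patient_id"] == pid]
        train = dataset[dataset["patient_id"] != pid]
        n1 = int((train["label"] == LABEL_TUMOR).sum())
        n0 = len(train) - n1
        if n1 == 0 or n0 == 0:
            folds.append({"patient_id": pid, "error": "single-class training fold"})
            continue

        if cfg.leakage_mode == "fold":
            Xtr, stats = log10_standardize(train[FEATURE_COLUMNS])
            pca = fit_pca(Xtr)
        else:
            Xtr, stats = log10_standardize(train[FEATURE_COLUMNS], global_stats)
            pca = global_pca
        Xte, _ = log10_standardize(test[FEATURE_COLUMNS], stats)

        cw = global_weights if cfg.weight_mode == "global" else ClassWeights.from_counts(n1, n0)
        ytr = (train["label"] == LABEL_TUMOR).to_numpy(float)
        sw = np.where(ytr == 1.0, cw.w_tumor, cw.w_no_tumor)

        Str = project(Xtr, pca, cfg.n_pcs)
        Ste = project(Xte, pca, cfg.n_pcs)
        model = fit_weighted_logistic(Str, ytr, sw, cfg.logistic)
        post = predict_posterior(model, Ste)

        out = test.copy()
        out["posterior"] = post
        out["prediction"] = decide(post, cfg.threshold, cfg.tie_is_tumor)
        pieces.append(out)
        folds.append({
            "patient_id": pid,
            "n_train": len(train),
            "n_test": len(test),
            "weights": (cw.w_tumor, cw.w_no_tumor),
            "converged": model.converged,
            "separation": model.separation,
        })
    if not pieces:
        raise ValueError("no usable folds")
    return CVResult(pd.concat(pieces, axis=0), folds)


def stratify(dataset: pd.DataFrame, subset: str) -> pd.DataFrame:
    """Composition-stratified view of the dataset.

    ``low``/``medium``/``high`` keep tumor regions in that tumor-area band
    (0<p<25, 25<=p<75, p>=75) plus ALL no-tumor regions, so each subset
    supports an independent tumor-vs-no-tumor training run.
    """
    if subset == "total":
        return dataset
    if subset == "heterogeneous_only":
        keep = dataset[["p_tumor", "p_fibro", "p_adipose"]].max(axis=1) < 100
        return dataset[keep]
    bands = {"low": (0, 25), "medium": (25, 75), "high": (75, 101)}
    if subset not in bands:
        raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")
    lo, hi = bands[subset]
    p = dataset["p_tumor"]
    keep = (p == 0) | ((p > 0) & (p >= lo) & (p < hi))
    return dataset[keep]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n_tumor(self) -> int:
        return self.tp + self.fn

    @property
    def n_no_tumor(self) -> int:
        return self.fp + self.tn


def confusion(cv: CVResult | pd.DataFrame) -> ConfusionMatrix:
    df = cv.frame if isinstance(cv, CVResult) else cv
    truth = df["label"] == LABEL_TUMOR
    pred = df["prediction"] == LABEL_TUMOR
    return ConfusionMatrix(
        tp=int((truth & pred).sum()),
        fn=int((truth & ~pred).sum()),
        fp=int((~truth & pred).sum()),
        tn=int((~truth & ~pred).sum()),
    )


def sens_spec(cm: ConfusionMatrix) -> tuple[float, float]:
    """(sensitivity, specificity) with tumor as the positive class."""
    if cm.n_tumor == 0 or cm.n_no_tumor == 0:
        raise ValueError("both classes must be represented")
    return cm.tp / cm.n_tumor, cm.tn / cm.n_no_tumor


def confusion_rates(cm: ConfusionMatrix) -> dict[str, float]:
    """Derived rates: prediction precisions and FP/FN rates (fractions)."""
    out = {}
    pred_tumor = cm.tp + cm.fp
    pred_no_tumor = cm.tn + cm.fn
    out["precision_tumor"] = cm.tp / pred_tumor if pred_tumor else float("nan")
    out["precision_no_tumor"] = cm.tn / pred_no_tumor if pred_no_tumor else float("nan")
    out["fp_rate"] = cm.fp / cm.n_no_tumor if cm.n_no_tumor else float("nan")
    out["fn_rate"] = cm.fn / cm.n_tumor if cm.n_tumor else float("nan")
    return out


def threshold_sweep(cv: CVResult, thresholds) -> pd.DataFrame:
    """Sensitivity/specificity as the decision threshold sweeps 0 -> 1."""
    rows = []
    df = cv.frame
    for thr in thresholds:
        pred = decide(df["posterior"].to_numpy(), thr)
        tmp = df.copy()
        tmp["prediction"] = pred
        cm = confusion(tmp)
        sens, spec = sens_spec(cm)
        rows.append({"threshold": thr, "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)
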