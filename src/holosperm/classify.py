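"""SVM classification of control vs stressed cells on the 11 predictors.

The feature table carries, per cell, the morphological predictors
(OT_max, S, V, S/V, Ψ) and texture predictors (mean, variance, entropy,
kurtosis, skewness, energy) plus a binary label (0 control, 1 stressed).
Training standardizes the predictors with train-set statistics only and
fits a support vector machine (linear kernel, C = 1 by default; the
kernel is configurable).  Evaluation reports the confusion matrix at
decision-score threshold 0, sensitivity, specificity, accuracy, the full
ROC curve obtained by sweeping every distinct decision score, and the
trapezoidal AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FEATURE_COLUMNS",
    "SVMModel",
    "ClassificationReport",
    "split_dataset",
    "train_svm",
    "evaluate",
    "roc_curve_points",
    "auc_trapezoid",
    "run_classification",
]

FEATURE_COLUMNS = [
    "ot_max", "S", "V", "S_over_V", "sphericity",
    "mean", "variance", "entropy", "kurtosis", "skewness", "energy",
]


def _validate_table(df: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_COLUMNS + ["label"] if c not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    if df[FEATURE_COLUMNS].isna().any().any():
        raise ValueError("feature table contains missing predictor values")
    labels = set(df["label"].unique())
    if not labels <= {0, 1}:
        raise ValueError(f"labels must be 0/1, got {sorted(labels)}")


def split_dataset(
    df: pd.DataFrame, train_fraction: float = 0.6, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random train/test split.

    Per class, ``round(train_fraction · class_size)`` rows go to the
    train partition; partitions are disjoint and exhaustive and
    deterministic given ``seed``.
    """
    _validate_table(df)
    for lbl in (0, 1):
        if (df["label"] == lbl).sum() < 2:
            raise ValueError(f"need at least 2 rows of class {lbl}")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for lbl in (0, 1):
        idx = df.index[df["label"] == lbl].to_numpy()
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        if n_train == len(idx) or n_train == 0:
            raise ValueError(
                f"train fraction {train_fraction} leaves an empty partition for class {lbl}"
            )
        train_idx.append(idx[perm[:n_train]])
        test_idx.append(idx[perm[n_train:]])
    return (
        df.loc[np.concatenate(train_idx)].copy(),
        df.loc[np.concatenate(test_idx)].copy(),
    )


@dataclass
class SVMModel:
    scaler: StandardScaler
    svc: SVC
    columns: list[str]
    dropped_columns: list[str] = field(default_factory=list)
    kernel: str = "linear"
    C: float = 1.0

    def decision_scores(self, df: pd.DataFrame) -> np.ndarray:
        X = self.scaler.transform(df[self.columns].to_numpy(dtype=float))
        return self.svc.decision_function(X)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return (self.decision_scores(df) > 0).astype(int)


def train_svm(
    train: pd.DataFrame, kernel: str = "linear", C: float = 1.0
) -> SVMModel:
    """Fit the standardizer and SVM on the train partition only.

    Zero-variance predictors are dropped with a warning (they carry no
    information and break standardization); the dropped names are kept on
    the model and echoed in the report.
    """
    _validate_table(train)
    if train["label"].nunique() < 2:
        raise ValueError("training data must contain both classes")
    cols = list(FEATURE_COLUMNS)
    variances = train[cols].to_numpy(dtype=float).var(axis=0)
    dropped = [c for c, v in zip(cols, variances) if v == 0.0]
    if dropped:
        warnings.warn(f"dropping zero-variance predictors: {dropped}")
        cols = [c for c in cols if c not in dropped]
    X = train[cols].to_numpy(dtype=float)
    y = train["label"].to_numpy(dtype=int)
    scaler = StandardScaler().fit(X)
    svc = SVC(kernel=kernel, C=C).fit(scaler.transform(X), y)
    return SVMModel(scaler=scaler, svc=svc, columns=cols,
                    dropped_columns=dropped, kernel=kernel, C=C)


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    split_seed: int | None = None
    hyperparameters: dict = field(default_factory=dict)
    dropped_columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "split_seed": self.split_seed,
            "hyperparameters": self.hyperparameters,
            "dropped_columns": self.dropped_columns,
        }
        return d


def roc_curve_points(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC by sweeping every distinct score plus ±∞ as thresholds.

    A point (FPR, TPR) is emitted for the rule ``score >= threshold``;
    the curve starts at (0, 0) and ends at (1, 1).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("ROC requires both classes")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1], [-np.inf]])
    tpr = np.array([(scores[labels == 1] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[labels == 0] >= t).mean() for t in thresholds])
    return fpr, tpr, thresholds


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def evaluate(model: SVMModel, test: pd.DataFrame) -> ClassificationReport:
    """Confusion at threshold 0, ROC over all distinct scores, AUC.

    A single-class test set still yields the confusion counts, with the
    AUC flagged undefined (None).
    """
    _validate_table(test)
    if len(test) == 0:
        raise ValueError("test set is empty")
    scores = model.decision_scores(test)
    y = test["label"].to_numpy(dtype=int)
    pred = (scores > 0).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(y)
    if len(np.unique(y)) == 2:
        fpr, tpr, thr = roc_curve_points(y, scores)
        auc = auc_trapezoid(fpr, tpr)
        roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    else:
        auc = None
        roc = pd.DataFrame(columns=["fpr", "tpr", "threshold"])
    return ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, accuracy=acc,
        auc=auc, roc=roc,
        hyperparameters={"kernel": model.kernel, "C": model.C},
        dropped_columns=model.dropped_columns,
    )


def run_classification(
    features: pd.DataFrame | str | Path,
    train_fraction: float = 0.6,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
    out_report: str | Path | None = None,
    out_roc: str | Path | None = None,
) -> ClassificationReport:
    """Orchestrate split → train → evaluate; optionally write report files."""
    df = pd.read_csv(features) if isinstance(features, (str, Path)) else features
    _validate_table(df)
    train, test = split_dataset(df, train_fraction, seed)
    model = train_svm(train, kernel=kernel, C=C)
    report = evaluate(model, test)
    report.split_seed = seed
    report.hyperparameters["train_fraction"] = train_fraction
    if out_report is not None:
        Path(out_report).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    if out_roc is not None:
        report.roc.to_csv(out_roc, index=False, float_format="%.10g")
    return report
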