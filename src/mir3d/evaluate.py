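"""Leave-one-out cross-validation of feature panels and the six-metric summary.

Four model families are evaluated: SVC (RBF kernel, decision margin mapped
through a logistic sigmoid so 0.5 is the class boundary), SVR with linear
and RBF kernels, and KNN regression.  Regressor outputs are used raw;
binary calls threshold the continuous score at 0.5 (scores below 0.5 are
negative calls).  Metrics: accuracy, precision, recall, F1, AUPR (average
precision) and AUC (Mann-Whitney rank statistic, ties half-weighted), with
the case label (1) as the positive class.

Two selection protocols are offered: ``fixed_panel`` evaluates a panel
supplied up front (if that panel was derived from the full dataset the
evaluation inherits selection leakage — a warning is logged), while
``nested`` re-derives the panel inside every training fold and never sees
the held-out label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .errors import DataError, InvalidConfigError
from .profiling import ExpressionMatrix
from .select import FeaturePanel

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("svc", "svr_linear", "svr_rbf", "knn_regression")
CUTOFF = 0.5  # continuous score at/above which a sample is called positive


@dataclass(frozen=True)
class ModelSpec:
    """One model family plus its hyperparameters.

    Defaults are the common library choices (C=1, gamma='scale', k=5);
    feature z-scoring (fit on the training fold) is on for the
    scale-sensitive SVM families and irrelevant-but-harmless for KNN.
    """

    family: str
    C: float = 1.0
    gamma: str | float = "scale"
    n_neighbors: int = 5
    scale_features: bool = True
    score_transform: str = "sigmoid"  # applied to the SVC decision margin

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise InvalidConfigError(f"unknown model family {self.family!r}")
        if self.n_neighbors < 1:
            raise InvalidConfigError("n_neighbors must be >= 1")
        if self.score_transform not in ("sigmoid", "identity"):
            raise InvalidConfigError(
                f"unknown score transform {self.score_transform!r}"
            )

    def label(self) -> str:
        return self.family

    def make_estimator(self):
        if self.family == "svc":
            return SVC(C=self.C, kernel="rbf", gamma=self.gamma)
        if self.family == "svr_linear":
            return SVR(C=self.C, kernel="linear")
        if self.family == "svr_rbf":
            return SVR(C=self.C, kernel="rbf", gamma=self.gamma)
        return KNeighborsRegressor(n_neighbors=self.n_neighbors)


def default_model_specs() -> list[ModelSpec]:
    return [ModelSpec(family=f) for f in MODEL_FAMILIES]


@dataclass
class PredictionVector:
    """One held-out continuous score and binary call per sample."""

    sample_ids: list[str]
    scores: np.ndarray
    truth: np.ndarray
    fold_panels: list[FeaturePanel] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.truth = np.asarray(self.truth, dtype=int)
        if not (len(self.sample_ids) == len(self.scores) == len(self.truth)):
            raise DataError("prediction vector lengths disagree")

    @property
    def calls(self) -> np.ndarray:
        return (self.scores >= CUTOFF).astype(int)


@dataclass
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    aupr: float
    auc: float
    undefined_precision: bool = False

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "undefined_precision"}


def _score_samples(spec: ModelSpec, est, x: np.ndarray) -> np.ndarray:
    if spec.family == "svc":
        margin = est.decision_function(x)
        if spec.score_transform == "sigmoid":
            return 1.0 / (1.0 + np.exp(-margin))
        return margin
    return est.predict(x)


def loocv_predict(
    m: ExpressionMatrix,
    panel: FeaturePanel | None,
    spec: ModelSpec,
    selection_mode: str = "fixed_panel",
    selector: Callable[[ExpressionMatrix], FeaturePanel] | None = None,
) -> PredictionVector:
    """One held-out prediction per sample under LOOCV.

    ``fixed_panel`` restricts features to ``panel`` in every fold;
    ``nested`` calls ``selector`` on each training fold to re-derive the
    panel, so selection never observes the held-out label.
    """
    y = m.labels.to_numpy()
    samples = m.sample_ids
    n = len(samples)
    if selection_mode == "fixed_panel":
        if panel is None or len(panel) == 0:
            raise DataError("fixed_panel mode requires a nonempty panel")
        missing = [mid for mid in panel.mirna_ids if mid not in m.signal.index]
        if missing:
            raise DataError(f"panel miRNAs absent from matrix: {missing}")
        logger.warning(
            "fixed_panel LOOCV: the supplied panel is reused in every fold; "
            "if it was selected on the full dataset the evaluation inherits "
            "selection leakage (use selection_mode='nested' to avoid it)"
        )
    elif selection_mode == "nested":
        if selector is None:
            raise InvalidConfigError("nested mode requires a selector callable")
    else:
        raise InvalidConfigError(f"unknown selection mode {selection_mode!r}")

    x_full = m.signal.to_numpy().T  # samples x features
    col_of = {mid: j for j, mid in enumerate(m.signal.index)}
    scores = np.empty(n)
    fold_panels: list[FeaturePanel] = []
    for i in range(n):
        train = np.arange(n) != i
        y_tr = y[train]
        if len(set(y_tr)) < 2:
            raise DataError(f"training fold {i} ({samples[i]} held out) is single-class")
        if selection_mode == "nested":
            train_m = m.subset_samples([s for j, s in enumerate(samples) if j != i])
            fold_panel = selector(train_m)
            if len(fold_panel) == 0:
                raise DataError(f"nested selector returned an empty panel in fold {i}")
        else:
            fold_panel = panel
        fold_panels.append(fold_panel)
        cols = [col_of[mid] for mid in fold_panel.mirna_ids]
        x_tr, x_te = x_full[train][:, cols], x_full[i : i + 1, cols]
        if spec.scale_features:
            scaler = StandardScaler().fit(x_tr)
            x_tr, x_te = scaler.transform(x_tr), scaler.transform(x_te)
        est = spec.make_estimator().fit(x_tr, y_tr)
        scores[i] = _score_samples(spec, est, x_te)[0]
    return PredictionVector(
        sample_ids=list(samples), scores=scores, truth=y, fold_panels=fold_panels
    )


def mann_whitney_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC as the rank statistic: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes required for AUC")
    r = rankdata(scores)
    return float((r[truth == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(pred: PredictionVector) -> MetricSet:
    """Six threshold/rank metrics with the case class (1) as positive."""
    truth = pred.truth
    if len(set(truth)) < 2:
        raise DataError("both classes required in truth labels")
    calls = pred.calls
    tp = int(((calls == 1) & (truth == 1)).sum())
    tn = int(((calls == 0) & (truth == 0)).sum())
    fp = int(((calls == 1) & (truth == 0)).sum())
    fn = int(((calls == 0) & (truth == 1)).sum())
    accuracy = (tp + tn) / len(truth)
    undefined = tp + fp == 0
    if undefined:
        logger.warning("no positive calls; precision defined as 0")
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    auc = mann_whitney_auc(pred.scores, truth)
    aupr = float(average_precision_score(truth, pred.scores))
    return MetricSet(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        aupr=aupr,
        auc=auc,
        undefined_precision=undefined,
    )


@dataclass
class CurveData:
    """Threshold sweeps for ROC and precision-recall plots."""

    roc: pd.DataFrame  # columns threshold, fpr, tpr
    pr: pd.DataFrame  # columns threshold, recall, precision


def curves(pred: PredictionVector) -> CurveData:
    if len(set(pred.truth)) < 2:
        raise DataError("both classes required for curves")
    fpr, tpr, thr = roc_curve(pred.truth, pred.scores, drop_intermediate=False)
    roc = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    prec, rec, pthr = precision_recall_curve(pred.truth, pred.scores)
    pr = pd.DataFrame(
        {
            "threshold": np.append(pthr, np.inf),  # final point is the (0, 1) anchor
            "recall": rec,
            "precision": prec,
        }
    )
    return CurveData(roc=roc, pr=pr)


def compare_panels(
    m: ExpressionMatrix,
    panels: Sequence[FeaturePanel],
    specs: Sequence[ModelSpec],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full panels x models grid of LOOCV metrics, plus per-sample scores.

    Returns ``(metrics, sample_scores)``: ``metrics`` has one row per
    (panel, model) with the six metric columns; ``sample_scores`` is the
    long table of held-out scores for violin-style plots.
    """
    if not panels or not specs:
        raise InvalidConfigError("need at least one panel and one model spec")
    metric_rows = []
    score_rows = []
    for panel in panels:
        for spec in specs:
            pred = loocv_predict(m, panel, spec)
            ms = compute_metrics(pred)
            metric_rows.append(
                {"panel": panel.method, "n_features": len(panel), "model": spec.label(), **ms.as_dict()}
            )
            for sid, sc, tr in zip(pred.sample_ids, pred.scores, pred.truth):
                score_rows.append(
                    {
                        "panel": panel.method,
                        "model": spec.label(),
                        "sample_id": sid,
                        "score": sc,
                        "truth": int(tr),
                    }
                )
    return pd.DataFrame(metric_rows), pd.DataFrame(score_rows)
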