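"""Binary-classification performance measures and evaluation harness.

Implements the standard confusion-matrix statistics

    SN   = TP / (TP + FN)
    SP   = TN / (TN + FP)
    ACC  = (TP + TN) / (TP + TN + FP + FN)
    MCC  = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    BACC = (SN + SP) / 2

plus rank-based (Mann–Whitney) AUC with midrank tie handling, and a
stratified cross-validation harness that pools out-of-fold predictions.
MCC and BACC are the primary measures under class imbalance; ACC alone
is misleading when one class dominates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import EmptyDatasetError, InputError, StratificationError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class MetricsReport:
    """SN/SP/ACC/BACC/MCC (and optionally AUC) with their raw counts.

    A metric whose denominator vanishes is reported as ``None`` and the
    degeneracy is flagged, except MCC which follows the common
    zero-denominator convention MCC = 0 (flagged).
    """

    counts: ConfusionCounts
    sn: float | None
    sp: float | None
    acc: float
    bacc: float | None
    mcc: float
    auc: float | None = None
    degenerate: list[str] | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    def as_row(self) -> dict:
        """ACC/BACC/SN/SP/MCC/AUC column layout used in report tables."""
        return {
            "ACC": self.acc, "BACC": self.bacc, "SN": self.sn,
            "SP": self.sp, "MCC": self.mcc, "AUC": self.auc,
        }


def _as_binary(y) -> np.ndarray:
    arr = np.asarray(y)
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1}:
        raise InputError(f"labels must be binary 0/1, got values {sorted(uniq)}")
    return arr.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN for binary label vectors (1 = positive)."""
    yt, yp = _as_binary(y_true), _as_binary(y_pred)
    if yt.shape != yp.shape:
        raise InputError(f"length mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def compute_metrics(c: ConfusionCounts, scores_auc: float | None = None) -> MetricsReport:
    """Derive SN, SP, ACC, BACC and MCC from confusion counts."""
    if c.n == 0:
        raise EmptyDatasetError("cannot compute metrics on zero samples")
    degenerate = []
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    if sn is None:
        degenerate.append("sn")
    if sp is None:
        degenerate.append("sp")
    acc = (c.tp + c.tn) / c.n
    bacc = (sn + sp) / 2 if sn is not None and sp is not None else None
    if bacc is None:
        degenerate.append("bacc")
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc = 0.0
        degenerate.append("mcc_zero_denominator")
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricsReport(
        counts=c, sn=sn, sp=sp, acc=acc, bacc=bacc, mcc=mcc,
        auc=scores_auc, degenerate=degenerate or None,
    )


def auc_score(y_true, scores) -> float:
    """Rank-based ROC AUC: P(score⁺ > score⁻) + ½·P(tie), via midranks."""
    yt = _as_binary(y_true)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise InputError(f"length mismatch: {yt.shape} vs {s.shape}")
    n_pos = int(yt.sum())
    n_neg = len(yt) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined with a single-class truth")
    ranks = rankdata(s)  # midranks
    u = ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report from probability scores: threshold, tally, add AUC."""
    y_pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    c = confusion(y_true, y_pred)
    try:
        auc = auc_score(y_true, scores)
    except UndefinedMetricError:
        auc = None
    return compute_metrics(c, scores_auc=auc)


@dataclass
class CrossValidationReport:
    pooled: MetricsReport
    per_fold: list[MetricsReport]
    oof_scores: np.ndarray
    folds: int
    seed: int


def cross_validate(
    model_factory, X, y, folds: int = 10, seed: int = 0,
    threshold: float = 0.5,
) -> CrossValidationReport:
    """Stratified K-fold evaluation with pooled out-of-fold predictions.

    ``model_factory()`` must return a fresh estimator with ``fit`` and
    ``predict_proba``.  Metrics are computed on the pooled out-of-fold
    score vector (single-number summary); the per-fold breakdown is
    retained, and summed per-fold confusions equal the pooled confusion
    by construction.
    """
    X = np.asarray(X)
    yt = _as_binary(y)
    counts = np.bincount(yt, minlength=2)
    if counts.min() < 2:
        raise StratificationError(
            f"smallest class has {counts.min()} member(s); cannot stratify"
        )
    # stratification caps the fold count at the smaller class size
    folds = min(int(folds), int(counts.min()))
    try:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, yt))
    except ValueError as exc:
        raise StratificationError(str(exc)) from exc
    oof = np.full(len(yt), np.nan)
    per_fold = []
    for train_idx, test_idx in splits:
        model = model_factory()
        model.fit(X[train_idx], yt[train_idx])
        proba = model.predict_proba(X[test_idx])[:, 1]
        oof[test_idx] = proba
        per_fold.append(evaluate(yt[test_idx], proba, threshold))
    pooled = evaluate(yt, oof, threshold)
    return CrossValidationReport(
        pooled=pooled, per_fold=per_fold, oof_scores=oof,
        folds=folds, seed=seed,
    )
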