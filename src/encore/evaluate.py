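"""Classifier metrics, grouped cross-validation and boundary recovery.

auROC is the Mann-Whitney probability that a random positive outscores a
random negative (ties count 1/2); auPRC is the step-wise (non-interpolated)
precision-recall integral.  Cross-validation schemes mirror the training
protocols: plain k-fold on merged data, and leave-one-cell-type-out /
leave-one-chromosome-out grouped splits where no group ever spans train and
validation.  Boundary recovery scores refined intervals against the
simulator's ground-truth cores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.base import clone
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold, LeaveOneGroupOut

from .labeling import LabeledDataset
from .model import EnhancerClassifier
from .signal_io import GenomicInterval

__all__ = ["FoldScheme", "MetricReport", "auroc", "auprc", "crossval",
           "boundary_recovery", "coverage_ratio"]


def auroc(labels, scores) -> float:
    """Area under the ROC curve; requires both classes present."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("auROC undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve (step-wise integration)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if not np.any(labels == 1):
        raise ValueError("auPRC undefined without positives")
    return float(average_precision_score(labels, scores))


@dataclass(frozen=True)
class FoldScheme:
    """Cross-validation scheme.

    kind: 'kfold' | 'leave-one-cell-type-out' | 'leave-one-chromosome-out'
    k: number of folds (kfold only).
    """

    kind: str = "kfold"
    k: int = 5

    _KINDS = ("kfold", "leave-one-cell-type-out", "leave-one-chromosome-out")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown scheme {self.kind!r}; use {self._KINDS}")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")

    def groups(self, dataset: LabeledDataset) -> Optional[np.ndarray]:
        if self.kind == "leave-one-cell-type-out":
            return np.asarray(dataset.cell_type)
        if self.kind == "leave-one-chromosome-out":
            return np.asarray(dataset.chrom)
        return None

    def split(self, dataset: LabeledDataset, random_state=0):
        groups = self.groups(dataset)
        if groups is None:
            kf = KFold(n_splits=self.k, shuffle=True,
                       random_state=random_state)
            yield from kf.split(dataset.X)
        else:
            if len(np.unique(groups)) < 2:
                raise ValueError("grouped CV needs >= 2 groups")
            yield from LeaveOneGroupOut().split(dataset.X, dataset.y, groups)


@dataclass
class MetricReport:
    """Per-fold metrics with mean +/- sd aggregates."""

    folds: list = field(default_factory=list)   # dicts per fold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.folds)

    def aggregate(self) -> dict:
        df = self.to_frame()
        out = {}
        for col in ("auroc", "auprc", "val_loss"):
            if col in df:
                out[f"{col}_mean"] = float(df[col].mean())
                out[f"{col}_sd"] = float(df[col].std(ddof=0))
        return out


def crossval(dataset: LabeledDataset, scheme: FoldScheme,
             estimator: Optional[EnhancerClassifier] = None,
             random_state: int = 0, **fit_params) -> MetricReport:
    """Train one model per fold on its training partition only.

    Grouped schemes hold out entire cell types or chromosomes.  A held-out
    fold whose labels are single-class cannot be scored and raises.
    """
    base = estimator if estimator is not None else EnhancerClassifier()
    if fit_params:
        base = clone(base).set_params(**fit_params)
    report = MetricReport()
    groups = scheme.groups(dataset)
    for fold_id, (tr, va) in enumerate(scheme.split(dataset, random_state)):
        yva = dataset.y[va]
        if len(np.unique(yva)) < 2:
            gname = groups[va[0]] if groups is not None else fold_id
            raise ValueError(
                f"held-out group {gname!r} contains a single class; "
                "metrics are undefined")
        est = clone(base)
        if est.random_state is None:
            est.set_params(random_state=random_state + fold_id)
        est.fit(dataset.X[tr], dataset.y[tr])
        scores = est.predict_proba(dataset.X[va])[:, 1]
        entry = {"fold": fold_id,
                 "n_train": int(len(tr)), "n_val": int(len(va)),
                 "auroc": auroc(yva, scores), "auprc": auprc(yva, scores)}
        if est.history_.get("val_loss"):
            entry["val_loss"] = est.history_["val_loss"][-1]
        if groups is not None:
            entry["held_out_group"] = str(groups[va[0]])
        report.folds.append(entry)
    return report


def _interval_trees(intervals: Sequence[GenomicInterval]) -> dict:
    trees: dict = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def boundary_recovery(refined: Sequence[GenomicInterval],
                      truth: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Per-truth-core precision, recall and Jaccard against refined calls.

    For each ground-truth core, the union of refined intervals overlapping
    it is the matched prediction; Jaccard = |intersection| / |union|.
    Cores with no overlapping refined interval score 0.  The returned frame
    has one row per core; medians are in `df.attrs['medians']`.
    """
    trees = _interval_trees(refined)
    rows = []
    for iv in truth:
        t = trees.get(iv.chrom)
        hits = sorted((h.begin, h.end) for h in t.overlap(iv.start, iv.end)) \
            if t is not None else []
        inter = sum(min(e, iv.end) - max(s, iv.start) for s, e in hits)
        matched = sum(e - s for s, e in hits)
        union = matched + len(iv) - inter
        rows.append({
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "precision": inter / matched if matched else 0.0,
            "recall": inter / len(iv),
            "jaccard": inter / union if union else 0.0,
        })
    df = pd.DataFrame(rows)
    df.attrs["medians"] = {
        c: float(df[c].median()) if len(df) else float("nan")
        for c in ("precision", "recall", "jaccard")}
    return df


def coverage_ratio(refined: Sequence[GenomicInterval],
                   original: Sequence[GenomicInterval]) -> float:
    """Total refined bases / total original bases."""
    denom = sum(len(iv) for iv in original)
    if denom == 0:
        raise ValueError("original annotation is empty")
    return sum(len(iv) for iv in refined) / denom
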