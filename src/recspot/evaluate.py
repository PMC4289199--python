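"""Jackknife evaluation, grid search over (C, Dim), metrics and ROC/AUC.

Metrics follow the hot/cold misclassification-count formulation:

    Sn  = 1 - N+_mis / N+
    Sp  = 1 - N-_mis / N-
    Acc = 1 - (N+_mis + N-_mis) / (N+ + N-)
    MCC = standard contingency form on (TP, FP, TN, FN)

The default protocol ranks features once on the full dataset and then
runs a leave-one-out (jackknife) evaluation for each (C, top-N) grid
point, mirroring a single accuracy-vs-topN curve; a nested mode re-ranks
inside every fold for a leakage-free estimate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .ranking import (
    DEFAULT_C,
    LabeledMatrix,
    RankingList,
    fit_linear_svm,
    fscore_rank,
    rfe_rank,
    select_top,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Class sizes and misclassification counts of a two-class evaluation."""

    n_hot: int
    n_cold: int
    hot_missed: int  # hotspots predicted coldspot
    cold_missed: int  # coldspots predicted hotspot

    def __post_init__(self) -> None:
        if self.n_hot <= 0 or self.n_cold <= 0:
            raise ValueError("both classes must have at least one sample")
        if not (0 <= self.hot_missed <= self.n_hot):
            raise ValueError("hot_missed out of range")
        if not (0 <= self.cold_missed <= self.n_cold):
            raise ValueError("cold_missed out of range")


@dataclass(frozen=True)
class Metrics:
    sn: float
    sp: float
    acc: float
    mcc: float


def metrics_from_counts(c: ConfusionCounts) -> Metrics:
    """Sn, Sp, Acc and MCC from hot/cold misclassification counts."""
    sn = 1 - c.hot_missed / c.n_hot
    sp = 1 - c.cold_missed / c.n_cold
    acc = 1 - (c.hot_missed + c.cold_missed) / (c.n_hot + c.n_cold)
    tp = c.n_hot - c.hot_missed
    fn = c.hot_missed
    tn = c.n_cold - c.cold_missed
    fp = c.cold_missed
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.info("MCC denominator is zero (a contingency marginal is empty); returning 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=float(mcc))


def jackknife_evaluate(
    data: LabeledMatrix,
    C: float = DEFAULT_C,
    feature_subset: Optional[Sequence[str]] = None,
) -> Tuple[ConfusionCounts, np.ndarray]:
    """Leave-one-out evaluation with an SVM refit on every fold.

    Each sample is predicted by a model trained on the remaining n-1
    samples, restricted to ``feature_subset`` if given. Returns aggregated
    misclassification counts and the n signed decision values. Prediction
    is hotspot iff the decision value is strictly positive. A fold whose
    training set loses a class predicts the fold's majority class with
    decision value 0 (logged).
    """
    if data.n < 3:
        raise ValueError("jackknife requires at least 3 samples")
    cols = (
        data.column_indices(feature_subset)
        if feature_subset is not None
        else np.arange(data.dim)
    )
    X, y = data.X[:, cols], data.y
    n = data.n
    decisions = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        y_tr = y[mask]
        if len(np.unique(y_tr)) < 2:
            majority = 1 if (y_tr == 1).sum() >= (y_tr == -1).sum() else -1
            logger.warning(
                "fold %d lost a class; defaulting to fold majority %+d", i, majority
            )
            decisions[i] = 0.0 if majority == -1 else np.finfo(float).eps
        else:
            model = fit_linear_svm(X[mask], y_tr, C)
            decisions[i] = model.decision(X[i : i + 1])[0]
        mask[i] = True
    pred = np.where(decisions > 0, 1, -1)
    counts = ConfusionCounts(
        n_hot=int((y == 1).sum()),
        n_cold=int((y == -1).sum()),
        hot_missed=int(((y == 1) & (pred == -1)).sum()),
        cold_missed=int(((y == -1) & (pred == 1)).sum()),
    )
    return counts, decisions


@dataclass(frozen=True)
class GridSpec:
    """Search space for the regularization parameter C and the top-N dimension."""

    c_values: Tuple[float, ...] = (2.0**-5, 2.0**0, 2.0**5, 2.0**10, 2.0**15)
    n_values: Tuple[int, ...] = tuple(range(1, 201))

    def __post_init__(self) -> None:
        if not self.c_values or not self.n_values:
            raise ValueError("grids must be non-empty")
        if any(c <= 0 for c in self.c_values):
            raise ValueError("C values must be positive")
        if any(n < 1 for n in self.n_values):
            raise ValueError("N values must be >= 1")


@dataclass
class GridResult:
    best_c: float
    best_dim: int
    surface: pd.DataFrame  # columns: C, N, accuracy


def grid_search(
    data: LabeledMatrix, ranking: RankingList, grid: GridSpec
) -> GridResult:
    """Jackknife accuracy for each (C, top-N) pair; argmax with parsimony ties.

    Ties on accuracy prefer the smaller N, then the smaller C.
    """
    if any(n > data.dim for n in grid.n_values):
        raise ValueError("N grid contains values larger than the feature dimension")
    rows = []
    best = (-1.0, None, None)
    for n in sorted(set(grid.n_values)):
        subset = select_top(ranking, n)
        for c in sorted(set(grid.c_values)):
            counts, _ = jackknife_evaluate(data, C=c, feature_subset=subset)
            acc = metrics_from_counts(counts).acc
            rows.append({"C": c, "N": n, "accuracy": acc})
            if acc > best[0]:
                best = (acc, c, n)
    return GridResult(
        best_c=best[1], best_dim=best[2], surface=pd.DataFrame(rows)
    )


def roc_auc(
    labels: np.ndarray, decision_values: np.ndarray
) -> Tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) by threshold sweep and AUC by the trapezoid rule.

    Tied decision values step simultaneously, so the AUC equals the
    normalized Mann-Whitney U statistic.
    """
    labels = np.asarray(labels)
    decision_values = np.asarray(decision_values, dtype=float)
    if not np.isfinite(decision_values).all():
        raise ValueError("decision values must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes")
    if np.ptp(decision_values) == 0:
        logger.warning("constant decision values; AUC defaults to 0.5")
    fpr, tpr, _ = _sk_roc_curve(labels, decision_values, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(_sk_auc(fpr, tpr))


@dataclass
class EvalReport:
    """Full evaluation result at the chosen (C, Dim)."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    roc_points: np.ndarray
    chosen_c: float
    chosen_dim: int
    protocol: str = "jackknife"

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["roc_points"] = np.asarray(self.roc_points).tolist()
        return d

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_with_grid(
    data: LabeledMatrix,
    grid: GridSpec,
    ranker: str = "svm-rfe",
    rfe_c: float = DEFAULT_C,
    nested: bool = False,
) -> Tuple[EvalReport, RankingList, GridResult]:
    """The full evaluation protocol: rank, grid-search (C, Dim), final jackknife.

    Default protocol: one ranking on the full dataset, then jackknife per
    grid point. With ``nested`` the final jackknife re-ranks inside every
    fold (the grid's best (C, Dim) is still chosen on the default surface).
    """
    ranking = (
        fscore_rank(data) if ranker == "fscore" else rfe_rank(data, C=rfe_c)
    )
    result = grid_search(data, ranking, grid)
    subset = select_top(ranking, result.best_dim)
    if nested:
        counts, decisions = _nested_jackknife(
            data, result.best_c, result.best_dim, ranker, rfe_c
        )
    else:
        counts, decisions = jackknife_evaluate(
            data, C=result.best_c, feature_subset=subset
        )
    m = metrics_from_counts(counts)
    points, auc_val = roc_auc(data.y, decisions)
    report = EvalReport(
        sn=m.sn,
        sp=m.sp,
        acc=m.acc,
        mcc=m.mcc,
        auc=auc_val,
        roc_points=points,
        chosen_c=result.best_c,
        chosen_dim=result.best_dim,
        protocol="jackknife-nested" if nested else "jackknife",
    )
    return report, ranking, result


def _nested_jackknife(
    data: LabeledMatrix, C: float, dim: int, ranker: str, rfe_c: float
) -> Tuple[ConfusionCounts, np.ndarray]:
    """Leakage-free jackknife: feature ranking recomputed inside each fold."""
    n = data.n
    decisions = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        fold = LabeledMatrix(data.X[mask], data.y[mask], data.feature_names)
        rank_i = fscore_rank(fold) if ranker == "fscore" else rfe_rank(fold, C=rfe_c)
        cols = data.column_indices(select_top(rank_i, dim))
        model = fit_linear_svm(fold.X[:, cols], fold.y, C)
        decisions[i] = model.decision(data.X[i : i + 1, cols])[0]
        mask[i] = True
    pred = np.where(decisions > 0, 1, -1)
    counts = ConfusionCounts(
        n_hot=int((data.y == 1).sum()),
        n_cold=int((data.y == -1).sum()),
        hot_missed=int(((data.y == 1) & (pred == -1)).sum()),
        cold_missed=int(((data.y == -1) & (pred == 1)).sum()),
    )
    return counts, decisions


@dataclass
class OverlapReport:
    """Top-N feature overlap between two random halves and the full dataset."""

    top_n: int
    common_kmer: List[str]
    common_psednc: List[str]
    top_full: List[str]
    top_half1: List[str]
    top_half2: List[str]

    @property
    def n_common_kmer(self) -> int:
        return len(self.common_kmer)

    @property
    def n_common_psednc(self) -> int:
        return len(self.common_psednc)


def feature_overlap(
    data: LabeledMatrix,
    C: float = DEFAULT_C,
    top_n: int = 106,
    seed: int = 0,
) -> OverlapReport:
    """Split-stability analysis of the SVM-RFE ranking.

    The dataset is split into two stratified random halves; SVM-RFE is run
    on each half and on the full set, and the intersection of the three
    top-N lists is reported per feature family (k-mer vs PseDNC).
    """
    rng = np.random.default_rng(seed)
    idx1, idx2 = [], []
    for cls in (1, -1):
        members = np.flatnonzero(data.y == cls)
        if len(members) < 2:
            raise ValueError("each class needs >= 2 samples to split in half")
        perm = rng.permutation(members)
        half = len(perm) // 2
        idx1.extend(perm[:half])
        idx2.extend(perm[half:])
    tops = []
    for idx in (None, np.array(idx1), np.array(idx2)):
        sub = (
            data
            if idx is None
            else LabeledMatrix(data.X[idx], data.y[idx], data.feature_names)
        )
        tops.append(set(select_top(rfe_rank(sub, C=C), top_n)))
    common = tops[0] & tops[1] & tops[2]
    return OverlapReport(
        top_n=top_n,
        common_kmer=sorted(f for f in common if f.startswith("kmer:")),
        common_psednc=sorted(f for f in common if f.startswith("pse:")),
        top_full=sorted(tops[0]),
        top_half1=sorted(tops[1]),
        top_half2=sorted(tops[2]),
    )
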