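"""Feature ranking: SVM-RFE with a linear kernel, and an F-score baseline.

SVM-RFE fits a soft-margin linear SVM on the surviving features, removes
the single feature with the smallest squared weight, and repeats until
none remain; the ranking is the reverse elimination order. Ties on the
squared weight eliminate the feature with the larger layout index, so
earlier-defined features survive longer and the ranking is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

DEFAULT_C = 32.0


@dataclass
class LabeledMatrix:
    """Feature matrix with +1 (hotspot) / -1 (coldspot) labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: List[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y shapes are inconsistent")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match X columns")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be +1 (hotspot) or -1 (coldspot)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def column_indices(self, names: Sequence[str]) -> np.ndarray:
        index = {n: i for i, n in enumerate(self.feature_names)}
        try:
            return np.array([index[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown feature name {e.args[0]!r}") from None


@dataclass
class LinearSvmModel:
    """Trained soft-margin linear SVM: per-feature weights, bias, C."""

    weights: np.ndarray
    bias: float
    C: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision(X) > 0, 1, -1)


def fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float = DEFAULT_C) -> LinearSvmModel:
    """Fit a linear-kernel SVM (libsvm) and expose its primal weight vector."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    # classes_ is sorted [-1, +1], so the decision function is positive on
    # the hotspot side already.
    return LinearSvmModel(
        weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]), C=C
    )


@dataclass
class RankingList:
    """Full feature ranking, best first.

    ``elimination_step`` is a permutation of 1..D over features in ranking
    order (the rank-1 feature was eliminated last, at step D);
    ``criterion`` is the squared linear-SVM weight (or F-score) of each
    feature at the moment it was eliminated (scored).
    """

    names: List[str]
    elimination_step: np.ndarray
    criterion: np.ndarray
    method: str

    def __post_init__(self) -> None:
        d = len(self.names)
        if sorted(self.elimination_step) != list(range(1, d + 1)):
            raise ValueError("elimination_step must be a permutation of 1..D")

    def top(self, n: int) -> List[str]:
        return select_top(self, n)

    def to_tsv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {
                "rank": np.arange(1, len(self.names) + 1),
                "feature_name": self.names,
                "elimination_step": self.elimination_step,
                "criterion_value": self.criterion,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path], method: str = "svm-rfe") -> "RankingList":
        df = pd.read_csv(path, sep="\t")
        return cls(
            names=df["feature_name"].tolist(),
            elimination_step=df["elimination_step"].to_numpy(int),
            criterion=df["criterion_value"].to_numpy(float),
            method=method,
        )


def rfe_rank(data: LabeledMatrix, C: float = DEFAULT_C) -> RankingList:
    """Rank features by recursive feature elimination with a linear SVM.

    One feature is removed per iteration — the one with the smallest squared
    weight in the model fit on the surviving features.
    """
    surviving = list(range(data.dim))
    eliminated: List[int] = []
    criterion: List[float] = []
    while len(surviving) > 1:
        model = fit_linear_svm(data.X[:, surviving], data.y, C)
        w2 = model.weights**2
        # smallest w^2 is eliminated; ties remove the larger layout index
        best = np.flatnonzero(w2 == w2.min())[-1]
        eliminated.append(surviving.pop(best))
        criterion.append(float(w2[best]))
    eliminated.append(surviving.pop())
    criterion.append(float("nan"))  # survivor of the final 1-feature model

    d = data.dim
    order = eliminated[::-1]  # rank 1 = last eliminated
    steps = np.arange(d, 0, -1)
    return RankingList(
        names=[data.feature_names[i] for i in order],
        elimination_step=steps,
        criterion=np.array(criterion[::-1]),
        method="svm-rfe",
    )


def fscore(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-class F-score per feature (the LIBSVM feature-selection form).

    F_i = ((m+ - m)^2 + (m- - m)^2) / (s+^2 + s-^2) with unbiased
    within-class variances. Zero within-class variance in both classes
    gives +inf when the class means differ (maximally discriminative) and
    0 when they coincide.
    """
    X = np.asarray(X, dtype=float)
    pos, neg = X[y == 1], X[y == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("F-score requires at least two samples per class")
    m, mp, mn = X.mean(0), pos.mean(0), neg.mean(0)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = pos.var(0, ddof=1) + neg.var(0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    f[(num == 0) & (den == 0)] = 0.0
    if np.isinf(f).any():
        logger.info(
            "%d feature(s) have zero within-class variance in both classes; "
            "ranked as maximally discriminative",
            int(np.isinf(f).sum()),
        )
    return f


def fscore_rank(data: LabeledMatrix) -> RankingList:
    """Rank features by descending F-score; ties keep layout order."""
    scores = fscore(data.X, data.y)
    order = np.argsort(-scores, kind="stable")
    d = data.dim
    return RankingList(
        names=[data.feature_names[i] for i in order],
        elimination_step=np.arange(d, 0, -1),
        criterion=scores[order],
        method="fscore",
    )


def select_top(ranking: RankingList, n: int) -> List[str]:
    """First n feature names of a ranking."""
    if n < 1 or n > len(ranking.names):
        raise ValueError(f"N={n} out of range 1..{len(ranking.names)}")
    return ranking.names[:n]
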