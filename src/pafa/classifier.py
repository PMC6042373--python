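"""Sparse L1-regularized logistic regression scoring and evaluation.

The scoring model is an L1-penalized logistic regression fit with the
liblinear coordinate-descent solver; the L1 penalty drives uninformative
weights exactly to zero, and the probability score of a variant is the
sigmoid of its sparse decision value.  Features absent from a variant's
sparse row contribute 0 to the decision value — the operational meaning of
"missing" in this model.

Evaluation statistics: rank-based (Mann-Whitney) AUC with ties counted 1/2,
and the Wilcoxon rank-sum p-value under the tie-corrected normal
approximation.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix, FeatureRegistry

__all__ = [
    "SparseLogisticModel",
    "train_l1_logistic",
    "score_variants",
    "auc",
    "ranksum_pvalue",
    "cross_validate",
    "select_regularization",
]


@dataclass
class SparseLogisticModel:
    """Trained sparse weight vector + intercept.

    ``decision(x) = intercept + sum_i w_i x_i`` over the stored (nonzero)
    weights; ``score(x) = sigmoid(decision(x))``.
    """

    weights: dict  # feature index (1-based) -> float, nonzero entries only
    intercept: float
    registry_hash: str
    C: float
    tol: float
    seed: int
    n_features: int = 0

    def decision(self, row: dict) -> float:
        return self.intercept + sum(
            w * row[idx] for idx, w in self.weights.items() if idx in row
        )

    def score(self, row: dict) -> float:
        return _sigmoid(self.decision(row))

    def decision_array(self, X: sp.spmatrix) -> np.ndarray:
        w = np.zeros(X.shape[1])
        for idx, val in self.weights.items():
            w[idx - 1] = val
        return np.asarray(X @ w).ravel() + self.intercept

    # -- serialization: TSV weight table + JSON header ---------------------

    def write(self, prefix: str | os.PathLike, registry: Optional[FeatureRegistry] = None) -> None:
        prefix = os.fspath(prefix)
        names = {idx: name for name, idx, _ in registry.items()} if registry else {}
        with open(prefix + ".tsv", "w") as fh:
            fh.write("index\tname\tweight\n")
            for idx in sorted(self.weights):
                fh.write(f"{idx}\t{names.get(idx, '.')}\t{self.weights[idx]!r}\n")
        header = {
            "intercept": self.intercept,
            "C": self.C,
            "tol": self.tol,
            "seed": self.seed,
            "registry_hash": self.registry_hash,
            "n_features": self.n_features,
        }
        with open(prefix + ".json", "w") as fh:
            json.dump(header, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, prefix: str | os.PathLike) -> "SparseLogisticModel":
        prefix = os.fspath(prefix)
        with open(prefix + ".json") as fh:
            header = json.load(fh)
        weights = {}
        with open(prefix + ".tsv") as fh:
            fh.readline()
            for line in fh:
                f = line.rstrip("\n").split("\t")
                weights[int(f[0])] = float(f[2])
        return cls(
            weights=weights,
            intercept=header["intercept"],
            registry_hash=header["registry_hash"],
            C=header["C"],
            tol=header["tol"],
            seed=header["seed"],
            n_features=header.get("n_features", 0),
        )


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if not set(classes.tolist()) <= {-1, 1}:
        raise ValueError("labels must be in {+1, -1}")
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    return y


def train_l1_logistic(
    X: FeatureMatrix | sp.spmatrix,
    y: Sequence[int],
    C: float = 1.0,
    seed: int = 0,
    tol: float = 1e-6,
) -> SparseLogisticModel:
    """Fit the L1-penalized logistic loss to tolerance ``tol``.

    With small C many weights are exactly zero; an all-zero feature column
    gets weight exactly 0 for any C.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    registry_hash = ""
    if isinstance(X, FeatureMatrix):
        registry_hash = X.registry.fingerprint()
        Xc = X.to_csr()
    else:
        Xc = sp.csr_matrix(X)
    if Xc.shape[0] < 2:
        raise ValueError("need at least two training rows")
    if not np.all(np.isfinite(Xc.data)):
        raise ValueError("non-finite values in feature matrix")
    y = _check_labels(np.asarray(y))
    if len(y) != Xc.shape[0]:
        raise ValueError("label/row count mismatch")

    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=tol, random_state=seed
    )
    clf.fit(Xc, y)
    # liblinear orients the decision toward classes_[1]; flip if that is -1
    sign = 1.0 if clf.classes_[1] == 1 else -1.0
    coef = sign * clf.coef_[0]
    weights = {i + 1: float(w) for i, w in enumerate(coef) if w != 0.0}
    return SparseLogisticModel(
        weights=weights,
        intercept=float(sign * clf.intercept_[0]),
        registry_hash=registry_hash,
        C=C,
        tol=tol,
        seed=seed,
        n_features=Xc.shape[1],
    )


def score_variants(model: SparseLogisticModel, X: FeatureMatrix | sp.spmatrix) -> np.ndarray:
    """Probability scores (sigmoid of decision values) per row, in (0, 1)."""
    if isinstance(X, FeatureMatrix):
        if model.registry_hash and X.registry.fingerprint() != model.registry_hash:
            raise ValueError("feature registry does not match the model's registry")
        Xc = X.to_csr()
    else:
        Xc = sp.csr_matrix(X)
    d = model.decision_array(Xc)
    return 1.0 / (1.0 + np.exp(-d))


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute 1/2.

    Equals the probability that a uniformly random positive outranks a
    uniformly random negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(np.asarray(labels))
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)  # average ranks handle ties with weight 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def ranksum_pvalue(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> float:
    """Wilcoxon rank-sum p-value, tie-corrected normal approximation.

    ``alternative="greater"`` tests whether ``group_a`` is stochastically
    larger than ``group_b``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    res = mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(min(res.pvalue, 1.0))


@dataclass
class CVResult:
    fold_aucs: list
    mean_auc: float
    C: float


def cross_validate(
    X: FeatureMatrix | sp.spmatrix,
    y: Sequence[int],
    folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
    tol: float = 1e-6,
) -> CVResult:
    """Stratified k-fold cross-validated AUC.

    Folds preserve the class ratio; assignment is seeded and deterministic.
    """
    y = _check_labels(np.asarray(y))
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = [int((y == c).sum()) for c in (-1, 1)]
    if min(counts) < folds:
        raise ValueError("each class must have at least `folds` members to stratify")
    Xc = X.to_csr() if isinstance(X, FeatureMatrix) else sp.csr_matrix(X)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        model = train_l1_logistic(Xc[train_idx], y[train_idx], C=C, seed=seed, tol=tol)
        d = model.decision_array(Xc[test_idx])
        fold_aucs.append(auc(d, y[test_idx]))
    return CVResult(fold_aucs=fold_aucs, mean_auc=float(np.mean(fold_aucs)), C=C)


def select_regularization(
    X: FeatureMatrix | sp.spmatrix,
    y: Sequence[int],
    grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
    folds: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    auc_slack: float = 0.005,
) -> float:
    """Pick C by cross-validated AUC with a one-standard-error-style rule:
    the smallest (sparsest) C whose mean AUC is within max(1 SE,
    ``auc_slack``) of the best grid point.  The absolute floor keeps the
    rule meaningful when the CV curve is flat near its maximum and the
    fold-to-fold SE collapses."""
    results = []
    for C in sorted(grid):
        cv = cross_validate(X, y, folds=folds, C=C, seed=seed, tol=tol)
        se = float(np.std(cv.fold_aucs, ddof=1) / math.sqrt(len(cv.fold_aucs)))
        results.append((C, cv.mean_auc, se))
    best_mean = max(m for _, m, _ in results)
    best_se = next(s for _, m, s in results if m == best_mean)
    slack = max(best_se, auc_slack)
    for C, mean, _ in results:  # ascending C
        if mean >= best_mean - slack:
            return C
    return results[-1][0]
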