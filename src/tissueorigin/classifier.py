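"""Two-class similarity-score classifier.

The classification algorithm consumes standardized log2 expression
profiles and emits a pair of *similarity scores* — one per candidate
tissue of origin — that sum to 100 and behave like percent
probabilities of class membership.  The higher score names the more
likely tissue of origin.

Training has three stages:

1. **Marker ranking** — probesets ordered by the absolute pooled
   two-sample t-statistic between classes (ties broken by probeset id
   so the ranking is fully deterministic).
2. **Model fit** — an L2-regularized logistic model on the top-k
   markers (features z-scored with training means/sds).
3. **Feature-count selection** — a stratified cross-validated
   performance curve over a grid of candidate k, re-ranking markers
   inside every training fold so no selection leaks into the held-out
   fold; the chosen k is the smallest one whose AUC is within a
   tolerance of the best (the "simplest model with maximal achievable
   performance" rule).

The production assay locks k = 375 markers; synthetic cohorts need
far fewer, and k is a free parameter everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .constants import ENDOMETRIAL, INDETERMINATE, OVARIAN
from .errors import (
    DegenerateLabelsError,
    ParameterError,
    SchemaError,
)
from .valstats import roc_auc, round_half_away

__all__ = [
    "SimilarityScores",
    "ClassifierModel",
    "PerformanceCurve",
    "rank_markers",
    "fit_model",
    "predict_probability",
    "predict_similarity",
    "cv_performance_curve",
    "select_k",
]


@dataclass(frozen=True)
class SimilarityScores:
    """The reported score pair; always sums to 100.0 exactly."""

    ss_endometrial: float
    ss_ovarian: float
    call: str

    def __post_init__(self) -> None:
        if round(self.ss_endometrial + self.ss_ovarian, 6) != 100.0:
            raise ParameterError("similarity scores must sum to 100")


@dataclass
class ClassifierModel:
    """Locked linear model over an ordered marker panel."""

    probeset_ids: list[str]
    coefficients: np.ndarray  #: one weight per marker
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    training_summary: pd.DataFrame  #: per-marker class means/variances
    k: int

    def __post_init__(self) -> None:
        if len(self.probeset_ids) != self.k:
            raise ParameterError("|probeset_ids| must equal k")
        if not np.all(np.isfinite(self.coefficients)):
            raise ParameterError("coefficients must be finite")

    def to_json(self) -> str:
        return json.dumps({
            "probeset_ids": self.probeset_ids,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "training_summary": self.training_summary.to_dict(),
            "k": self.k,
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        return cls(
            probeset_ids=d["probeset_ids"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            training_summary=pd.DataFrame(d["training_summary"]),
            k=int(d["k"]),
        )


@dataclass
class PerformanceCurve:
    """Cross-validated operating statistics per candidate marker count."""

    k_grid: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.k_grid)
        if k.size == 0:
            raise ParameterError("curve must be non-empty")
        if np.any(np.diff(k) <= 0):
            raise ParameterError("k_grid must be strictly increasing")
        for arr in (self.sensitivity, self.specificity, self.auc):
            a = np.asarray(arr, dtype=float)
            if np.any((a < 0) | (a > 1)):
                raise ParameterError("estimates must lie in [0, 1]")


def _check_two_classes(labels: np.ndarray) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    if set(classes) != {ENDOMETRIAL, OVARIAN} or counts.min() < 2:
        raise DegenerateLabelsError(
            "need both classes with >= 2 specimens each"
        )


def rank_markers(train: pd.DataFrame, labels: Sequence) -> pd.DataFrame:
    """Order probesets by decreasing |pooled two-sample t|.

    ``train`` is a standardized log2 matrix (probesets x specimens).
    Returns a DataFrame indexed by probeset id, in rank order, with
    the signed t statistic (positive = higher in endometrial).
    """
    labels = np.asarray(labels)
    _check_two_classes(labels)
    a = train.to_numpy()[:, labels == ENDOMETRIAL]
    b = train.to_numpy()[:, labels == OVARIAN]
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((na - 1) * a.var(axis=1, ddof=1)
           + (nb - 1) * b.var(axis=1, ddof=1)) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se,
                     np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    out = pd.DataFrame({"t_stat": t, "abs_t": np.abs(t)},
                       index=train.index.astype(str))
    out = out.sort_index(kind="mergesort").sort_values(
        "abs_t", ascending=False, kind="mergesort")
    return out


def fit_model(train: pd.DataFrame, labels: Sequence, k: int,
              C: float = 1.0) -> ClassifierModel:
    """Fit the top-k marker logistic model on standardized profiles.

    Deterministic: refitting on identical input reproduces identical
    coefficients (lbfgs from a fixed zero start, no sampling).
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > train.shape[0]:
        raise ParameterError(
            f"k = {k} exceeds available probesets ({train.shape[0]})"
        )
    labels = np.asarray(labels)
    ranked = rank_markers(train, labels)
    ids = list(ranked.index[:k])

    X = train.loc[ids].to_numpy().T
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    Z = (X - means) / sds
    y = (labels == ENDOMETRIAL).astype(int)

    # default penalty is the L2 ridge; C controls its strength
    lr = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
    lr.fit(Z, y)

    mask_a = labels == ENDOMETRIAL
    summary = pd.DataFrame({
        "mean_endometrial": train.loc[ids].to_numpy()[:, mask_a].mean(axis=1),
        "mean_ovarian": train.loc[ids].to_numpy()[:, ~mask_a].mean(axis=1),
        "var_endometrial": train.loc[ids].to_numpy()[:, mask_a].var(
            axis=1, ddof=1),
        "var_ovarian": train.loc[ids].to_numpy()[:, ~mask_a].var(
            axis=1, ddof=1),
    }, index=ids)

    return ClassifierModel(
        probeset_ids=ids,
        coefficients=lr.coef_.ravel().copy(),
        intercept=float(lr.intercept_[0]),
        feature_means=means,
        feature_sds=sds,
        training_summary=summary,
        k=k,
    )


def predict_probability(model: ClassifierModel,
                        profile: pd.Series) -> float:
    """Probability that the profile matches the endometrial class."""
    missing = set(model.probeset_ids) - set(profile.index)
    if missing:
        raise SchemaError(
            f"profile missing model probesets: {sorted(missing)[:5]}"
        )
    z = (profile.loc[model.probeset_ids].to_numpy() - model.feature_means) \
        / model.feature_sds
    eta = float(z @ model.coefficients + model.intercept)
    return float(1.0 / (1.0 + np.exp(-eta)))


def predict_similarity(model: ClassifierModel,
                       profile: pd.Series) -> SimilarityScores:
    """Score one standardized profile.

    The endometrial score is the class probability times 100, rounded
    half-away-from-zero to one decimal; the ovarian score is its
    rounded complement, so the printed pair sums to 100.0 by
    construction.  A 50.0/50.0 tie yields an indeterminate call.
    """
    p = predict_probability(model, profile)
    ss_e = round_half_away(100.0 * p, 1)
    ss_o = round(100.0 - ss_e, 1)
    if ss_e > ss_o:
        call = ENDOMETRIAL
    elif ss_o > ss_e:
        call = OVARIAN
    else:
        call = INDETERMINATE
    return SimilarityScores(ss_e, ss_o, call)


def cv_performance_curve(
    train: pd.DataFrame,
    labels: Sequence,
    k_grid: Sequence[int],
    n_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> PerformanceCurve:
    """Stratified cross-validated sensitivity/specificity/AUC per k.

    Markers are re-ranked inside each training fold, so feature
    selection never sees the held-out fold.  Sensitivity is the
    endometrial recall at the 50-point score threshold; specificity
    the ovarian recall.  Deterministic given the seed.
    """
    labels = np.asarray(labels)
    _check_two_classes(labels)
    k_grid = np.asarray(sorted(set(int(k) for k in k_grid)))
    if k_grid[0] < 1 or k_grid[-1] > train.shape[0]:
        raise ParameterError("k_grid out of range")
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    class_min = min(np.sum(labels == c) for c in (ENDOMETRIAL, OVARIAN))
    if n_folds > class_min:
        raise ParameterError("n_folds exceeds the smaller class size")

    y = (labels == ENDOMETRIAL).astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    probs = {k: np.empty(labels.size) for k in k_grid}
    for tr_idx, te_idx in skf.split(np.zeros(labels.size), y):
        fold_train = train.iloc[:, tr_idx]
        fold_labels = labels[tr_idx]
        for k in k_grid:
            model = fit_model(fold_train, fold_labels, int(k), C=C)
            Xte = train.loc[model.probeset_ids].to_numpy()[:, te_idx].T
            z = (Xte - model.feature_means) / model.feature_sds
            eta = z @ model.coefficients + model.intercept
            probs[k][te_idx] = 1.0 / (1.0 + np.exp(-eta))

    sens, spec, aucs = [], [], []
    is_a = y.astype(bool)
    for k in k_grid:
        p = probs[k]
        called_a = p > 0.5
        sens.append(float(np.mean(called_a[is_a])))
        spec.append(float(np.mean(~called_a[~is_a])))
        aucs.append(roc_auc(p, labels, positive=ENDOMETRIAL))
    return PerformanceCurve(
        k_grid=k_grid,
        sensitivity=np.asarray(sens),
        specificity=np.asarray(spec),
        auc=np.asarray(aucs),
    )


def select_k(curve: PerformanceCurve, tolerance: float = 0.0) -> int:
    """Smallest marker count whose AUC is within ``tolerance`` of the best.

    With ``tolerance=0`` this returns the argmax (smallest k on ties):
    the simplest model achieving maximal cross-validated performance.
    """
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    auc = np.asarray(curve.auc, dtype=float)
    cutoff = auc.max() - tolerance
    for k, a in zip(curve.k_grid, auc):
        if a >= cutoff:
            return int(k)
    return int(curve.k_grid[-1])  # unreachable; max always qualifies
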