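"""Classifier training, evaluation and ensembling.

Random-forest / gradient-boosted-tree classifiers on any feature matrix,
with the four regularising hyper-parameters tuned by 5-fold grid search,
repeated stratified cross-validation (5 folds x 2 repeats = ten fold
models), ROC-AUC / average-precision / FPR-threshold curves, soft-voting
and consensus ensembles, and FPR-calibrated decision thresholds for
proteome-scale scanning.

Everywhere in the package a score >= threshold counts as a positive call
(ties included). Reproducibility: fold splits are seeded with
``seed + repeat_index`` and fold models with ``seed + global_fold_index``.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

#: Default hyper-parameter search grid; every other learner setting stays at
#: the library default.
DEFAULT_GRID = {
    "max_depth": [3, 5, 10, None],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 3, 5],
    "n_estimators": [100, 200, 500],
}


@dataclass(frozen=True)
class HyperParams:
    """The four tuned tree-ensemble hyper-parameters."""

    algorithm: str  # 'rf' | 'gbt'
    n_estimators: int = 200
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if self.algorithm not in ("rf", "gbt"):
            raise ValueError("algorithm must be 'rf' or 'gbt'")
        if self.n_estimators < 1 or self.min_samples_split < 2 \
                or self.min_samples_leaf < 1:
            raise ValueError("invalid hyper-parameter values")

    def make_estimator(self, seed: int):
        if self.algorithm == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                min_samples_split=self.min_samples_split,
                min_samples_leaf=self.min_samples_leaf,
                random_state=seed,
                n_jobs=1,
            )
        return GradientBoostingClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth if self.max_depth is not None else 3,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            random_state=seed,
        )


@dataclass
class TrainedClassifier:
    """A fitted fold model plus the metadata needed to reuse it."""

    algorithm: str
    hyperparams: HyperParams
    feature_name: str
    fold_tag: str
    model: object
    class_counts: tuple[int, int]  # (negatives, positives) in the fit set

    def predict_proba(self, X) -> np.ndarray:
        """Positive-class probability for each row of X."""
        return self.model.predict_proba(np.asarray(X, dtype=float))[:, 1]


@dataclass
class CurveSet:
    """Aligned threshold / TPR / FPR / precision / recall arrays.

    Thresholds are the unique scores in descending order; a sample is
    called positive iff its score >= threshold, so FPR, TPR and recall are
    non-decreasing along the arrays.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def fpr_at(self, t: float) -> float:
        """Step-wise right-continuous FPR at an arbitrary threshold."""
        if t > self.thresholds[0]:
            return 0.0
        # thresholds descending; find last index with thresholds[i] >= t
        idx = np.searchsorted(-self.thresholds, -t, side="right") - 1
        return float(self.fpr[idx])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney tie convention)."""
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, scores))


def average_precision(scores, labels) -> float:
    """Average precision AP = sum_n (R_n - R_{n-1}) P_n, no interpolation."""
    scores, labels = _check_scores_labels(scores, labels)
    if labels.sum() == 0:
        raise ValueError("average_precision needs at least one positive")
    return float(average_precision_score(labels, scores))


def fpr_threshold_curve(scores, labels) -> CurveSet:
    """Threshold-indexed TPR/FPR/precision/recall over unique scores."""
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_neg == 0:
        raise ValueError("fpr_threshold_curve needs negatives present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # cumulative counts at each position, collapsed to unique thresholds
    tp_cum = np.cumsum(y)
    fp_cum = np.cumsum(1 - y)
    last_of_value = np.nonzero(np.r_[s[1:] != s[:-1], True])[0]
    thresholds = s[last_of_value]
    tp = tp_cum[last_of_value].astype(float)
    fp = fp_cum[last_of_value].astype(float)
    fpr = fp / n_neg
    tpr = tp / n_pos if n_pos else np.zeros_like(fp)
    precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
    recall = tpr
    return CurveSet(thresholds, tpr, fpr, precision, recall)


def sensitivity_at_threshold(scores, labels, threshold: float) -> float:
    """Recall of the positive class at score >= threshold."""
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("no positives")
    return float(((scores >= threshold) & (labels == 1)).sum() / n_pos)


# ---------------------------------------------------------------------------
# Grid search and repeated stratified cross-validation
# ---------------------------------------------------------------------------

def _check_class_sizes(y, folds):
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs at least {folds} samples for {folds}-fold "
            f"stratified CV; got counts {counts.tolist()}"
        )
    return y


def grid_search(X, y, algorithm: str, grid: dict | None = None,
                folds: int = 5, seed: int = 0) -> HyperParams:
    """Pick the grid point with the highest mean CV ROC-AUC.

    Ties are broken by fewer trees, then shallower depth, then grid order.
    The same stratified fold split is reused for every grid point.
    """
    X = np.asarray(X, dtype=float)
    y = _check_class_sizes(y, folds)
    grid = dict(DEFAULT_GRID if grid is None else grid)
    if any(len(v) == 0 for v in grid.values()) or not grid:
        raise ValueError("empty hyper-parameter grid")
    keys = list(grid)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X, y))
    best = None
    for order, combo in enumerate(itertools.product(*(grid[k] for k in keys))):
        params = HyperParams(algorithm=algorithm, **dict(zip(keys, combo)))
        aucs = []
        for fi, (tr, va) in enumerate(splits):
            est = params.make_estimator(seed + fi)
            est.fit(X[tr], y[tr])
            aucs.append(roc_auc(est.predict_proba(X[va])[:, 1], y[va]))
        mean_auc = float(np.mean(aucs))
        depth_key = params.max_depth if params.max_depth is not None else np.inf
        key = (-mean_auc, params.n_estimators, depth_key, order)
        if best is None or key < best[0]:
            best = (key, params)
    logger.info("grid search selected %s (mean AUC %.4f)", best[1], -best[0][0])
    return best[1]


@dataclass
class CVReport:
    """Fold models, scores and curves from repeated stratified CV."""

    fold_models: list[TrainedClassifier]
    fold_roc_auc: np.ndarray
    fold_ap: np.ndarray
    curves: list[CurveSet]
    fold_val_indices: list[np.ndarray]
    fold_val_scores: list[np.ndarray]
    folds: int
    repeats: int
    seed: int
    hyperparams: HyperParams

    @property
    def mean_roc_auc(self) -> float:
        return float(self.fold_roc_auc.mean())

    @property
    def sd_roc_auc(self) -> float:
        return float(self.fold_roc_auc.std(ddof=1))

    @property
    def mean_ap(self) -> float:
        return float(self.fold_ap.mean())

    @property
    def sd_ap(self) -> float:
        return float(self.fold_ap.std(ddof=1))

    def to_ensemble(self, mode: str = "soft",
                    threshold: float = 0.5) -> "EnsembleModel":
        """Deployable ensemble = the fold models with equal-weight voting."""
        return EnsembleModel(list(self.fold_models), mode=mode,
                             threshold=threshold)

    def pooled_validation_scores(self, y) -> tuple[np.ndarray, np.ndarray]:
        """Out-of-fold scores pooled over all folds (labels aligned)."""
        y = np.asarray(y, dtype=int)
        scores = np.concatenate(self.fold_val_scores)
        labels = np.concatenate([y[idx] for idx in self.fold_val_indices])
        return scores, labels

    def summary(self) -> dict:
        return {
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "hyperparams": asdict(self.hyperparams),
            "fold_roc_auc": self.fold_roc_auc.tolist(),
            "fold_ap": self.fold_ap.tolist(),
            "mean_roc_auc": self.mean_roc_auc,
            "sd_roc_auc": self.sd_roc_auc,
            "mean_ap": self.mean_ap,
            "sd_ap": self.sd_ap,
        }


def repeated_stratified_cv(X, y, params: HyperParams, folds: int = 5,
                           repeats: int = 2, seed: int = 0,
                           feature_name: str = "") -> CVReport:
    """Stratified k-fold CV repeated with distinct derived seeds.

    At the defaults (5 folds x 2 repeats) this yields the ten fold models
    that form the deployable soft-voting ensemble. Folds preserve class
    proportions to within one sample; within one repeat every sample
    appears in exactly one validation fold.
    """
    X = np.asarray(X, dtype=float)
    y = _check_class_sizes(y, folds)
    fold_models: list[TrainedClassifier] = []
    aucs, aps, curves, val_idx, val_scores = [], [], [], [], []
    global_fold = 0
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=seed + rep)
        for fi, (tr, va) in enumerate(splitter.split(X, y)):
            est = params.make_estimator(seed + global_fold)
            est.fit(X[tr], y[tr])
            s = est.predict_proba(X[va])[:, 1]
            aucs.append(roc_auc(s, y[va]))
            aps.append(average_precision(s, y[va]))
            curves.append(fpr_threshold_curve(s, y[va]))
            val_idx.append(va)
            val_scores.append(s)
            counts = np.bincount(y[tr], minlength=2)
            fold_models.append(TrainedClassifier(
                algorithm=params.algorithm,
                hyperparams=params,
                feature_name=feature_name,
                fold_tag=f"rep{rep}_fold{fi}",
                model=est,
                class_counts=(int(counts[0]), int(counts[1])),
            ))
            global_fold += 1
    return CVReport(fold_models, np.array(aucs), np.array(aps), curves,
                    val_idx, val_scores, folds, repeats, seed, params)


# ---------------------------------------------------------------------------
# Ensembles and threshold calibration
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Ordered trained classifiers with a voting mode and decision threshold."""

    members: list[TrainedClassifier]
    mode: str = "soft"  # 'soft' | 'consensus'
    threshold: float = 0.90

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.mode not in ("soft", "consensus"):
            raise ValueError("mode must be 'soft' or 'consensus'")

    def member_probabilities(self, X) -> np.ndarray:
        return np.stack([m.predict_proba(X) for m in self.members])

    def predict_proba(self, X) -> np.ndarray:
        """Equal-weight soft-vote probability."""
        return self.member_probabilities(X).mean(axis=0)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "mode": self.mode,
            "threshold": self.threshold,
            "members": [],
        }
        for i, m in enumerate(self.members):
            fname = f"member_{i:02d}.joblib"
            joblib.dump(m.model, directory / fname)
            manifest["members"].append({
                "file": fname,
                "algorithm": m.algorithm,
                "hyperparams": asdict(m.hyperparams),
                "feature_name": m.feature_name,
                "fold_tag": m.fold_tag,
                "class_counts": list(m.class_counts),
            })
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "EnsembleModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        members = []
        for entry in manifest["members"]:
            hp = HyperParams(**entry["hyperparams"])
            members.append(TrainedClassifier(
                algorithm=entry["algorithm"],
                hyperparams=hp,
                feature_name=entry["feature_name"],
                fold_tag=entry["fold_tag"],
                model=joblib.load(directory / entry["file"]),
                class_counts=tuple(entry["class_counts"]),
            ))
        return cls(members, mode=manifest["mode"],
                   threshold=manifest["threshold"])


def soft_vote(ensemble: EnsembleModel, x) -> float:
    """Unweighted mean of member probabilities for one feature vector."""
    if ensemble.mode != "soft":
        raise ValueError("soft_vote requires an ensemble in 'soft' mode")
    x = np.asarray(x, dtype=float).reshape(1, -1)
    return float(ensemble.predict_proba(x)[0])


def consensus_predict(ensemble: EnsembleModel, x, threshold: float) -> str:
    """'positive' iff every member's probability is >= threshold."""
    if ensemble.mode != "consensus":
        raise ValueError("consensus_predict requires 'consensus' mode")
    x = np.asarray(x, dtype=float).reshape(1, -1)
    probs = ensemble.member_probabilities(x)[:, 0]
    return "positive" if bool(np.all(probs >= threshold)) else "negative"


def calibrate_threshold(curves: list[CurveSet], target_fpr: float,
                        grid_step: float = 0.01) -> float:
    """Smallest grid threshold whose fold-averaged FPR is <= target_fpr.

    Each fold's FPR-threshold step function is evaluated (right-continuous)
    on a common 0.00-1.00 grid and averaged with equal weight. If even a
    threshold of 1.0 cannot attain the target, 1.0 is returned with a
    warning.
    """
    if not 0 < target_fpr <= 1:
        raise ValueError("target_fpr must be in (0, 1]")
    if not curves:
        raise ValueError("no curves provided")
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    avg = np.array([
        np.mean([c.fpr_at(t) for c in curves]) for t in grid
    ])
    attainable = np.nonzero(avg <= target_fpr)[0]
    if len(attainable) == 0:
        warnings.warn(
            f"target FPR {target_fpr} unattainable below threshold 1.0; "
            f"returning 1.0", stacklevel=2,
        )
        return 1.0
    return float(grid[attainable[0]])


def scan_proteome(ensemble: EnsembleModel, dataset, X,
                  threshold: float = 0.90) -> tuple[pd.DataFrame, list[str]]:
    """Soft-vote score for every protein plus the hit list at the cutoff.

    Returns a DataFrame (id, score, call) in dataset order and the list of
    hit ids sorted by score descending, ties by id.
    """
    X = np.asarray(X, dtype=float)
    if len(X) != len(dataset):
        raise ValueError("feature matrix rows != dataset records")
    if len(dataset) == 0:
        return pd.DataFrame(columns=["id", "score", "call"]), []
    if X.shape[1] != _ensemble_dim(ensemble):
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the ensemble "
            f"training dimension {_ensemble_dim(ensemble)}"
        )
    scores = ensemble.predict_proba(X)
    df = pd.DataFrame({
        "id": dataset.ids,
        "score": scores,
        "call": (scores >= threshold).astype(int),
    })
    hits = df[df["call"] == 1].sort_values(
        ["score", "id"], ascending=[False, True]
    )["id"].tolist()
    return df, hits


def _ensemble_dim(ensemble: EnsembleModel) -> int:
    return int(ensemble.members[0].model.n_features_in_)
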