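"""Model training, validation and majority-vote ensembling.

Base classifiers (random forest, RBF support-vector machine, gradient
boosting) are trained on a feature block with the configured imbalance
handling, optionally tuned by exhaustive grid search in an inner
stratified ten-fold CV, and evaluated by repeated stratified 90/10
shuffle splits (a disjoint stratified k-fold mode is also available).
Structure-aware validation uses a Butina leader-clustering split on
Tanimoto fingerprint distances so that no cluster straddles the split.
The best members are combined by majority voting with ties resolved
positive (precautionary for a hazard endpoint).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import BulkTanimotoSimilarity
from rdkit.ML.Cluster import Butina
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .balancing import BalancingConfig, class_weights, smote_resample

MODELS = ("rf", "svm", "xgb")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {"n_estimators": [100, 300, 500], "max_depth": [None, 10, 20]},
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01]},
    "xgb": {"n_estimators": [100, 300], "max_depth": [3, 6],
            "learning_rate": [0.1, 0.3]},
}


@dataclass
class PipelineConfig:
    """One model-training pipeline: learner, grid, balancing, CV scheme.

    ``grid=None`` skips hyperparameter search and trains with ``params``.
    ``cv_mode='shuffle'`` performs ``outer_folds`` independent stratified
    90/10 shuffle splits; ``'kfold'`` uses a disjoint stratified
    partition instead.
    """

    model: str = "rf"
    params: dict = field(default_factory=dict)
    grid: dict[str, list] | None = None
    balancing: BalancingConfig = field(default_factory=BalancingConfig)
    outer_folds: int = 10
    val_fraction: float = 0.1
    inner_folds: int = 10
    cv_mode: str = "shuffle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.cv_mode not in ("shuffle", "kfold"):
            raise ValueError("cv_mode must be 'shuffle' or 'kfold'")


def make_classifier(
    model: str,
    params: dict | None = None,
    seed: int = 0,
    sample_class_weights: dict[int, float] | None = None,
):
    """Instantiate a base learner with optional class weighting."""
    params = dict(params or {})
    if model == "rf":
        return RandomForestClassifier(
            random_state=seed, n_jobs=1,
            class_weight=sample_class_weights, **params,
        )
    if model == "svm":
        params.setdefault("kernel", "rbf")
        return SVC(random_state=seed, probability=False,
                   class_weight=sample_class_weights, **params)
    if model == "xgb":
        if sample_class_weights is not None:
            # xgboost expresses binary class weighting as a single ratio
            params.setdefault(
                "scale_pos_weight",
                sample_class_weights[1] / sample_class_weights[0],
            )
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss",
            verbosity=0, **params,
        )
    raise ValueError(f"unknown model {model!r}")


def predict_scores(clf, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class scores (probability or margin)."""
    if hasattr(clf, "predict_proba") and getattr(clf, "probability", True):
        return np.asarray(clf.predict_proba(X)[:, 1], dtype=float)
    return np.asarray(clf.decision_function(X), dtype=float)


def _fit_balanced(
    model: str, params: dict, X: np.ndarray, y: np.ndarray,
    balancing: BalancingConfig, seed: int,
):
    """Fit one learner with the configured imbalance handling."""
    if balancing.method == "smote":
        X, y = smote_resample(X, y, balancing)
        clf = make_classifier(model, params, seed=seed)
    elif balancing.method == "class_weight":
        clf = make_classifier(
            model, params, seed=seed, sample_class_weights=class_weights(y)
        )
    else:
        clf = make_classifier(model, params, seed=seed)
    clf.fit(X, y)
    return clf


def evaluate_predictions(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    scores: np.ndarray | None = None,
) -> dict:
    """Confusion-matrix metrics of binary predictions.

    Acc = (TP+TN)/n, SE = TP/(TP+FN), SP = TN/(TN+FP); AUC (probability
    that a random positive outscores a random negative, ties counting
    half) only when continuous scores are given — a majority vote yields
    labels only, so its AUC is undefined and omitted.
    """
    y = np.asarray(true_labels).astype(int)
    p = np.asarray(pred_labels).astype(int)
    if p.shape != y.shape:
        raise ValueError("prediction and truth must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("SE/SP/AUC need both classes in the truth vector")
    tp = int(((p == 1) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    out = {
        "acc": (tp + tn) / len(y),
        "se": tp / (tp + fn),
        "sp": tn / (tn + fp),
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }
    if scores is not None:
        out["auc"] = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    return out


@dataclass
class EvaluationReport:
    """Per-fold and averaged Acc/SE/SP/AUC with confusion counts."""

    folds: list[dict]

    @property
    def means(self) -> dict:
        keys = [k for k in ("acc", "se", "sp", "auc") if k in self.folds[0]]
        return {k: float(np.mean([f[k] for f in self.folds])) for k in keys}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.folds)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"folds": self.folds, "means": self.means}, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _outer_splitter(cfg: PipelineConfig):
    if cfg.cv_mode == "shuffle":
        return StratifiedShuffleSplit(
            n_splits=cfg.outer_folds, test_size=cfg.val_fraction,
            random_state=cfg.seed,
        )
    return StratifiedKFold(n_splits=cfg.outer_folds, shuffle=True,
                           random_state=cfg.seed)


def stratified_cv(cfg: PipelineConfig, X: np.ndarray, y: np.ndarray) -> EvaluationReport:
    """Repeated stratified CV of one pipeline.

    Each split holds out ``val_fraction`` of compounds with the class
    ratio preserved; balancing (and any grid search) is fitted on the
    training portion only. Fold assignments are reproducible for a
    fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    folds = []
    for train, val in _outer_splitter(cfg).split(X, y):
        if cfg.grid:
            clf, _ = grid_search_fit(cfg, X[train], y[train])
        else:
            clf = _fit_balanced(cfg.model, cfg.params, X[train], y[train],
                                cfg.balancing, cfg.seed)
        pred = np.asarray(clf.predict(X[val])).astype(int)
        folds.append(
            evaluate_predictions(pred, y[val], scores=predict_scores(clf, X[val]))
        )
    return EvaluationReport(folds=folds)


def grid_search_fit(
    cfg: PipelineConfig, X: np.ndarray, y: np.ndarray
) -> tuple[object, dict]:
    """Exhaustive grid search by inner stratified k-fold mean AUC.

    Combinations are scored in grid order and ties keep the earlier
    combination; the winner is refitted on the full training portion.
    """
    grid = cfg.grid if cfg.grid is not None else DEFAULT_GRIDS[cfg.model]
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    names = list(grid)
    combos = [dict(zip(names, values))
              for values in itertools.product(*(grid[n] for n in names))]

    inner = StratifiedKFold(n_splits=min(cfg.inner_folds, int(np.bincount(y).min())),
                            shuffle=True, random_state=cfg.seed)
    best_params, best_auc = None, -np.inf
    for params in combos:
        aucs = []
        for tr, te in inner.split(X, y):
            clf = _fit_balanced(cfg.model, params, X[tr], y[tr],
                                cfg.balancing, cfg.seed)
            aucs.append(roc_auc_score(y[te], predict_scores(clf, X[te])))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_params, best_auc = params, mean_auc
    clf = _fit_balanced(cfg.model, best_params, X, y, cfg.balancing, cfg.seed)
    return clf, best_params


# ---------------------------------------------------------------------------
# Butina structure-aware split


def butina_clusters(
    records: Sequence,
    distance_cutoff: float = 0.4,
    radius: int = 2,
    nbits: int = 2048,
) -> list[tuple[int, ...]]:
    """Butina leader clustering on Tanimoto fingerprint distances.

    Returns clusters of compound indices, largest first (ties by member
    indices, so the result is deterministic).
    """
    from .featurization import _as_mol  # avoid cycle at import time

    mols = [_as_mol(r) for r in records]
    n = len(mols)
    if n < 2:
        raise ValueError("need at least 2 compounds to cluster")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    fps = [gen.GetFingerprint(m) for m in mols]
    dists = []
    for i in range(1, n):
        sims = BulkTanimotoSimilarity(fps[i], fps[:i])
        dists.extend(1.0 - s for s in sims)
    clusters = Butina.ClusterData(dists, n, distance_cutoff, isDistData=True)
    return sorted((tuple(sorted(c)) for c in clusters), key=lambda c: (-len(c), c))


def butina_split(
    records: Sequence,
    val_fraction: float = 0.1,
    distance_cutoff: float = 0.4,
    radius: int = 2,
    nbits: int = 2048,
) -> tuple[list[int], list[int]]:
    """Cluster-aware train/validation split.

    Compounds are clustered by the Butina leader algorithm on Tanimoto
    distances of circular fingerprints; whole clusters are then assigned
    greedily (largest first, to the side with the larger remaining
    deficit) so validation holds about ``val_fraction`` of compounds and
    no cluster straddles the split.
    """
    n = len(records)
    clusters = butina_clusters(records, distance_cutoff=distance_cutoff,
                               radius=radius, nbits=nbits)
    if len(clusters) == 1:
        raise ValueError(
            "all compounds fell into one cluster; adjust the distance cutoff"
        )
    n_val_target = round(val_fraction * n)
    train: list[int] = []
    val: list[int] = []
    for cluster in clusters:
        deficit_train = (n - n_val_target) - len(train)
        deficit_val = n_val_target - len(val)
        side = val if deficit_val > deficit_train else train
        side.extend(cluster)
    return sorted(train), sorted(val)


# ---------------------------------------------------------------------------
# Majority-vote ensemble


def majority_vote(member_predictions: Sequence[np.ndarray]) -> np.ndarray:
    """Per-compound label with more votes; exact ties return positive."""
    if len(member_predictions) < 2:
        raise ValueError("majority vote needs at least 2 members")
    votes = np.vstack([np.asarray(p).astype(int) for p in member_predictions])
    if not np.isin(votes, (0, 1)).all():
        raise ValueError("member predictions must be binary")
    return (2 * votes.sum(axis=0) >= votes.shape[0]).astype(int)


@dataclass
class EnsembleMember:
    """One ensemble member: feature block + learner + balancing."""

    name: str
    feature_block: str
    model: str
    params: dict = field(default_factory=dict)
    balancing: BalancingConfig = field(default_factory=BalancingConfig)


@dataclass
class TrainedEnsemble:
    """Fitted majority-vote ensemble over named feature blocks."""

    members: list[tuple[EnsembleMember, object]]
    vote: str = "majority"
    tie_rule: str = "positive"

    def predict(self, features: dict[str, np.ndarray]) -> np.ndarray:
        preds = [
            np.asarray(clf.predict(features[member.feature_block])).astype(int)
            for member, clf in self.members
        ]
        return majority_vote(preds)


def train_ensemble(
    members: Sequence[EnsembleMember],
    features: dict[str, np.ndarray],
    y: np.ndarray,
    seed: int = 0,
) -> TrainedEnsemble:
    """Fit every member on its feature block (same compounds, same labels)."""
    if len(members) < 2:
        raise ValueError("an ensemble needs at least 2 members")
    y = np.asarray(y).astype(int)
    n = len(y)
    for member in members:
        if member.feature_block not in features:
            raise ValueError(f"missing feature block {member.feature_block!r}")
        if len(features[member.feature_block]) != n:
            raise ValueError("all members must be trained on identical compounds")
    fitted = []
    for member in members:
        X = np.asarray(features[member.feature_block], dtype=float)
        clf = _fit_balanced(member.model, member.params, X, y,
                            member.balancing, seed)
        fitted.append((member, clf))
    return TrainedEnsemble(members=fitted)


def cross_validate_ensemble(
    members: Sequence[EnsembleMember],
    features: dict[str, np.ndarray],
    y: np.ndarray,
    outer_folds: int = 10,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified shuffle-split CV of the majority-vote ensemble.

    The vote yields labels only, so the report carries Acc/SE/SP without
    AUC.
    """
    y = np.asarray(y).astype(int)
    splitter = StratifiedShuffleSplit(
        n_splits=outer_folds, test_size=val_fraction, random_state=seed
    )
    any_block = next(iter(features.values()))
    folds = []
    for train, val in splitter.split(any_block, y):
        train_features = {k: np.asarray(v, dtype=float)[train]
                          for k, v in features.items()}
        val_features = {k: np.asarray(v, dtype=float)[val]
                        for k, v in features.items()}
        ensemble = train_ensemble(members, train_features, y[train], seed=seed)
        pred = ensemble.predict(val_features)
        folds.append(evaluate_predictions(pred, y[val]))
    return EvaluationReport(folds=folds)
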