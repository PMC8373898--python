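"""Atlas-region super learner: nested CV over regions as a hyperparameter.

The primary analysis treats each parcellation region (which voxels feed the
classifier) as a hyperparameter of a boosted-logistic model, tuned jointly
with the AdaBoost/logistic grid by subject-level nested cross-validation:

* outer 5-fold CV splits *subjects* (stratified by diagnostic group) into
  train/test — a subject's time points never straddle the boundary;
* inner 5-fold CV over the outer-training subjects scores every
  (region, grid point) by subject-level accuracy after majority voting the
  per-time-point predictions;
* the winning configuration is refit on the full outer-training set and
  outer-test subjects are labeled by majority vote over their time points.

Alongside the subject predictions the search returns a region ranking:
each region's best inner-CV accuracy averaged over outer folds, with the
standard error across folds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .volume_io import TimePointDataset, WHOLE_BRAIN

__all__ = [
    "HyperGrid",
    "CVResult",
    "RegionRanking",
    "fit_boosted_logistic",
    "majority_vote",
    "nested_region_search",
    "classification_metrics",
    "accuracy_by_covariate",
]


@dataclass(frozen=True)
class HyperGrid:
    """Candidate AdaBoost/logistic settings (defaults: the full study grid).

    ``max_iterations`` caps the logistic weak learner's optimizer (the
    boosting rounds are ``n_estimators``); ``penalty``/``C`` regularize the
    weak learner.
    """

    n_estimators: tuple[int, ...] = (10, 50, 100, 150)
    learning_rate: tuple[float, ...] = (0.05, 1.0, 2.0)
    max_iterations: tuple[int, ...] = (100, 500, 1000)
    penalty: tuple[str, ...] = ("l1", "l2", "none")
    C: tuple[float, ...] = (0.5, 1.0, 2.0)

    def __post_init__(self) -> None:
        for name in ("n_estimators", "learning_rate", "max_iterations", "penalty", "C"):
            if not getattr(self, name):
                raise ValueError(f"hyper-grid axis {name} must be non-empty")
        bad = set(self.penalty) - {"l1", "l2", "none"}
        if bad:
            raise ValueError(f"unknown penalties: {sorted(bad)}")

    @classmethod
    def reduced(cls) -> "HyperGrid":
        """One mid-grid point — the cheap search used for calibration runs."""
        return cls(
            n_estimators=(10,),
            learning_rate=(1.0,),
            max_iterations=(100,),
            penalty=("l2",),
            C=(1.0,),
        )

    def points(self) -> list[dict]:
        """Grid points in a deterministic order (each axis ascending)."""
        return [
            dict(
                n_estimators=n, learning_rate=lr, max_iterations=mi, penalty=p, C=c
            )
            for n, lr, mi, p, c in itertools.product(
                sorted(self.n_estimators),
                sorted(self.learning_rate),
                sorted(self.max_iterations),
                self.penalty,
                sorted(self.C),
            )
        ]


@dataclass
class CVResult:
    """Outer-CV subject-level predictions and metrics of the super learner."""

    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    timepoint_preds: dict[str, np.ndarray]  # subject -> (T,) labels
    fold_of: dict[str, int]
    fold_train_subjects: dict[int, list[str]]  # leakage audit trail
    chosen: dict[int, dict]  # fold -> {"region_id": ..., **params, "inner_acc": ...}
    metrics: dict
    fold_metrics: pd.DataFrame

    def subject_timepoint_accuracy(self, subject_id: str) -> float:
        """Fraction of this subject's time points predicted as its true group."""
        i = self.subject_ids.index(subject_id)
        return float(np.mean(self.timepoint_preds[subject_id] == self.y_true[i]))


@dataclass
class RegionRanking:
    """Per-region mean inner-CV accuracy (over outer folds) with SE, sorted."""

    table: pd.DataFrame  # columns: region_id, mean_acc, ste, sorted desc

    def top(self, n: int = 1) -> list[int]:
        return [int(r) for r in self.table["region_id"].head(n)]


def _make_base_learner(penalty: str, C: float, max_iterations: int) -> LogisticRegression:
    if penalty == "none":
        return LogisticRegression(C=np.inf, max_iter=max_iterations, solver="lbfgs")
    if penalty == "l1":
        return LogisticRegression(
            C=C, l1_ratio=1.0, max_iter=max_iterations, solver="liblinear"
        )
    return LogisticRegression(C=C, max_iter=max_iterations, solver="lbfgs")


def fit_boosted_logistic(
    X: np.ndarray,
    y: Sequence,
    n_estimators: int = 50,
    learning_rate: float = 1.0,
    max_iterations: int = 100,
    penalty: str = "l2",
    C: float = 1.0,
    seed: int = 0,
):
    """Fit an adaptive-boosting ensemble of regularized logistic learners.

    Boosting sequentially reweights misclassified time points; the weak
    learner is a logistic model with the given penalty/C and optimizer
    iteration cap. With ``n_estimators=1`` the ensemble's predictions reduce
    to the bare weak learner's.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2D matrix with at least one feature")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("need two classes to fit a classifier")
    clf = AdaBoostClassifier(
        estimator=_make_base_learner(penalty, C, max_iterations),
        n_estimators=n_estimators,
        learning_rate=learning_rate,
        random_state=seed,
    )
    try:
        clf.fit(X, y)
    except ValueError as exc:
        if "worse than random" not in str(exc):
            raise
        # boosting terminates immediately when the first weak learner is no
        # better than random (featureless regions); keep the bare learner
        clf = _make_base_learner(penalty, C, max_iterations)
        clf.fit(X, y)
    return clf


def majority_vote(timepoint_preds: Sequence) -> str:
    """Most frequent label over a subject's time points.

    With the study's odd T=35 a binary tie is impossible; a general tie is
    broken toward the lexicographically smallest label for determinism.
    """
    preds = np.asarray(timepoint_preds)
    if preds.size == 0:
        raise ValueError("cannot vote over an empty prediction vector")
    labels, counts = np.unique(preds, return_counts=True)  # labels sorted
    return labels[np.argmax(counts)]


def classification_metrics(y_true: Sequence, y_pred: Sequence) -> dict:
    """Accuracy plus macro- and per-class precision/recall/F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = sorted(set(y_true) | set(y_pred))
    p, r, f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    pc, rc, fc, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=None, zero_division=0
    )
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "precision": float(p),
        "recall": float(r),
        "f1": float(f),
        "per_class": {
            str(lab): {
                "precision": float(pc[i]),
                "recall": float(rc[i]),
                "f1": float(fc[i]),
                "support": int(support[i]),
            }
            for i, lab in enumerate(labels)
        },
    }


def _stack_rows(
    ds: TimePointDataset, subj_idx: np.ndarray, region_id: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stack (T x V_r) blocks of the given subjects into rows + group labels."""
    block = ds.region_view(region_id)[subj_idx]  # (n, T, V_r)
    n, t, v = block.shape
    X = block.reshape(n * t, v)
    y = np.repeat(ds.group_labels[subj_idx], t)
    return X, y


def _score_subjects(
    clf, ds: TimePointDataset, subj_idx: np.ndarray, region_id: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Majority-vote subject predictions (and per-time-point ones)."""
    block = ds.region_view(region_id)[subj_idx]
    n, t, v = block.shape
    tp_preds = clf.predict(block.reshape(n * t, v)).reshape(n, t)
    votes = np.array([majority_vote(tp_preds[i]) for i in range(n)])
    return votes, [tp_preds[i] for i in range(n)]


def nested_region_search(
    ds: TimePointDataset,
    grid: HyperGrid | None = None,
    outer_k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
    include_whole_brain: bool = False,
    region_ids: Sequence[int] | None = None,
    inner_metric: str = "subject",
    search: str = "joint",
) -> tuple[CVResult, RegionRanking]:
    """Nested subject-level CV over (region x hyper-grid); returns
    subject predictions and the region ranking.

    ``inner_metric`` scores inner folds at the ``"subject"`` level
    (post-majority-vote, the headline metric) or ``"timepoint"`` level.
    ``search="staged"`` ranks regions at the first grid point only, then
    tunes the grid on the winning region — a cheaper approximation of the
    joint search. Ties break toward the lowest region id, then the earliest
    grid point (smallest n_estimators first).
    """
    grid = grid or HyperGrid()
    if inner_metric not in ("subject", "timepoint"):
        raise ValueError("inner_metric must be 'subject' or 'timepoint'")
    if search not in ("joint", "staged"):
        raise ValueError("search must be 'joint' or 'staged'")
    n_subjects = ds.n_subjects
    if n_subjects < outer_k:
        raise ValueError("fewer subjects than outer folds")
    regions = list(region_ids) if region_ids is not None else sorted(ds.region_index)
    for rid in regions:
        if rid != WHOLE_BRAIN and ds.region_view(rid).shape[2] == 0:
            raise ValueError(f"region {rid} has zero voxels")
    if include_whole_brain:
        regions = regions + [WHOLE_BRAIN]
    points = grid.points()

    rng = np.random.RandomState(seed)
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=rng.randint(2**31 - 1))
    all_idx = np.arange(n_subjects)
    groups = ds.group_labels

    y_pred = np.empty(n_subjects, dtype=object)
    timepoint_preds: dict[str, np.ndarray] = {}
    fold_of: dict[str, int] = {}
    fold_train_subjects: dict[int, list[str]] = {}
    chosen: dict[int, dict] = {}
    ranking_acc: dict[int, list[float]] = {rid: [] for rid in regions}
    fold_rows = []

    for fold, (tr_idx, te_idx) in enumerate(outer.split(all_idx, groups)):
        assert not set(tr_idx) & set(te_idx)
        inner = StratifiedKFold(
            n_splits=inner_k, shuffle=True, random_state=rng.randint(2**31 - 1)
        )
        inner_splits = list(inner.split(tr_idx, groups[tr_idx]))

        def inner_score(rid: int, params: dict) -> float:
            accs = []
            for in_tr, in_va in inner_splits:
                itr, iva = tr_idx[in_tr], tr_idx[in_va]
                X, y = _stack_rows(ds, itr, rid)
                clf = fit_boosted_logistic(X, y, seed=seed, **params)
                if inner_metric == "subject":
                    votes, _ = _score_subjects(clf, ds, iva, rid)
                    accs.append(np.mean(votes == groups[iva]))
                else:
                    Xv, yv = _stack_rows(ds, iva, rid)
                    accs.append(np.mean(clf.predict(Xv) == yv))
            return float(np.mean(accs))

        # region scores at their best grid point (for ranking + selection)
        best_for_region: dict[int, tuple[float, dict]] = {}
        search_points = points if search == "joint" else points[:1]
        for rid in regions:
            best = (-1.0, points[0])
            for params in search_points:
                acc = inner_score(rid, params)
                if acc > best[0]:
                    best = (acc, params)
            best_for_region[rid] = best
            ranking_acc[rid].append(best[0])

        best_rid = min(
            regions, key=lambda r: (-best_for_region[r][0], r if r != WHOLE_BRAIN else np.inf)
        )
        best_acc, best_params = best_for_region[best_rid]
        if search == "staged" and len(points) > 1:
            for params in points[1:]:
                acc = inner_score(best_rid, params)
                if acc > best_acc:
                    best_acc, best_params = acc, params

        X, y = _stack_rows(ds, tr_idx, best_rid)
        clf = fit_boosted_logistic(X, y, seed=seed, **best_params)
        votes, tp = _score_subjects(clf, ds, te_idx, best_rid)
        for j, si in enumerate(te_idx):
            sid = ds.subject_ids[si]
            y_pred[si] = votes[j]
            timepoint_preds[sid] = tp[j]
            fold_of[sid] = fold
        fold_train_subjects[fold] = [ds.subject_ids[i] for i in tr_idx]
        chosen[fold] = {"region_id": int(best_rid), "inner_acc": best_acc, **best_params}
        fm = classification_metrics(groups[te_idx], votes)
        fold_rows.append(
            {"fold": fold, **{k: fm[k] for k in ("accuracy", "precision", "recall", "f1")}}
        )

    y_pred = y_pred.astype(str)
    metrics = classification_metrics(groups, y_pred)
    fold_metrics = pd.DataFrame(fold_rows)
    for key in ("accuracy", "precision", "recall", "f1"):
        vals = fold_metrics[key].to_numpy()
        metrics[f"{key}_ste"] = float(vals.std(ddof=1) / np.sqrt(len(vals)))

    rows = []
    for rid in regions:
        accs = np.asarray(ranking_acc[rid])
        rows.append(
            {
                "region_id": rid,
                "mean_acc": float(accs.mean()),
                "ste": float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["mean_acc", "region_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )

    result = CVResult(
        subject_ids=list(ds.subject_ids),
        y_true=groups.copy(),
        y_pred=y_pred,
        timepoint_preds=timepoint_preds,
        fold_of=fold_of,
        fold_train_subjects=fold_train_subjects,
        chosen=chosen,
        metrics=metrics,
        fold_metrics=fold_metrics,
    )
    return result, RegionRanking(table=table)


def accuracy_by_covariate(
    result: CVResult,
    covariate: Mapping[str, object] | Callable[[str], object],
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-category mean subject accuracy with percentile-bootstrap 95% CI.

    A subject's accuracy is the fraction of its time points predicted as
    its true group (the reporting convention behind per-age / per-site /
    per-subtype summaries). Categories are bootstrap-resampled over
    subjects (2000 draws, seeded).
    """
    get = covariate.__getitem__ if isinstance(covariate, Mapping) else covariate
    if isinstance(covariate, Mapping):
        unknown = set(covariate) - set(result.subject_ids)
        if unknown:
            raise KeyError(f"unknown subjects in covariate map: {sorted(unknown)}")
        missing = set(result.subject_ids) - set(covariate)
        if missing:
            raise KeyError(f"covariate undefined for subjects: {sorted(missing)}")
    accs = pd.Series(
        {sid: result.subject_timepoint_accuracy(sid) for sid in result.subject_ids}
    )
    cats = pd.Series({sid: get(sid) for sid in result.subject_ids})
    rng = np.random.default_rng(seed)
    rows = []
    for cat in sorted(cats.unique(), key=str):
        vals = accs[cats == cat].to_numpy()
        boots = vals[rng.integers(0, len(vals), size=(n_boot, len(vals)))].mean(axis=1)
        rows.append(
            {
                "category": cat,
                "n_subjects": len(vals),
                "mean_accuracy": float(vals.mean()),
                "ci_low": float(np.percentile(boots, 2.5)),
                "ci_high": float(np.percentile(boots, 97.5)),
            }
        )
    return pd.DataFrame(rows)
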