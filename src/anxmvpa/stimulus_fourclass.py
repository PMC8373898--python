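"""Fearful-vs-angry decoding in the aligned space, and the coupled
four-class (group x stimulus) ensemble.

The stimulus decoder trains a linear max-margin classifier on region
voxels, either raw (``align=False``) or after shared-response-model
alignment (``align=True``): the SRM is fit on the training subjects only,
test subjects are mapped in through the orthogonal-Procrustes estimate of
their subject map against the frozen shared response. Folds split by
subject; there is no inner CV and no majority vote — every time point is
predicted individually.

The four-class model composes each time point's predicted group (from the
region super learner, broadcast over the subject's time points) with its
predicted stimulus, scoring against the true (group, stimulus) pair with
balanced accuracy (the unweighted mean of the four per-class recalls) and
a one-way ANOVA across the classes' fold-wise precisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import KFold
from sklearn.svm import LinearSVC

from .region_superlearner import classification_metrics
from .shared_response import estimate_new_subject, fit_srm
from .volume_io import TimePointDataset

__all__ = [
    "StimulusCVResult",
    "FourClassResult",
    "decode_stimulus_cv",
    "combine_fourclass",
    "precision_anova",
    "FOUR_CLASSES",
]

#: Canonical four-class labels (group x stimulus).
FOUR_CLASSES = (
    "anxious_fear",
    "anxious_anger",
    "control_fear",
    "control_anger",
)


def _fourclass_label(group: str, stimulus: str) -> str:
    g = "anxious" if group == "anxious" else "control"
    return f"{g}_{stimulus}"


@dataclass
class StimulusCVResult:
    """Per-time-point stimulus predictions from subject-level k-fold CV."""

    predictions: np.ndarray  # (n_subjects, T) predicted condition
    fold_of: dict[str, int]
    fold_train_subjects: dict[int, list[str]]  # leakage audit trail
    aligned: bool
    metrics: dict
    fold_metrics: pd.DataFrame
    subject_ids: list[str]


@dataclass
class FourClassResult:
    """Coupled group x stimulus predictions and their metrics."""

    predictions: np.ndarray  # (n_subjects, T) four-class labels
    truth: np.ndarray  # (n_subjects, T)
    balanced_accuracy: float
    metrics: dict
    per_fold_class_precision: pd.DataFrame  # index: class, columns: fold
    anova_F: float
    anova_p: float


def decode_stimulus_cv(
    ds: TimePointDataset,
    region_id: int,
    k: int = 10,
    folds: int = 5,
    align: bool = True,
    C: float = 1.0,
    seed: int = 0,
    srm_method: str = "deterministic",
) -> StimulusCVResult:
    """Cross-validated fear/anger decoding on one region's voxels.

    Folds split by subject. With ``align=True`` an SRM with ``k`` shared
    features is fit on the training subjects of each fold and test subjects
    enter the space through :func:`estimate_new_subject`; with
    ``align=False`` the classifier sees raw voxel features, so any
    cross-subject transfer must survive subject-specific topography.
    """
    conditions = set(ds.stimulus_labels)
    if len(conditions) < 2:
        raise ValueError("need both stimulus conditions to decode")
    block = ds.region_view(region_id)  # (n, T, V)
    n, T, V = block.shape
    if align and k >= V:
        raise ValueError(f"k={k} must be below the region voxel count {V}")
    if n < folds:
        raise ValueError("fewer subjects than folds")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty((n, T), dtype=object)
    fold_of: dict[str, int] = {}
    fold_train_subjects: dict[int, list[str]] = {}
    fold_rows = []
    y_tp = ds.stimulus_labels

    for fold, (tr_idx, te_idx) in enumerate(kf.split(np.arange(n))):
        assert not set(tr_idx) & set(te_idx)
        if align:
            space = fit_srm(
                [block[i].T for i in tr_idx], k=k, seed=seed, method=srm_method
            )
            X_tr = np.vstack([(space.W[j].T @ (block[i].T - space.means[j][:, None])).T
                              for j, i in enumerate(tr_idx)])
            X_te_parts = []
            for i in te_idx:
                w_new, mean_new = estimate_new_subject(space, block[i].T)
                X_te_parts.append((w_new.T @ (block[i].T - mean_new[:, None])).T)
            X_te = np.vstack(X_te_parts)
        else:
            X_tr = block[tr_idx].reshape(len(tr_idx) * T, V)
            X_te = block[te_idx].reshape(len(te_idx) * T, V)
        y_tr = np.tile(y_tp, len(tr_idx))
        y_te = np.tile(y_tp, len(te_idx))
        clf = LinearSVC(C=C, random_state=seed)
        clf.fit(X_tr, y_tr)
        y_hat = clf.predict(X_te)
        for j, i in enumerate(te_idx):
            sid = ds.subject_ids[i]
            preds[i] = y_hat[j * T : (j + 1) * T]
            fold_of[sid] = fold
        fold_train_subjects[fold] = [ds.subject_ids[i] for i in tr_idx]
        fm = classification_metrics(y_te, y_hat)
        fm["balanced_accuracy"] = float(balanced_accuracy_score(y_te, y_hat))
        fold_rows.append(
            {
                "fold": fold,
                **{
                    kk: fm[kk]
                    for kk in ("accuracy", "balanced_accuracy", "precision", "recall", "f1")
                },
            }
        )

    preds = preds.astype(str)
    flat_true = np.tile(y_tp, n)
    flat_pred = preds.reshape(-1)
    metrics = classification_metrics(flat_true, flat_pred)
    metrics["balanced_accuracy"] = float(balanced_accuracy_score(flat_true, flat_pred))
    fold_metrics = pd.DataFrame(fold_rows)
    for key in ("accuracy", "balanced_accuracy", "precision", "recall", "f1"):
        vals = fold_metrics[key].to_numpy()
        metrics[f"{key}_ste"] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return StimulusCVResult(
        predictions=preds,
        fold_of=fold_of,
        fold_train_subjects=fold_train_subjects,
        aligned=align,
        metrics=metrics,
        fold_metrics=fold_metrics,
        subject_ids=list(ds.subject_ids),
    )


def combine_fourclass(
    group_preds: Mapping[str, str],
    stim_result: StimulusCVResult,
    ds: TimePointDataset,
) -> FourClassResult:
    """Couple subject-level group predictions with per-time-point stimulus
    predictions into the four-class model.

    Each time point's prediction is (its subject's predicted group) x (its
    predicted stimulus); truth is the subject's true group x the presented
    stimulus. Balanced accuracy is the unweighted mean of the four
    per-class recalls. Fold-wise per-class precisions (folds inherited from
    the stimulus CV) feed a one-way ANOVA across classes.
    """
    if set(stim_result.subject_ids) != set(ds.subject_ids):
        raise ValueError("stimulus result does not cover the dataset's subjects")
    missing = set(ds.subject_ids) - set(group_preds)
    if missing:
        raise ValueError(f"group predictions missing subjects: {sorted(missing)}")
    n, T = len(ds.subject_ids), ds.n_timepoints
    pred = np.empty((n, T), dtype=object)
    true = np.empty((n, T), dtype=object)
    for i, sid in enumerate(ds.subject_ids):
        si = stim_result.subject_ids.index(sid)
        for t in range(T):
            pred[i, t] = _fourclass_label(group_preds[sid], stim_result.predictions[si, t])
            true[i, t] = _fourclass_label(ds.group_labels[i], ds.stimulus_labels[t])
    flat_pred, flat_true = pred.reshape(-1), true.reshape(-1)
    metrics = classification_metrics(flat_true, flat_pred)
    recalls = [metrics["per_class"].get(c, {"recall": 0.0})["recall"] for c in FOUR_CLASSES]
    balanced = float(np.mean(recalls))

    folds = sorted(set(stim_result.fold_of.values()))
    prec = pd.DataFrame(index=list(FOUR_CLASSES), columns=folds, dtype=float)
    for fold in folds:
        sids = [s for s, f in stim_result.fold_of.items() if f == fold]
        idx = [ds.subject_ids.index(s) for s in sids]
        fm = classification_metrics(true[idx].reshape(-1), pred[idx].reshape(-1))
        for c in FOUR_CLASSES:
            prec.loc[c, fold] = fm["per_class"].get(c, {"precision": np.nan})["precision"]
    F, p = precision_anova(prec.to_numpy())
    return FourClassResult(
        predictions=pred.astype(str),
        truth=true.astype(str),
        balanced_accuracy=balanced,
        metrics=metrics,
        per_fold_class_precision=prec,
        anova_F=F,
        anova_p=p,
    )


def precision_anova(per_fold_class_precisions: np.ndarray) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across classes' fold-wise precisions.

    Rows are classes, columns folds. Returns (F, p). Requires at least two
    finite values per class.
    """
    mat = np.asarray(per_fold_class_precisions, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a classes x folds matrix with >= 2 folds")
    groups = [row[np.isfinite(row)] for row in mat]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each class needs at least 2 fold-wise values")
    if all(np.allclose(g, groups[0][0]) for g in groups):
        return 0.0, 1.0
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)
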