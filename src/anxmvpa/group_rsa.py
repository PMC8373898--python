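"""Condition beta estimation and grouped representational comparison.

Per subject and voxel, the task time points of a region are regressed on
condition indicator columns (fear, anger), giving a beta — the estimated
condition-evoked response — per condition per voxel. Group-level contrasts
then compare the distribution of per-voxel group-mean betas between
anxious and non-anxious children with a two-tailed Mann–Whitney U test
(no normality assumption), and summarize condition pattern (dis)similarity
in a per-group representational dissimilarity matrix (1 - Pearson r).

This is the ordinary-least-squares simplification of a grouped Bayesian
representational similarity analysis: the betas here come from OLS (with
an optional ridge term) rather than a hierarchical covariance model; the
downstream group test is the same.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import TASK_CONDITIONS, TimePointDataset

__all__ = [
    "BetaMaps",
    "GroupComparison",
    "estimate_betas",
    "mann_whitney_u",
    "compare_groups_mwu",
    "build_rsm",
]


@dataclass
class BetaMaps:
    """Per-subject condition x voxel regression coefficients for one region."""

    betas: np.ndarray  # (n_subjects, n_conditions, V)
    conditions: tuple[str, ...]
    design: np.ndarray  # (T, n_conditions) indicators
    residual_var: np.ndarray  # (n_subjects, V)
    subject_ids: list[str]
    group_labels: np.ndarray
    region_id: int


@dataclass
class GroupComparison:
    """Two-sample Mann–Whitney comparison of per-voxel group-mean betas."""

    U: float
    p_two_sided: float
    n1: int
    n2: int
    group1: str
    group2: str
    group_means: dict[str, np.ndarray]  # group -> per-voxel mean beta
    method: str  # "exact" or "asymptotic"


def estimate_betas(
    ds: TimePointDataset, region_id: int, ridge: float = 0.0
) -> BetaMaps:
    """Least-squares condition betas per subject and voxel.

    The design is the T x 2 indicator matrix of (fear, anger). Since the
    indicators are orthogonal, the OLS betas equal the per-condition means
    of each voxel's standardized signal. ``ridge`` adds an optional L2 term
    (default 0 — plain OLS).
    """
    Y = ds.region_view(region_id)  # (n, T, V)
    n, T, V = Y.shape
    D = np.stack(
        [(ds.stimulus_labels == c).astype(float) for c in TASK_CONDITIONS], axis=1
    )
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise ValueError("rank-deficient design: a condition has no time points")
    G = D.T @ D + ridge * np.eye(D.shape[1])
    coef = np.linalg.solve(G, D.T)  # (2, T)
    betas = np.einsum("ct,ntv->ncv", coef, Y)
    resid = Y - np.einsum("tc,ncv->ntv", D, betas)
    dof = max(T - rank, 1)
    residual_var = np.sum(resid**2, axis=1) / dof
    return BetaMaps(
        betas=betas,
        conditions=TASK_CONDITIONS,
        design=D,
        residual_var=residual_var,
        subject_ids=list(ds.subject_ids),
        group_labels=ds.group_labels.copy(),
        region_id=region_id,
    )


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for sample x: #{(a, b): a > b} + half-ties.

    Computed from midranks, which is exactly pair counting with ties
    contributing 1/2 each.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def compare_groups_mwu(
    betas: BetaMaps,
    group1: str = "anxious",
    group2: str = "non_anxious",
) -> GroupComparison:
    """Two-tailed Mann–Whitney U on per-voxel group-mean betas.

    Each group contributes one value per voxel: the beta averaged over the
    group's subjects and over the two conditions (the region voxel count
    sets the sample sizes). U is reported for ``group1``. The p-value uses
    exact enumeration when ``n1*n2 <= 10000`` and the data is tie-free,
    otherwise the tie-corrected normal approximation.
    """
    masks = {g: betas.group_labels == g for g in (group1, group2)}
    for g, m in masks.items():
        if not m.any():
            raise ValueError(f"group {g!r} is empty")
    means = {
        g: betas.betas[m].mean(axis=(0, 1)) for g, m in masks.items()
    }  # per-voxel, averaged over subjects then conditions
    x, y = means[group1], means[group2]
    U = mann_whitney_u(x, y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("all beta values tied; p set to 1", stacklevel=2)
        p, method = 1.0, "asymptotic"
    elif x.size * y.size <= 10_000 and not has_ties:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
        method = "asymptotic"
    return GroupComparison(
        U=U,
        p_two_sided=p,
        n1=x.size,
        n2=y.size,
        group1=group1,
        group2=group2,
        group_means=means,
        method=method,
    )


def build_rsm(betas: BetaMaps, metric: str = "pearson_dissimilarity") -> dict[str, pd.DataFrame]:
    """Per-group condition x condition dissimilarity matrix (1 - Pearson r).

    Patterns are the group-mean beta vectors per condition over the
    region's voxels. Symmetric, zero diagonal; a zero-variance pattern
    makes the entry undefined (NaN, with a warning).
    """
    if metric != "pearson_dissimilarity":
        raise ValueError(f"unknown metric {metric!r}")
    conds = betas.conditions
    if len(conds) < 2:
        raise ValueError("need at least two conditions")
    out: dict[str, pd.DataFrame] = {}
    for g in np.unique(betas.group_labels):
        mask = betas.group_labels == g
        patterns = betas.betas[mask].mean(axis=0)  # (n_conditions, V)
        mat = np.zeros((len(conds), len(conds)))
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                a, b = patterns[i], patterns[j]
                if a.std() == 0 or b.std() == 0:
                    warnings.warn(
                        f"zero-variance pattern in group {g}; RSM entry undefined",
                        stacklevel=2,
                    )
                    d = np.nan
                else:
                    d = 1.0 - float(np.corrcoef(a, b)[0, 1])
                mat[i, j] = mat[j, i] = d
        out[str(g)] = pd.DataFrame(mat, index=list(conds), columns=list(conds))
    return out
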