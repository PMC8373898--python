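"""Shared response model (SRM): functional alignment across subjects.

The SRM factorizes each subject's region data ``X_i`` (V_i voxels x T time
points, temporally aligned across subjects) as ``X_i ~ W_i S`` with a
subject-specific orthonormal map ``W_i`` (V_i x k, k << V_i) and a shared
response ``S`` (k x T) common to all subjects. Projecting through ``W_i^T``
moves every subject into the same low-dimensional feature space, which is
what makes cross-subject stimulus decoding possible.

Two engines share one contract:

* ``deterministic`` (default): alternating minimization of
  ``sum_i ||X_i - W_i S||_F^2`` — S by averaging ``W_i^T X_i``, W_i by the
  orthogonal Procrustes solution of ``X_i S^T``. The objective trace is
  non-increasing by construction.
* ``probabilistic``: EM for the generative model
  ``x_t^i = W_i s_t + mu_i + N(0, sigma_i^2 I)``, ``s_t ~ N(0, Sigma_s)``,
  reporting per-subject noise variances; the trace is the (monotone)
  negative log-likelihood.

The shared space is identifiable only up to a k x k orthogonal transform,
so recovery comparisons must align estimates first (see tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SharedSpace",
    "fit_srm",
    "transform",
    "estimate_new_subject",
    "save_shared_space",
    "load_shared_space",
]


@dataclass
class SharedSpace:
    """A fitted shared response model."""

    k: int
    W: list[np.ndarray]  # per subject, (V_i, k), orthonormal columns
    S: np.ndarray  # (k, T)
    means: list[np.ndarray]  # per subject, (V_i,) voxel means removed at fit
    objective_trace: list[float]
    converged: bool
    method: str = "deterministic"
    noise_vars: list[float] | None = None  # probabilistic engine only

    @property
    def n_subjects(self) -> int:
        return len(self.W)

    @property
    def n_timepoints(self) -> int:
        return self.S.shape[1]


def _check_inputs(X: list[np.ndarray], k: int) -> list[np.ndarray]:
    if not X:
        raise ValueError("need at least one subject")
    X = [np.asarray(x, dtype=float) for x in X]
    T = X[0].shape[1]
    for i, x in enumerate(X):
        if x.ndim != 2:
            raise ValueError("each X_i must be a (V_i, T) matrix")
        if x.shape[1] != T:
            raise ValueError("all subjects must share the time dimension T")
        if not np.isfinite(x).all():
            raise ValueError(f"subject {i} has non-finite values")
        if k > x.shape[0]:
            raise ValueError(
                f"k={k} exceeds subject {i}'s voxel count {x.shape[0]}"
            )
    return X


def _random_orthonormal(rng: np.random.Generator, v: int, k: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((v, k)))
    return q * np.sign(np.diag(r))


def _procrustes(A: np.ndarray) -> np.ndarray:
    """Orthonormal-column matrix nearest to A: U V^T from its thin SVD."""
    u, _, vt = np.linalg.svd(A, full_matrices=False)
    return u @ vt


def _objective(X: list[np.ndarray], W: list[np.ndarray], S: np.ndarray) -> float:
    return float(sum(np.linalg.norm(x - w @ S, "fro") ** 2 for x, w in zip(X, W)))


def fit_srm(
    X: list[np.ndarray],
    k: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    method: str = "deterministic",
) -> SharedSpace:
    """Fit the shared response model on training subjects.

    ``X`` holds per-subject (V_i x T) matrices over the same T aligned time
    points. Data is column-centered internally (per-voxel means stored and
    reapplied at transform). Iteration stops when the relative objective
    change drops below ``tol`` or after ``max_iter`` rounds. Initialization
    is seeded random orthonormal maps.
    """
    if method not in ("deterministic", "probabilistic"):
        raise ValueError("method must be 'deterministic' or 'probabilistic'")
    X = _check_inputs(X, k)
    means = [x.mean(axis=1) for x in X]
    Xc = [x - m[:, None] for x, m in zip(X, means)]
    rng = np.random.default_rng(seed)
    W = [_random_orthonormal(rng, x.shape[0], k) for x in Xc]
    if method == "deterministic":
        W, S, trace, converged = _fit_deterministic(Xc, W, max_iter, tol)
        noise = None
    else:
        W, S, trace, converged, noise = _fit_probabilistic(Xc, W, max_iter, tol)
    return SharedSpace(
        k=k,
        W=W,
        S=S,
        means=means,
        objective_trace=trace,
        converged=converged,
        method=method,
        noise_vars=noise,
    )


def _fit_deterministic(Xc, W, max_iter, tol):
    n = len(Xc)
    S = sum(w.T @ x for w, x in zip(W, Xc)) / n
    trace = [_objective(Xc, W, S)]
    converged = False
    for _ in range(max_iter):
        W = [_procrustes(x @ S.T) for x in Xc]
        S = sum(w.T @ x for w, x in zip(W, Xc)) / n
        trace.append(_objective(Xc, W, S))
        prev, cur = trace[-2], trace[-1]
        if prev - cur <= tol * max(prev, 1e-12):
            converged = True
            break
    return W, S, trace, converged


def _fit_probabilistic(Xc, W, max_iter, tol):
    """EM with per-subject isotropic noise and a learned shared covariance."""
    n = len(Xc)
    k = W[0].shape[1]
    T = Xc[0].shape[1]
    V = [x.shape[0] for x in Xc]
    normsq = [float(np.sum(x * x)) for x in Xc]
    # noise-variance floor keeps the likelihood bounded when data is noiseless
    floor = max(1e-8 * float(np.mean([ns / (v * T) for ns, v in zip(normsq, V)])), 1e-12)
    rho2 = np.ones(n)
    sigma_s = np.eye(k)
    trace = []
    converged = False
    ES = None
    for _ in range(max_iter):
        # E-step: posterior of the shared response at each time point
        c = float(np.sum(1.0 / rho2))
        sigma_inv = np.linalg.inv(sigma_s)
        Vs = np.linalg.inv(sigma_inv + c * np.eye(k))
        M = sum((w.T @ x) / r for w, x, r in zip(W, Xc, rho2))  # (k, T)
        ES = Vs @ M

        # negative log-likelihood of the current parameters (monotone)
        sign, logdet_sig = np.linalg.slogdet(np.eye(k) + c * sigma_s)
        logdet = float(sum(v * np.log(r) for v, r in zip(V, rho2))) + logdet_sig
        quad = (
            sum(ns / r for ns, r in zip(normsq, rho2)) - float(np.sum(M * (Vs @ M)))
        ) / T
        vtot = sum(V)
        nll = 0.5 * T * (vtot * np.log(2 * np.pi) + logdet + quad)
        trace.append(float(nll))
        if len(trace) > 1 and trace[-2] - trace[-1] <= tol * max(abs(trace[-2]), 1e-12):
            converged = True
            break

        # M-step
        Ess = T * Vs + ES @ ES.T  # sum_t E[s_t s_t^T]
        W = [_procrustes(x @ ES.T) for x in Xc]
        rho2 = np.array(
            [
                max(
                    (ns - 2.0 * float(np.sum(w * (x @ ES.T))) + float(np.trace(Ess)))
                    / (T * v),
                    floor,
                )
                for ns, w, x, v in zip(normsq, W, Xc, V)
            ]
        )
        sigma_s = Ess / T
    return W, ES, trace, converged, [float(r) for r in rho2]


def transform(space: SharedSpace, X_new: np.ndarray, subject_index: int) -> np.ndarray:
    """Project new data from a fitted subject into the shared space.

    Returns ``W_i^T (X_new - mean_i)`` — the same centering as training.
    """
    if not 0 <= subject_index < space.n_subjects:
        raise KeyError(f"unknown subject index {subject_index}")
    X_new = np.asarray(X_new, dtype=float)
    w = space.W[subject_index]
    if X_new.shape[0] != w.shape[0]:
        raise ValueError(
            f"voxel count {X_new.shape[0]} does not match fitted {w.shape[0]}"
        )
    return w.T @ (X_new - space.means[subject_index][:, None])


def estimate_new_subject(
    space: SharedSpace, X_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate an orthonormal map for a subject not seen at fit time.

    Solves the orthogonal Procrustes problem ``min_W ||X_new - W S||`` for
    the existing shared response S (the new subject must cover the same T
    aligned time points). Returns ``(W_new, voxel_means)``; the shared
    response itself is left untouched, so no test-subject information leaks
    into the space.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != space.n_timepoints:
        raise ValueError("time dimension does not match the fitted S")
    mean = X_new.mean(axis=1)
    A = (X_new - mean[:, None]) @ space.S.T
    u, sv, vt = np.linalg.svd(A, full_matrices=False)
    if sv[-1] < 1e-10 * max(sv[0], 1.0):
        raise ValueError(
            "rank-deficient cross-product: the data cannot pin down all k "
            "directions — lower k"
        )
    return u @ vt, mean


def save_shared_space(space: SharedSpace, path: str | Path) -> None:
    """Serialize a shared space as a single .npz archive with a JSON manifest."""
    manifest = {
        "k": space.k,
        "converged": bool(space.converged),
        "method": space.method,
        "n_subjects": space.n_subjects,
        "noise_vars": space.noise_vars,
        "objective_trace": space.objective_trace,
    }
    arrays = {"S": space.S, "manifest": np.array(json.dumps(manifest))}
    for i, (w, m) in enumerate(zip(space.W, space.means)):
        arrays[f"W_{i}"] = w
        arrays[f"mean_{i}"] = m
    np.savez_compressed(path, **arrays)


def load_shared_space(path: str | Path) -> SharedSpace:
    with np.load(path, allow_pickle=False) as npz:
        manifest = json.loads(str(npz["manifest"]))
        n = manifest["n_subjects"]
        return SharedSpace(
            k=manifest["k"],
            W=[npz[f"W_{i}"] for i in range(n)],
            S=npz["S"],
            means=[npz[f"mean_{i}"] for i in range(n)],
            objective_trace=list(manifest["objective_trace"]),
            converged=manifest["converged"],
            method=manifest["method"],
            noise_vars=manifest["noise_vars"],
        )
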