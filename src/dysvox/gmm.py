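"""Diagonal-covariance Gaussian mixture models and EM fitting for UBMs.

A universal background model (UBM) is a GMM trained on frames pooled over a
reference cohort; its density is p(x | lambda) = sum_i w_i p_i(x) with
diagonal component covariances.  The EM loop here keeps a per-iteration
log-likelihood trace (monotone non-decreasing up to the variance floor),
re-seeds components that collapse to zero responsibility, and floors each
dimension's variance at a small fraction of the data variance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

M_GRID_DEFAULT = (2, 4, 8, 16, 32, 64, 128)
VARIANCE_FLOOR_FACTOR = 1e-4
EM_TOL = 1e-5
EM_MAX_ITER = 200


@dataclass
class GMMParams:
    """Mixture parameters lambda = {w_i, mu_i, Sigma_i} with diagonal Sigma."""

    weights: np.ndarray  # (M,)
    means: np.ndarray  # (M, D)
    variances: np.ndarray  # (M, D) diagonal covariances
    variance_floor: np.ndarray | float = 1e-10
    loglik_trace: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=np.float64))
        if self.means.shape != self.variances.shape:
            raise ValueError("means and variances must share shape (M, D)")
        if len(self.weights) != self.means.shape[0]:
            raise ValueError("weights length must equal component count")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def M(self) -> int:
        return self.means.shape[0]

    @property
    def D(self) -> int:
        return self.means.shape[1]


def _check_dims(X: np.ndarray, params: GMMParams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != params.D:
        raise ValueError(f"data dimension {X.shape[1]} != model dimension {params.D}")
    return X


def component_log_densities(X: np.ndarray, params: GMMParams) -> np.ndarray:
    """(T, M) matrix of log[w_i p_i(x_t)] computed in log space."""
    X = _check_dims(X, params)
    inv_var = 1.0 / params.variances  # (M, D)
    log_det = np.sum(np.log(params.variances), axis=1)  # (M,)
    # squared Mahalanobis distances via the expanded quadratic form
    quad = (
        (X**2) @ inv_var.T
        - 2.0 * X @ (params.means * inv_var).T
        + np.sum(params.means**2 * inv_var, axis=1)
    )
    log_norm = -0.5 * (params.D * np.log(2.0 * np.pi) + log_det)
    with np.errstate(divide="ignore"):
        log_w = np.log(params.weights)
    return log_w + log_norm - 0.5 * quad


def gmm_log_density(X: np.ndarray, params: GMMParams) -> np.ndarray:
    """Per-row log p(x_t | lambda) = log sum_i w_i p_i(x_t)."""
    return logsumexp(component_log_densities(X, params), axis=1)


def responsibilities(X: np.ndarray, params: GMMParams) -> np.ndarray:
    """Posterior Pr(i | x_t); rows sum to 1.

    If every component underflows for a frame, a uniform posterior is
    substituted with a warning.
    """
    single = np.asarray(X).ndim == 1
    log_joint = component_log_densities(X, params)
    total = logsumexp(log_joint, axis=1)
    bad = ~np.isfinite(total)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} frame(s) underflowed all components; "
            "using uniform posteriors",
            stacklevel=2,
        )
        log_joint[bad] = 0.0
        total[bad] = np.log(params.M)
    R = np.exp(log_joint - total[:, None])
    return R[0] if single else R


def em_fit(
    X: np.ndarray,
    M: int,
    seed: int = 0,
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
    variance_floor_factor: float = VARIANCE_FLOOR_FACTOR,
) -> GMMParams:
    """Fit an M-component diagonal GMM by EM.

    Initialization draws k-means++ centers (seeded) from a subsample; each
    dimension's variance is floored at ``variance_floor_factor`` times the
    data variance in that dimension.  Convergence: relative change of the
    mean log-likelihood below ``tol``.  Components whose soft count drops to
    ~0 are re-seeded at the frame with the lowest model density.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    T, D = X.shape
    if T < M:
        raise ValueError(f"need at least M={M} frames, got T={T}")
    rng = np.random.default_rng(seed)
    data_var = X.var(axis=0)
    floor = np.maximum(variance_floor_factor * data_var, 1e-12)

    if M == 1:
        params = GMMParams(
            np.ones(1),
            X.mean(axis=0, keepdims=True),
            np.maximum(X.var(axis=0, keepdims=True), floor),
            variance_floor=floor,
        )
        ll = float(gmm_log_density(X, params).mean())
        params.loglik_trace = np.array([ll])
        params.meta = {"seed": seed, "n_iter": 0, "converged": True}
        return params

    sub = X if T <= 5000 else X[rng.choice(T, 5000, replace=False)]
    centers, _ = kmeans_plusplus(
        sub, n_clusters=M, random_state=int(rng.integers(0, 2**31 - 1))
    )
    # hard-assignment initialization of weights and variances
    d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2) if T * M * D <= 2e7 else None
    if d2 is None:
        d2 = (
            (X**2).sum(1)[:, None]
            - 2 * X @ centers.T
            + (centers**2).sum(1)[None, :]
        )
    assign = np.argmin(d2, axis=1)
    weights = np.bincount(assign, minlength=M).astype(np.float64)
    weights = np.maximum(weights, 1.0)
    weights /= weights.sum()
    variances = np.empty((M, D))
    for i in range(M):
        pts = X[assign == i]
        variances[i] = pts.var(axis=0) if len(pts) > 1 else data_var
    variances = np.maximum(variances, floor)
    params = GMMParams(weights, centers, variances, variance_floor=floor)

    trace = []
    prev_ll = -np.inf
    for it in range(max_iter):
        log_joint = component_log_densities(X, params)
        total = logsumexp(log_joint, axis=1)
        trace.append(float(total.mean()))
        R = np.exp(log_joint - total[:, None])
        n = R.sum(axis=0)
        empty = n < 1e-8
        if np.any(empty):
            worst = np.argsort(total)[: int(empty.sum())]
            for j, i in zip(worst, np.nonzero(empty)[0]):
                params.means[i] = X[j]
                params.variances[i] = np.maximum(data_var, floor)
                params.weights[i] = 1.0 / T
            params.weights /= params.weights.sum()
            continue
        new_means = (R.T @ X) / n[:, None]
        new_vars = (R.T @ (X**2)) / n[:, None] - new_means**2
        new_vars = np.maximum(new_vars, floor)
        params = GMMParams(n / T, new_means, new_vars, variance_floor=floor)
        if prev_ll > -np.inf and abs(trace[-1] - prev_ll) < tol * abs(prev_ll):
            break
        prev_ll = trace[-1]
    trace.append(float(gmm_log_density(X, params).mean()))
    params.loglik_trace = np.asarray(trace)
    params.meta = {
        "seed": seed,
        "n_iter": len(trace) - 1,
        "converged": len(trace) - 1 < max_iter,
    }
    return params


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_gmm(params: GMMParams, path: str | Path, **metadata) -> None:
    """Write a model bundle: <path>.json (metadata) + <path>.npz (arrays)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path.with_suffix(".npz"),
        weights=params.weights,
        means=params.means,
        variances=params.variances,
        variance_floor=np.atleast_1d(params.variance_floor),
        loglik_trace=(
            params.loglik_trace if params.loglik_trace is not None else np.empty(0)
        ),
    )
    meta = {"M": params.M, "D": params.D, **params.meta, **metadata}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_gmm(path: str | Path) -> GMMParams:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    floor = arrays["variance_floor"]
    params = GMMParams(
        arrays["weights"],
        arrays["means"],
        arrays["variances"],
        variance_floor=floor if floor.size > 1 else float(floor[0]),
        loglik_trace=arrays["loglik_trace"] if arrays["loglik_trace"].size else None,
        meta=meta,
    )
    return params
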