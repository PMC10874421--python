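"""MAP adaptation of a UBM to a single recording and supervector assembly.

Given a UBM lambda = {w_i, mu_i, Sigma_i} and a recording's frames
X = {x_1..x_T}, adaptation proceeds in two steps: (1) compute the
Baum-Welch sufficient statistics n_i, E_i(x), E_i(x^2) from the frame
posteriors Pr(i|x_t); (2) interpolate each parameter between its UBM value
and the data estimate with the data-dependent adaptive coefficient
alpha_i = n_i / (n_i + r), where r is the relevance factor (default 16):

    w'_i      = [alpha_i n_i / T + (1 - alpha_i) w_i] * gamma
    mu'_i     = alpha_i E_i(x) + (1 - alpha_i) mu_i
    Sigma'_i  = alpha_i E_i(x^2) + (1 - alpha_i)(Sigma_i + mu_i^2) - mu'_i^2

with gamma renormalizing the weights to sum to 1.  The supervector for a
recording stacks the adapted means and diagonal covariances into a single
2*M*D vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix
from .gmm import GMMParams, responsibilities

RELEVANCE_FACTOR = 16.0

FUSION_ORDER = ("articulation", "phonation", "prosody")


@dataclass
class SufficientStats:
    """Soft counts and first/second moments of frames under a UBM."""

    n: np.ndarray  # (M,)
    first_moment: np.ndarray  # (M, D): E_i(x)
    second_moment: np.ndarray  # (M, D): E_i(x^2)
    T: int

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.float64)
        self.first_moment = np.atleast_2d(np.asarray(self.first_moment, np.float64))
        self.second_moment = np.atleast_2d(np.asarray(self.second_moment, np.float64))
        if np.any(self.n < 0):
            raise ValueError("soft counts must be nonnegative")
        if abs(self.n.sum() - self.T) > 1e-8 * max(self.T, 1):
            raise ValueError("soft counts must sum to the frame count")


@dataclass
class AdaptationConfig:
    """Relevance factor and which parameter groups to adapt."""

    relevance_factor: float = RELEVANCE_FACTOR
    adapt_weights: bool = True
    adapt_means: bool = True
    adapt_variances: bool = True

    def __post_init__(self) -> None:
        if self.relevance_factor <= 0:
            raise ValueError("relevance_factor must be positive")


@dataclass
class Supervector:
    """Stacked adapted means and diagonal covariances: length 2*M*D."""

    values: np.ndarray
    M: int
    D: int
    dimension_name: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != 2 * self.M * self.D:
            raise ValueError("supervector length must be 2*M*D")
        if np.any(self.values[self.M * self.D :] <= 0):
            raise ValueError("variance block must be strictly positive")


def adaptive_coefficient(n, relevance_factor: float = RELEVANCE_FACTOR):
    """alpha_i = n_i / (n_i + r): the data-vs-prior balance per component.

    Strictly increasing in the soft count n_i, equal to 1/2 exactly at
    n_i = r, and approaching 1 as a component accumulates data.
    """
    n = np.asarray(n, dtype=np.float64)
    if relevance_factor <= 0:
        raise ValueError("relevance_factor must be positive")
    return n / (n + relevance_factor)


def sufficient_stats(X: np.ndarray | FeatureMatrix, ubm: GMMParams) -> SufficientStats:
    """Baum-Welch statistics of X under the UBM.

    Components receiving zero posterior mass carry the UBM's own moments, so
    the subsequent update leaves them untouched (alpha_i = 0 there anyway).
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("cannot compute statistics of an empty feature matrix")
    R = responsibilities(X, ubm)  # (T, M)
    n = R.sum(axis=0)
    safe_n = np.where(n > 0, n, 1.0)
    first = (R.T @ X) / safe_n[:, None]
    second = (R.T @ (X**2)) / safe_n[:, None]
    zero = n == 0
    if np.any(zero):
        first[zero] = ubm.means[zero]
        second[zero] = ubm.variances[zero] + ubm.means[zero] ** 2
    return SufficientStats(n, first, second, T=X.shape[0])


def map_adapt(
    ubm: GMMParams,
    stats: SufficientStats,
    cfg: AdaptationConfig | None = None,
) -> GMMParams:
    """One MAP pass updating weights, means and variances of the UBM."""
    cfg = cfg or AdaptationConfig()
    if stats.first_moment.shape != ubm.means.shape:
        raise ValueError("statistics do not match the UBM's shape")
    alpha = adaptive_coefficient(stats.n, cfg.relevance_factor)  # (M,)

    if cfg.adapt_weights and stats.T > 0:
        w_new = alpha * stats.n / stats.T + (1.0 - alpha) * ubm.weights
        w_new = w_new / w_new.sum()  # gamma normalization
    else:
        w_new = ubm.weights.copy()

    if cfg.adapt_means:
        mu_new = alpha[:, None] * stats.first_moment + (1.0 - alpha[:, None]) * ubm.means
    else:
        mu_new = ubm.means.copy()

    if cfg.adapt_variances:
        var_new = (
            alpha[:, None] * stats.second_moment
            + (1.0 - alpha[:, None]) * (ubm.variances + ubm.means**2)
            - mu_new**2
        )
        floor = np.atleast_1d(np.asarray(ubm.variance_floor, dtype=np.float64))
        n_floored = int(np.sum(var_new < floor))
        if n_floored:
            warnings.warn(
                f"floored {n_floored} adapted variance entries", stacklevel=2
            )
        var_new = np.maximum(var_new, floor)
    else:
        var_new = ubm.variances.copy()

    # components with no data are skipped outright (exact identity, not the
    # alpha_i = 0 float algebra, which loses ulps in the variance update)
    untouched = stats.n == 0
    if np.any(untouched):
        mu_new[untouched] = ubm.means[untouched]
        var_new[untouched] = ubm.variances[untouched]
        if np.all(untouched):
            w_new = ubm.weights.copy()

    return GMMParams(
        w_new,
        mu_new,
        var_new,
        variance_floor=ubm.variance_floor,
        meta={**ubm.meta, "adapted": True, "relevance_factor": cfg.relevance_factor},
    )


def build_supervector(
    adapted: GMMParams, dimension_name: str = "", source_id: str = ""
) -> Supervector:
    """Stack adapted means then diagonal covariances, component order preserved."""
    values = np.concatenate([adapted.means.ravel(), adapted.variances.ravel()])
    return Supervector(values, adapted.M, adapted.D, dimension_name, source_id)


def adapt_recording(
    X: np.ndarray | FeatureMatrix,
    ubm: GMMParams,
    cfg: AdaptationConfig | None = None,
    dimension_name: str = "",
    source_id: str = "",
) -> Supervector:
    """sufficient_stats -> map_adapt -> build_supervector for one recording."""
    if isinstance(X, FeatureMatrix):
        dimension_name = dimension_name or X.dimension_name
        source_id = source_id or X.source_id
        X = X.values
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError(
            f"recording {source_id!r} has no frames in dimension {dimension_name!r}"
        )
    stats = sufficient_stats(X, ubm)
    adapted = map_adapt(ubm, stats, cfg)
    return build_supervector(adapted, dimension_name, source_id)
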