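"""Temporal expression dynamics: profile clustering and trend tests.

Gene-level temporal profiles (mean TPM per time point within a
response group, z-scored across time points) are clustered with fuzzy
c-means; the cluster number is chosen by the elbow rule formalized as
the maximum second difference of the objective-vs-k curve.  Cell-type
abundance trends over time are tested with the Mann-Kendall test on
the time-ordered group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .matrix import ExpressionMatrix
from .stats import TrendResult, mann_kendall

DEFAULT_FUZZIFIER = 2.0
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500
DEFAULT_K_RANGE = range(2, 13)


def build_profiles(
    expr: ExpressionMatrix, manifest: pd.DataFrame, group: str = "responder"
) -> pd.DataFrame:
    """Per-gene z-scored mean-expression profile across time points.

    Rows = genes, columns = time points in manifest order of first
    appearance; constant genes get an all-zero profile and are flagged
    in ``attrs['constant_genes']``.
    """
    sel = manifest[manifest["response_label"] == group]
    time_points = list(dict.fromkeys(sel["time_point"]))
    if len(time_points) < 2:
        raise InputError(f"group {group!r} has fewer than 2 time points")
    means = {}
    for tp in time_points:
        samples = sel.loc[sel["time_point"] == tp, "sample_id"].tolist()
        if not samples:
            raise InputError(f"no samples at time point {tp!r}")
        means[tp] = expr.values[samples].mean(axis=1)
    prof = pd.DataFrame(means)
    mu = prof.mean(axis=1)
    sd = prof.std(axis=1, ddof=0)
    constant = sd <= 0
    z = prof.sub(mu, axis=0).div(sd.where(~constant, 1.0), axis=0)
    z[constant] = 0.0
    z.attrs["constant_genes"] = list(prof.index[constant])
    return z


@dataclass
class FcmResult:
    memberships: np.ndarray  # genes x k, rows sum to 1
    centroids: np.ndarray  # k x time
    objective: float
    objective_history: list
    k: int
    iterations: int
    converged: bool


class FuzzyCMeans:
    """Fuzzy c-means clusterer with the standard alternating updates.

    Membership ``u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))`` with
    Euclidean distances; centroid ``c_k = sum_i u_ik^m x_i / sum_i
    u_ik^m``.  Points coincident with one centroid get membership 1
    there; coincident with several, an equal split.  Initialization
    picks k distinct data points with the seeded generator, so runs
    are deterministic for a fixed seed.
    """

    def __init__(self, k: int, m: float = DEFAULT_FUZZIFIER, tol: float = DEFAULT_TOL,
                 max_iter: int = DEFAULT_MAX_ITER, seed: int = 0):
        if k < 2:
            raise InputError("k must be >= 2")
        self.k, self.m, self.tol, self.max_iter, self.seed = k, m, tol, max_iter, seed

    def _memberships(self, X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        u = np.empty((X.shape[0], self.k))
        power = 1.0 / (self.m - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** -power
        for i in range(X.shape[0]):
            if zero[i].any():
                u[i] = zero[i] / zero[i].sum()  # equal split over coincident centroids
            else:
                u[i] = inv[i] / inv[i].sum()
        return u

    def fit(self, X: np.ndarray) -> "FuzzyCMeans":
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.k >= n:
            raise InputError(f"k={self.k} must be < number of profiles ({n})")
        rng = np.random.default_rng(self.seed)
        centroids = X[rng.choice(n, size=self.k, replace=False)].copy()
        history = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            u = self._memberships(X, centroids)
            um = u**self.m
            new_centroids = (um.T @ X) / um.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - new_centroids[None, :, :]) ** 2).sum(axis=2)
            history.append(float((um * d2).sum()))
            shift = np.abs(new_centroids - centroids).max()
            centroids = new_centroids
            if shift < self.tol:
                converged = True
                break
        u = self._memberships(X, centroids)
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        objective = float(((u**self.m) * d2).sum())
        self.result_ = FcmResult(u, centroids, objective, history, self.k, it, converged)
        self.cluster_centers_ = centroids
        self.labels_ = u.argmax(axis=1)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._memberships(np.asarray(X, dtype=float), self.cluster_centers_).argmax(axis=1)


def fuzzy_cmeans(profiles, k: int, m: float = DEFAULT_FUZZIFIER, tol: float = DEFAULT_TOL,
                 max_iter: int = DEFAULT_MAX_ITER, seed: int = 0) -> FcmResult:
    X = profiles.to_numpy() if hasattr(profiles, "to_numpy") else np.asarray(profiles, float)
    return FuzzyCMeans(k, m, tol, max_iter, seed).fit(X).result_


def _objective_k1(X: np.ndarray) -> float:
    c = X.mean(axis=0)
    return float(((X - c) ** 2).sum())


def elbow_select(profiles, k_range=DEFAULT_K_RANGE, m: float = DEFAULT_FUZZIFIER,
                 tol: float = DEFAULT_TOL, seed: int = 0):
    """Choose k by maximum curvature of the objective-vs-k curve.

    The objective is evaluated from ``min(k_range) - 1`` (the k=1
    objective has a closed form) through ``max(k_range)``; k* is the
    interior point with the largest second difference, ties broken
    toward the smallest k.  Returns (k*, objective table).
    """
    ks = sorted(k_range)
    X = profiles.to_numpy() if hasattr(profiles, "to_numpy") else np.asarray(profiles, float)
    eval_ks = ([ks[0] - 1] if ks[0] - 1 >= 1 else []) + ks
    obj = {}
    for k in eval_ks:
        obj[k] = _objective_k1(X) if k == 1 else fuzzy_cmeans(X, k, m=m, tol=tol, seed=seed).objective
    curve = pd.DataFrame({"k": eval_ks, "objective": [obj[k] for k in eval_ks]})
    return elbow_from_curve(eval_ks, [obj[k] for k in eval_ks]), curve


def elbow_from_curve(ks, objectives) -> int:
    """Max-second-difference elbow rule; ties go to the smallest k."""
    ks = list(ks)
    objectives = list(objectives)
    best_k, best_curv = None, -np.inf
    for i in range(1, len(ks) - 1):
        curv = objectives[i - 1] - 2 * objectives[i] + objectives[i + 1]
        if curv > best_curv + 1e-12:
            best_k, best_curv = ks[i], curv
    if best_k is None:  # curve too short for curvature: fall back to smallest
        best_k = ks[0]
    return best_k


def trend_per_type(
    fractions: pd.DataFrame,
    cell_type: str,
    direction: str = "increasing",
    time_order=None,
) -> TrendResult:
    """Mann-Kendall trend on the time-ordered mean abundance of a type.

    ``fractions`` rows are (sample/subject x time point) groups indexed
    by a MultiIndex whose last level is the time point, columns are
    cell types (as produced by ``cell_type_fractions`` with
    ``by=["time_point"]`` or ``["subject_id", "time_point"]``).
    """
    if cell_type not in fractions.columns:
        raise InputError(f"unknown cell type {cell_type!r}")
    level = fractions.index.names[-1]
    means = fractions[cell_type].groupby(level=level, observed=True).mean()
    if time_order is not None:
        means = means.reindex(time_order).dropna()
    if len(means) < 3:
        raise InputError("need >= 3 time points for a trend test")
    return mann_kendall(means.to_numpy(), direction)
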