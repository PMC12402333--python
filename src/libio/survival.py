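"""Survival association of the LiBIO score with overall survival.

Kaplan-Meier product-limit estimation, the log-rank test between
mean-dichotomized score groups, and Cox proportional-hazards
regression of survival on the continuous score adjusted for age and
sex.  The Cox partial likelihood uses Efron's tie handling and is
maximized by damped Newton iterations; the reported hazard ratio is
per 1-unit score increase with a Wald p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import InputError

log = logging.getLogger("libio")

MAX_NEWTON_ITER = 100
NEWTON_TOL = 1e-9


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    ``records`` needs ``time`` (> 0) and ``event`` (0/1) columns.
    Returns a step table (time, n_at_risk, n_events, survival) with
    rows at distinct event times; S(0) = 1 implicitly.
    """
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    if len(t) == 0:
        raise InputError("no records")
    if (t <= 0).any():
        raise InputError("survival times must be positive")
    event_times = np.unique(t[e == 1])
    rows = []
    s = 1.0
    for tt in event_times:
        at_risk = int((t >= tt).sum())
        d = int(((t == tt) & (e == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append({"time": tt, "n_at_risk": at_risk, "n_events": d, "survival": s})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def split_by_mean(records: pd.DataFrame, score_col: str = "score") -> pd.Series:
    """High/low dichotomization at the mean score (ties at the mean → low)."""
    scores = records[score_col].to_numpy(dtype=float)
    if scores.size < 2:
        raise InputError("need >= 2 records to split")
    mean = scores.mean()
    groups = np.where(scores > mean, "high", "low")
    if (groups == "low").all():
        log.warning("split_by_mean: degenerate split (no scores above the mean)")
    return pd.Series(groups, index=records.index, name="group")


def logrank_test(records: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    g = np.asarray(groups) == np.unique(groups)[0]
    if e[g].sum() == 0 or e[~g].sum() == 0:
        log.warning("logrank_test: a group has no events")
    obs_minus_exp = 0.0
    var = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        d = int(((t == tt) & (e == 1)).sum())
        d1 = int(((t == tt) & (e == 1) & g).sum())
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp**2 / var
    # 1 df chi-square survival via the normal tail
    p = float(2.0 * (1.0 - ndtr(math.sqrt(chi2))))
    return float(chi2), p


@dataclass
class CoxFit:
    covariates: list
    coef: np.ndarray
    hazard_ratios: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    log_likelihood: float
    iterations: int
    converged: bool
    flags: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hazard_ratios,
                "se": self.se,
                "z": self.z,
                "p": self.p,
            },
            index=self.covariates,
        )


def _cox_loglik_grad_hess(beta, times, events, X):
    """Efron-tied Cox partial log-likelihood with gradient and Hessian."""
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # decreasing time
    times_o, events_o, X_o, w_o = times[order], events[order], X[order], w[order]

    ll = 0.0
    grad = np.zeros_like(beta)
    hess = np.zeros((beta.size, beta.size))
    # running risk-set aggregates as time decreases
    s0 = 0.0
    s1 = np.zeros_like(beta)
    s2 = np.zeros((beta.size, beta.size))
    i = 0
    n = len(times_o)
    while i < n:
        tt = times_o[i]
        j = i
        while j < n and times_o[j] == tt:
            j += 1
        block = slice(i, j)
        for idx in range(i, j):
            xi = X_o[idx]
            wx = w_o[idx] * xi
            s0 += w_o[idx]
            s1 += wx
            s2 += np.outer(wx, xi)
        ev = events_o[block] == 1
        d = int(ev.sum())
        if d > 0:
            Xd = X_o[block][ev]
            wd = w_o[block][ev]
            d0 = wd.sum()
            d1 = (wd[:, None] * Xd).sum(axis=0)
            d2 = (wd[:, None, None] * (Xd[:, :, None] * Xd[:, None, :])).sum(axis=0)
            ll += (np.log(wd)).sum()
            grad += Xd.sum(axis=0)
            for r in range(d):
                f = r / d
                e0 = s0 - f * d0
                e1 = s1 - f * d1
                e2 = s2 - f * d2
                ll -= math.log(e0)
                grad -= e1 / e0
                hess -= e2 / e0 - np.outer(e1, e1) / e0**2
        i = j
    return ll, grad, hess


def cox_fit(records: pd.DataFrame, covariates=("score", "age", "sex")) -> CoxFit:
    """Cox proportional-hazards fit by damped Newton on the Efron partial likelihood.

    Missing covariate values lead to complete-case exclusion (logged).
    Constant covariates are dropped with a flag.
    """
    cols = [c for c in covariates if c in records.columns]
    df = records.dropna(subset=["time", "event", *cols])
    excluded = len(records) - len(df)
    flags = []
    if excluded:
        flags.append(f"complete-case: excluded {excluded} records with missing values")
        log.info("cox_fit: excluded %d incomplete records", excluded)
    kept = [c for c in cols if df[c].nunique() > 1]
    for c in cols:
        if c not in kept:
            flags.append(f"dropped constant covariate {c!r}")
    if not kept:
        raise InputError("no non-constant covariates")
    if int(df["event"].sum()) < 2:
        raise InputError("need at least 2 events")
    times = df["time"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    X = df[kept].to_numpy(dtype=float)
    X = X - X.mean(axis=0)  # centering; invariant for the partial likelihood

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _cox_loglik_grad_hess(beta, times, events, X)
    converged = False
    it = 0
    for it in range(1, MAX_NEWTON_ITER + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            flags.append("singular information matrix (possible separation)")
            break
        # damped Newton: halve until the partial likelihood increases
        factor = 1.0
        for _ in range(30):
            new_beta = beta + factor * step
            new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_beta, times, events, X)
            if new_ll >= ll - 1e-12:
                break
            factor /= 2.0
        if abs(new_beta).max() > 50:
            flags.append("monotone likelihood (perfect separation)")
            beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
            break
        improved = new_ll - ll
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.abs(grad).max() < NEWTON_TOL or improved < NEWTON_TOL:
            converged = True
            break
    if not converged and not flags:
        flags.append(f"no convergence in {MAX_NEWTON_ITER} iterations")
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * (1.0 - ndtr(np.abs(z)))
    return CoxFit(
        covariates=kept,
        coef=beta,
        hazard_ratios=np.exp(beta),
        se=se,
        z=z,
        p=p,
        log_likelihood=float(ll),
        iterations=it,
        converged=converged,
        flags=flags,
    )
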