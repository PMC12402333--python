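"""Statistical primitives used throughout the pipeline.

Self-contained implementations of the four tests the analysis relies
on: the one-tailed Wilcoxon rank-sum (Mann–Whitney) test, Fisher's
exact test on a 2×2 table with both sample and conditional-MLE odds
ratios, Benjamini–Hochberg FDR adjustment, and the Mann–Kendall
monotone-trend test.  Each returns enough detail (statistic, method
variant, tie counts) for full provenance in run logs.

Conventions
-----------
* Wilcoxon: exact p by enumeration of the Mann–Whitney U null
  distribution when ``n_x * n_y <= 200`` and the pooled data are
  tie-free; otherwise normal approximation with midranks, tie-corrected
  variance and a 0.5 continuity correction.
* Fisher: p by hypergeometric enumeration over all tables with the
  observed margins; two-sided sums tables no more probable than the
  observed one.  ``or_sample`` is (a·d)/(b·c), with the
  Haldane–Anscombe +0.5 applied to all cells when any cell is zero.
  ``or_cmle`` maximizes the noncentral hypergeometric likelihood
  (solves E[a | psi] = a by bisection on log psi), the convention of
  R's ``fisher.test``.
* Mann–Kendall: S = Σ_{i<j} sgn(x_j − x_i); Var(S) with the tie term
  Σ t(t−1)(2t+5); z with ±1 continuity correction; one-sided p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import comb, ndtr
from scipy.stats import rankdata

from .errors import InputError

__all__ = [
    "ContingencyTable2x2",
    "TrendResult",
    "WilcoxonResult",
    "FisherResult",
    "wilcoxon_one_tailed",
    "fisher_exact",
    "bh_adjust",
    "mann_kendall",
]

EXACT_WILCOXON_MAX_PRODUCT = 200


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2×2 table; row 1 = condition present, column 1 = outcome present."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in cells):
            raise InputError("contingency cells must be non-negative integers")
        if sum(cells) == 0:
            raise InputError("all-zero contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TrendResult:
    S: int
    var_S: float
    z: float
    p_one_sided: float
    direction: str


@dataclass(frozen=True)
class WilcoxonResult:
    u: float
    p: float
    method: str  # "exact" | "normal"
    n_ties: int


@dataclass(frozen=True)
class FisherResult:
    p: float
    or_sample: float
    or_cmle: float
    corrected: bool  # Haldane-Anscombe applied to or_sample


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _mann_whitney_exact_sf(m: int, n: int, u_obs: float) -> float:
    """P(U >= u_obs) for the tie-free Mann-Whitney null, by counting.

    Subset-sum dynamic program: ``ways[j][s]`` counts the subsets of j
    ranks from {1..m+n} with rank sum s; U = ranksum - j(j+1)/2.
    """
    N = m + n
    max_sum = m * N
    ways = np.zeros((m + 1, max_sum + 1))
    ways[0, 0] = 1.0
    for rank in range(1, N + 1):
        # iterate j downward so each rank is used at most once
        for j in range(min(rank, m), 0, -1):
            ways[j, rank:] += ways[j - 1, : max_sum + 1 - rank]
    total = comb(N, m, exact=True)
    ranksum_min = int(math.ceil(u_obs + m * (m + 1) / 2.0 - 1e-9))
    if ranksum_min <= m * (m + 1) // 2:
        return 1.0
    if ranksum_min > max_sum:
        return 0.0
    return float(ways[m, ranksum_min:].sum() / total)


def wilcoxon_one_tailed(x, y, alternative: str = "greater") -> WilcoxonResult:
    """One-tailed Wilcoxon rank-sum test for location shift of x vs y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    if alternative not in ("greater", "less"):
        raise InputError(f"unknown alternative {alternative!r}")
    if alternative == "less":
        res = wilcoxon_one_tailed(y, x, "greater")
        return WilcoxonResult(x.size * y.size - res.u, res.p, res.method, res.n_ties)

    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    rx = ranks[:m].sum()
    u = rx - m * (m + 1) / 2.0  # Mann-Whitney U for x
    _, tie_counts = np.unique(pooled, return_counts=True)
    n_ties = int((tie_counts > 1).sum())

    if n_ties == 0 and m * n <= EXACT_WILCOXON_MAX_PRODUCT:
        p = _mann_whitney_exact_sf(m, n, u)
        return WilcoxonResult(u, p, "exact", 0)

    N = m + n
    mu = m * n / 2.0
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return WilcoxonResult(u, 1.0, "normal", n_ties)
    z = (u - mu - 0.5) / math.sqrt(var)
    p = float(1.0 - ndtr(z))
    return WilcoxonResult(u, p, "normal", n_ties)


# ---------------------------------------------------------------------------
# Fisher's exact test


def _hypergeom_pmf_vector(t: ContingencyTable2x2):
    """Support and pmf of cell `a` under the central hypergeometric null."""
    r1 = t.a + t.b
    c1 = t.a + t.c
    n = t.total
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logp = (
        _log_comb(c1, ks)
        + _log_comb(n - c1, r1 - ks)
        - _log_comb(n, r1)
    )
    return ks, np.exp(logp)


def _log_comb(n, k):
    from scipy.special import gammaln

    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _noncentral_mean(ks: np.ndarray, logw: np.ndarray, logpsi: float) -> float:
    logl = logw + ks * logpsi
    logl -= logl.max()
    w = np.exp(logl)
    return float((ks * w).sum() / w.sum())


def fisher_exact(t: ContingencyTable2x2, alternative: str = "two_sided") -> FisherResult:
    """Fisher's exact test with sample and conditional-MLE odds ratios."""
    if alternative not in ("two_sided", "greater", "less"):
        raise InputError(f"unknown alternative {alternative!r}")
    ks, pmf = _hypergeom_pmf_vector(t)
    p_obs = pmf[ks == t.a][0]
    if alternative == "greater":
        p = pmf[ks >= t.a].sum()
    elif alternative == "less":
        p = pmf[ks <= t.a].sum()
    else:
        p = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    p = float(min(1.0, p))

    corrected = 0 in (t.a, t.b, t.c, t.d)
    if corrected:
        a, b, c, d = (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)
    else:
        a, b, c, d = (t.a, t.b, t.c, t.d)
    or_sample = (a * d) / (b * c)

    # conditional MLE: solve E[a | psi] = observed a on the log scale
    lo_k, hi_k = ks[0], ks[-1]
    with np.errstate(divide="ignore"):
        logw = np.log(pmf)  # central weights; noncentral adds k*log(psi)
    if t.a <= lo_k:
        or_cmle = 0.0
    elif t.a >= hi_k:
        or_cmle = math.inf
    else:
        lo, hi = -50.0, 50.0
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if _noncentral_mean(ks, logw, mid) < t.a:
                lo = mid
            else:
                hi = mid
        or_cmle = math.exp((lo + hi) / 2.0)
    return FisherResult(p, float(or_sample), or_cmle, corrected)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(p) -> np.ndarray:
    """Step-up BH adjustment; output order matches input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Mann-Kendall


def mann_kendall(x, alternative: str = "increasing") -> TrendResult:
    """Mann–Kendall monotone-trend test on an ordered sequence."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise InputError("Mann-Kendall needs at least 3 observations")
    if alternative not in ("increasing", "decreasing"):
        raise InputError(f"unknown alternative {alternative!r}")
    diff = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diff, k=1).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = float((tie_counts * (tie_counts - 1) * (2 * tie_counts + 5)).sum())
    var_S = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var_S <= 0:
        z = 0.0
    elif S > 0:
        z = (S - 1) / math.sqrt(var_S)
    elif S < 0:
        z = (S + 1) / math.sqrt(var_S)
    else:
        z = 0.0
    if alternative == "increasing":
        p = float(1.0 - ndtr(z))
    else:
        p = float(ndtr(z))
    if S > 0:
        direction = "increasing"
    elif S < 0:
        direction = "decreasing"
    else:
        direction = "none"
    return TrendResult(S, var_S, z, p, direction)
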