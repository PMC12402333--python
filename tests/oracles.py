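"""Independent brute-force reference implementations used across tests.

Everything here is deliberately naive (explicit loops, direct
definitions) and shares no code with the package implementation.
"""

import itertools

import numpy as np
from scipy.special import comb
from scipy.stats import rankdata


def ssgsea_oracle(values, genes, gene_set, alpha):
    """Per-sample running-sum enrichment, computed step by step."""
    gene_set = set(gene_set)
    n = len(genes)
    k = sum(g in gene_set for g in genes)
    out = []
    for j in range(values.shape[1]):
        col = values[:, j]
        order = sorted(range(n), key=lambda i: (-col[i], i))
        rank = {gi: n - pos for pos, gi in enumerate(order)}
        denom = sum(rank[i] ** alpha for i in range(n) if genes[i] in gene_set)
        running = es = 0.0
        for gi in order:
            if genes[gi] in gene_set:
                running += rank[gi] ** alpha / denom
            else:
                running -= 1.0 / (n - k)
            es += running
        out.append(es)
    return np.array(out)


def auc_pairs_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def calibrate_oracle(scores, labels):
    """Exhaustive threshold search; returns (threshold, odds ratio)."""
    distinct = sorted(set(scores))
    best = None
    for a, b in itertools.pairwise(distinct):
        th = (a + b) / 2
        tp = sum(1 for s, l in zip(scores, labels) if s >= th and l)
        fp = sum(1 for s, l in zip(scores, labels) if s >= th and not l)
        fn = sum(1 for s, l in zip(scores, labels) if s < th and l)
        tn = sum(1 for s, l in zip(scores, labels) if s < th and not l)
        if tp + fp == 0 or fn + tn == 0:
            continue
        if 0 in (tp, fp, fn, tn):
            o = (tp + 0.5) * (tn + 0.5) / ((fp + 0.5) * (fn + 0.5))
        else:
            o = tp * tn / (fp * fn)
        bacc = (tp / (tp + fn) + tn / (tn + fp)) / 2
        key = (o, bacc, -th)
        if best is None or key > best[0]:
            best = (key, th, o)
    return best[1], best[2]


def wilcoxon_permutation_oracle(x, y):
    """One-sided (x greater) exact p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    m = len(x)
    obs = ranks[:m].sum()
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), m):
        count += ranks[list(idx)].sum() >= obs - 1e-9
        total += 1
    return count / total


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric summation."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, r1, exact=True)
    probs = {
        k: comb(c1, k, exact=True) * comb(n - c1, r1 - k, exact=True) / denom
        for k in range(lo, hi + 1)
    }
    return sum(p for p in probs.values() if p <= probs[a] * (1 + 1e-7))


def mann_kendall_s_oracle(x):
    return sum(
        np.sign(x[j] - x[i]) for i in range(len(x)) for j in range(i + 1, len(x))
    )
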