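"""Single-sample gene-set scoring and the combined LiBIO score.

ssGSEA variant
--------------
Per sample, genes are ranked by expression (largest expression gets
rank n; ties broken by stable gene order in the matrix).  Walking the
genes in decreasing expression, an in-set gene at walk position i
contributes a step of ``rank_i**alpha / sum(rank_g**alpha for g in
set)`` and an out-of-set gene a step of ``1/(n - |set|)``.  The
enrichment score is the sum over all positions of the running
(in - out) difference.  With ``normalize=True`` the per-sample scores
for a gene set are divided by (max - min) of those scores across the
samples of the call, so scores are comparable within a cohort.

The LiBIO score of a sample is the arithmetic mean of its effector
memory T cell (T_em) and B cell signature scores.

A transcriptomic PD-L1 combined positive score (CPS) is also provided:
CPS = 100 * (# PD-L1+ tumor cells + # PD-L1+ immune cells) / (# tumor
cells), a cell called PD-L1 positive iff more than ``min_reads``
raw reads map to CD274.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError
from .matrix import ExpressionMatrix
from .signature import SignatureSet

log = logging.getLogger("libio")

DEFAULT_ALPHA = 0.25
DEFAULT_MIN_READS_EXCLUSIVE = 2


def _sample_ranks(values: np.ndarray) -> np.ndarray:
    """Ranks per column: largest value -> rank n; ties by gene order."""
    n = values.shape[0]
    # stable argsort ascending, then invert: first (lowest) gets rank 1.
    # For ties the earlier gene must get the HIGHER rank, so sort
    # descending stably and assign n..1 in that order.
    order = np.argsort(-values, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    np.put_along_axis(ranks, order, n - rows, axis=0)
    return ranks


def ssgsea(
    expr: ExpressionMatrix,
    gene_set,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> pd.Series:
    """Per-sample ssGSEA enrichment score for one gene set."""
    genes = expr.gene_ids
    in_set = np.array([g in set(gene_set) for g in genes])
    n = len(genes)
    k = int(in_set.sum())
    if k == 0:
        raise InputError("gene set has no overlap with the matrix")
    if k == n:
        raise InputError("gene set covers every gene; out-of-set step undefined")
    values = expr.values.to_numpy(dtype=float)
    ranks = _sample_ranks(values)
    weights = ranks.astype(float) ** alpha
    weights[~in_set, :] = 0.0
    in_step = weights / weights.sum(axis=0, keepdims=True)
    out_step = np.where(in_set, 0.0, 1.0 / (n - k))[:, None] * np.ones((1, values.shape[1]))
    # walk order = decreasing expression (stable in gene order): position
    # of each gene is n - rank (0-based from the top).
    scores = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        pos = np.argsort(-values[:, j], kind="stable")
        running = np.cumsum(in_step[pos, j] - out_step[pos, j])
        scores[j] = running.sum()
    out = pd.Series(scores, index=expr.obs_ids, name="es")
    if normalize:
        rng = out.max() - out.min()
        if rng <= 0:
            log.warning("ssgsea: degenerate normalization (constant scores); raw ES kept")
        else:
            out = out / rng
    return out


def score_samples(
    cohort: ExpressionMatrix,
    tem: SignatureSet,
    b: SignatureSet,
    modality: str = "bulk",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-sample T_em, B, and LiBIO scores for one cohort.

    Normalization is within-cohort: each signature's scores are scaled
    by their range across this cohort's samples only.
    """
    tem_scores = ssgsea(cohort, tem.genes, alpha=alpha, normalize=True)
    b_scores = ssgsea(cohort, b.genes, alpha=alpha, normalize=True)
    table = pd.DataFrame(
        {
            "sample_id": cohort.obs_ids,
            "tem_score": tem_scores.to_numpy(),
            "b_score": b_scores.to_numpy(),
        }
    )
    table["libio"] = (table["tem_score"] + table["b_score"]) / 2.0
    table["modality"] = modality
    return table


def compute_cps(
    cps_in: pd.DataFrame,
    min_reads_exclusive: int = DEFAULT_MIN_READS_EXCLUSIVE,
) -> pd.Series:
    """Transcriptomic PD-L1 CPS per sample.

    ``cps_in`` columns: ``sample_id``, ``cd274_count`` (raw reads),
    ``cell_class`` in {tumor, immune, excluded}.  Excluded cells are
    ignored everywhere.  Positivity requires strictly more than
    ``min_reads_exclusive`` reads.
    """
    bad = set(cps_in["cell_class"]) - {"tumor", "immune", "excluded"}
    if bad:
        raise InputError(f"unknown cell classes: {sorted(bad)}")
    df = cps_in[cps_in["cell_class"] != "excluded"]
    out = {}
    for sample, grp in df.groupby("sample_id"):
        n_tumor = int((grp["cell_class"] == "tumor").sum())
        if n_tumor == 0:
            raise InputError(f"sample {sample!r} has no tumor cells")
        pos = grp["cd274_count"].astype(float) > min_reads_exclusive
        n_pos = int(pos.sum())  # PD-L1+ tumor + PD-L1+ immune
        out[sample] = 100.0 * n_pos / n_tumor
    return pd.Series(out, name="cps")
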