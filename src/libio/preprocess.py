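"""Single-cell QC, normalization, marker gating, and pseudobulk.

Cells with more than 25% mitochondrial content or fewer than 500
detected genes are discarded (strict inequalities); genes detected in
fewer than 3 cells are dropped.  Normalization is counts-per-10,000
followed by log1p.  Cell types are assigned by simple +/- marker
gating (e.g. CD8 T cells: Cd8a+, Cd8b1+, Cd4-).  Pseudobulk profiles
average the de-logged normalized expression over each sample's cells,
matching average-expression semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, IntegrityError
from .matrix import ExpressionMatrix
from .tables import validate_annotations

log = logging.getLogger("libio")

DEFAULT_MAX_MITO = 0.25
DEFAULT_MIN_GENES = 500
DEFAULT_MIN_CELLS = 3
DEFAULT_SCALE = 1e4


@dataclass(frozen=True)
class GateRule:
    """Marker gate: all ``positive_genes`` expressed, all ``negative_genes`` silent."""

    label: str
    positive_genes: tuple
    negative_genes: tuple = ()

    def __post_init__(self):
        pos, neg = set(self.positive_genes), set(self.negative_genes)
        if not (pos or neg):
            raise ConfigError(f"gate {self.label!r} has no genes")
        if pos & neg:
            raise ConfigError(f"gate {self.label!r} lists genes as both + and -: {pos & neg}")


@dataclass
class PseudobulkMatrix(ExpressionMatrix):
    """Per-sample average expression with the aggregated cell counts."""

    cell_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))


def qc_filter_cells(
    counts: ExpressionMatrix,
    ann: pd.DataFrame,
    max_mito: float = DEFAULT_MAX_MITO,
    min_genes: int = DEFAULT_MIN_GENES,
):
    """Drop cells failing mitochondrial or gene-detection QC.

    Removes cells with ``mito_fraction > max_mito`` OR
    ``n_genes_detected < min_genes`` (both thresholds exclusive on the
    passing side, i.e. exactly 25% mito passes).  Returns the filtered
    matrix, the filtered annotations, and a per-reason report.
    """
    validate_annotations(ann, counts)
    ann = ann.set_index("cell_id", drop=False).loc[counts.obs_ids]
    high_mito = ann["mito_fraction"].astype(float) > max_mito
    low_genes = ann["n_genes_detected"].astype(int) < min_genes
    fail = high_mito | low_genes
    report = {
        "n_input": int(len(ann)),
        "n_removed": int(fail.sum()),
        "n_high_mito": int(high_mito.sum()),
        "n_low_genes": int(low_genes.sum()),
        "removed_cell_ids": ann.loc[fail, "cell_id"].tolist(),
        "max_mito": max_mito,
        "min_genes": min_genes,
    }
    keep = ann.loc[~fail, "cell_id"].tolist()
    log.info("qc_filter_cells: removed %d/%d cells", report["n_removed"], report["n_input"])
    return counts.subset_obs(keep), ann.loc[~fail].reset_index(drop=True), report


def filter_genes(counts: ExpressionMatrix, min_cells: int = DEFAULT_MIN_CELLS) -> ExpressionMatrix:
    """Drop genes with nonzero counts in fewer than ``min_cells`` cells."""
    if counts.value_kind != "counts":
        raise InputError("filter_genes expects raw counts")
    detected = (counts.values > 0).sum(axis=1)
    keep = detected[detected >= min_cells].index
    return counts.subset_genes(keep)


def normalize_lognorm(counts: ExpressionMatrix, scale: float = DEFAULT_SCALE) -> ExpressionMatrix:
    """Library-size normalize to ``scale`` counts per cell, then log1p."""
    if counts.value_kind != "counts":
        raise InputError("normalize_lognorm expects raw counts")
    totals = counts.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise IntegrityError(f"cells with zero total counts: {list(zero.index)[:10]}")
    vals = np.log1p(counts.values * (scale / totals))
    return counts.with_values(vals, "lognorm")


def gate_cells(lognorm: ExpressionMatrix, rules) -> pd.Series:
    """Assign each cell the unique gate label it satisfies, else 'unassigned'.

    A cell satisfies a gate iff every positive gene has expression > 0
    and every negative gene is exactly 0; cells matching zero or
    several gates are unassigned.
    """
    for rule in rules:
        missing = [g for g in (*rule.positive_genes, *rule.negative_genes)
                   if g not in lognorm.values.index]
        if missing:
            raise ConfigError(f"gate {rule.label!r} references absent gene(s): {missing}")
    n_cells = lognorm.shape[1]
    hits = np.zeros(n_cells, dtype=int)
    labels = np.array(["unassigned"] * n_cells, dtype=object)
    for rule in rules:
        ok = np.ones(n_cells, dtype=bool)
        for g in rule.positive_genes:
            ok &= lognorm.values.loc[g].to_numpy() > 0
        for g in rule.negative_genes:
            ok &= lognorm.values.loc[g].to_numpy() == 0
        labels[ok] = rule.label
        hits += ok.astype(int)
    labels[hits != 1] = "unassigned"
    return pd.Series(labels, index=lognorm.obs_ids, name="cell_type")


def cell_type_fractions(ann: pd.DataFrame, by="sample_id") -> pd.DataFrame:
    """Per-group cell-type proportions (each cell counted once; rows sum to 1)."""
    if isinstance(by, str):
        by = [by]
    counts = ann.groupby(by + ["cell_type"], observed=True).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def pseudobulk_mean(lognorm: ExpressionMatrix, ann: pd.DataFrame, by: str = "sample_id") -> PseudobulkMatrix:
    """Average de-logged normalized expression per sample.

    ``expm1`` is applied per cell before averaging so the pseudobulk is
    on the normalized-count scale.
    """
    if lognorm.value_kind != "lognorm":
        raise InputError("pseudobulk_mean expects log-normalized input")
    mapping = ann.set_index("cell_id")[by]
    missing = set(lognorm.obs_ids) - set(mapping.index)
    if missing:
        raise IntegrityError(f"{len(missing)} cells lack a {by} annotation")
    groups = mapping.loc[lognorm.obs_ids]
    delogged = np.expm1(lognorm.values)
    agg = delogged.T.groupby(groups.to_numpy()).mean().T
    cell_counts = groups.value_counts().reindex(agg.columns)
    agg = agg[sorted(agg.columns)]
    return PseudobulkMatrix(
        values=agg,
        value_kind="pseudobulk",
        meta=dict(lognorm.meta),
        cell_counts=cell_counts.reindex(sorted(agg.columns)).astype(int),
    )
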