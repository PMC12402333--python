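"""Cell-type marker signatures from on-treatment single-cell data.

Markers for a target cell type are derived one-vs-rest from the early
on-treatment time point (Day 9 in the mouse study design): per-gene
two-sided Wilcoxon rank-sum on log-normalized expression, BH FDR
across tested genes, and a linear-scale fold-change filter on
de-logged group means with a pseudocount.  Retained markers are
up-regulated with FDR <= 0.01 and fold change >= 1.5.  Mouse symbols
are then mapped to human through a one-to-one ortholog map and genes
not detected in every validation cohort are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, PipelineError
from .matrix import ExpressionMatrix
from .stats import bh_adjust, wilcoxon_one_tailed

log = logging.getLogger("libio")

DEFAULT_FDR_MAX = 0.01
DEFAULT_FC_MIN = 1.5
DEFAULT_EPSILON = 1.0
DEFAULT_TIME_POINT = "D9"
MIN_CELLS_PER_GROUP = 3


@dataclass(frozen=True)
class SignatureSet:
    """Named, unique gene list with its derivation provenance."""

    name: str
    genes: tuple
    provenance: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self):
        if len(self.genes) == 0:
            raise PipelineError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise PipelineError(f"signature {self.name!r} has duplicate genes")


def _two_sided_wilcoxon(x, y) -> float:
    g = wilcoxon_one_tailed(x, y, "greater").p
    l = wilcoxon_one_tailed(x, y, "less").p
    return min(1.0, 2.0 * min(g, l))


def derive_markers(
    lognorm: ExpressionMatrix,
    ann: pd.DataFrame,
    target_type: str,
    time_point: str = DEFAULT_TIME_POINT,
    fdr_max: float = DEFAULT_FDR_MAX,
    fc_min: float = DEFAULT_FC_MIN,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """One-vs-rest marker table for ``target_type`` at ``time_point``.

    Returns the full per-gene table (gene, p, fdr, fold_change,
    mean_in, mean_out, retained flag), sorted by FDR then fold change.
    """
    at_tp = ann[ann["time_point"] == time_point]
    if target_type not in set(at_tp["cell_type"]):
        raise ConfigError(f"no cells of type {target_type!r} at {time_point}")
    in_cells = at_tp.loc[at_tp["cell_type"] == target_type, "cell_id"].tolist()
    out_cells = at_tp.loc[at_tp["cell_type"] != target_type, "cell_id"].tolist()
    if len(in_cells) < MIN_CELLS_PER_GROUP or len(out_cells) < MIN_CELLS_PER_GROUP:
        raise InputError(
            f"need >= {MIN_CELLS_PER_GROUP} cells per group, got "
            f"{len(in_cells)} target / {len(out_cells)} rest"
        )
    vin = lognorm.values[in_cells].to_numpy()
    vout = lognorm.values[out_cells].to_numpy()
    genes = lognorm.gene_ids
    pvals = np.array([_two_sided_wilcoxon(vin[i], vout[i]) for i in range(len(genes))])
    fdr = bh_adjust(pvals)
    mean_in = np.expm1(vin).mean(axis=1)
    mean_out = np.expm1(vout).mean(axis=1)
    fc = (mean_in + epsilon) / (mean_out + epsilon)
    table = pd.DataFrame(
        {
            "gene": genes,
            "p": pvals,
            "fdr": fdr,
            "fold_change": fc,
            "mean_in": mean_in,
            "mean_out": mean_out,
        }
    )
    table["retained"] = (table["fdr"] <= fdr_max) & (table["fold_change"] >= fc_min)
    return table.sort_values(["fdr", "p", "gene"], kind="stable").reset_index(drop=True)


def markers_to_signature(
    table: pd.DataFrame, name: str, **provenance
) -> SignatureSet:
    genes = tuple(table.loc[table["retained"], "gene"])
    return SignatureSet(name, genes, dict(provenance))


def map_orthologs(sig: SignatureSet, ortholog_map: pd.DataFrame) -> SignatureSet:
    """Translate mouse symbols to human, keeping one-to-one pairs only."""
    m = ortholog_map[["mouse", "human"]].drop_duplicates()
    mouse_multi = set(m.loc[m["mouse"].duplicated(keep=False), "mouse"])
    human_multi = set(m.loc[m["human"].duplicated(keep=False), "human"])
    one2one = m[~m["mouse"].isin(mouse_multi) & ~m["human"].isin(human_multi)]
    lut = dict(zip(one2one["mouse"], one2one["human"]))
    mapped, dropped = [], []
    for g in sig.genes:
        if g in lut:
            mapped.append(lut[g])
        else:
            dropped.append(g)
    if dropped:
        log.info("map_orthologs[%s]: dropped %d genes (ambiguous or unmapped)",
                 sig.name, len(dropped))
    if not mapped:
        raise PipelineError(f"signature {sig.name!r} empty after ortholog mapping")
    prov = dict(sig.provenance)
    prov["ortholog_dropped"] = dropped
    return SignatureSet(sig.name, tuple(dict.fromkeys(mapped)), prov)


def cross_cohort_filter(sig: SignatureSet, cohorts) -> SignatureSet:
    """Keep genes detected (nonzero in >= 1 sample) in every cohort matrix."""
    if not cohorts:
        raise InputError("cross_cohort_filter needs at least one cohort")
    keep = []
    for g in sig.genes:
        detected_everywhere = True
        for cohort in cohorts:
            if g not in cohort.values.index or not (cohort.values.loc[g] > 0).any():
                detected_everywhere = False
                break
        if detected_everywhere:
            keep.append(g)
    if not keep:
        raise PipelineError(f"signature {sig.name!r} empty after cross-cohort filter")
    prov = dict(sig.provenance)
    prov["cross_cohort_removed"] = [g for g in sig.genes if g not in set(keep)]
    return SignatureSet(sig.name, tuple(keep), prov)
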