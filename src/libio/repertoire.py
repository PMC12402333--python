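"""TCR/BCR repertoire statistics: clone sizes, expansion, clonality.

Clone size is the number of units (cells or reads) in a sample sharing
a clonotype key; a clone is called expanded when its size is >= 2.
Clonality per sample is the Simpson dominance index sum(p_i^2) over
clone frequencies, oriented so higher values mean stronger clonal
expansion; an optional small-sample rescaling
(sum(p^2) - 1/S) / (1 - 1/S) is available behind a flag.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import InputError
from .stats import ContingencyTable2x2, fisher_exact, wilcoxon_one_tailed

log = logging.getLogger("libio")

DEFAULT_MIN_EXPANDED = 2


def clone_sizes(records: pd.DataFrame, by=("sample_id",)) -> pd.DataFrame:
    """Count units per clonotype within each grouping key.

    ``by`` defaults to sample; add ``cell_type`` for per-subset spectra.
    """
    by = list(by)
    if records.empty:
        return pd.DataFrame(columns=by + ["clonotype_key", "size"])
    sizes = (
        records.groupby(by + ["clonotype_key"], observed=True)
        .size()
        .rename("size")
        .reset_index()
    )
    return sizes


def expansion_flags(sizes: pd.DataFrame, min_expanded: int = DEFAULT_MIN_EXPANDED) -> pd.DataFrame:
    """Flag each clone as expanded iff its size >= ``min_expanded``."""
    out = sizes.copy()
    out["expanded"] = out["size"] >= min_expanded
    return out


def unit_expansion_flags(records: pd.DataFrame, by=("sample_id",),
                         min_expanded: int = DEFAULT_MIN_EXPANDED) -> pd.Series:
    """Per-unit expanded flag: does the unit's clone have size >= threshold."""
    by = list(by)
    sizes = clone_sizes(records, by)
    flagged = expansion_flags(sizes, min_expanded)
    merged = records.merge(flagged, on=by + ["clonotype_key"], how="left")
    return pd.Series(merged["expanded"].to_numpy(), index=records.index, name="expanded")


def expansion_enrichment(expanded: pd.Series, groups: pd.Series):
    """Fisher's exact test of expansion against a binary unit grouping.

    ``groups`` must be boolean (True = group of interest, e.g. T_em or
    responder).  Returns the 2x2 table and the Fisher result (p plus
    sample and conditional-MLE odds ratios).
    """
    expanded = expanded.astype(bool)
    groups = groups.astype(bool)
    if groups.all() or not groups.any():
        raise InputError("both groups must be non-empty")
    a = int((expanded & groups).sum())
    b = int((~expanded & groups).sum())
    c = int((expanded & ~groups).sum())
    d = int((~expanded & ~groups).sum())
    table = ContingencyTable2x2(a, b, c, d)
    return table, fisher_exact(table, "two_sided")


def clonality(sizes: pd.DataFrame, scaled: bool = False, by=("sample_id",)) -> pd.DataFrame:
    """Simpson dominance index and clone-size summary per sample.

    ``scaled`` applies (sum(p^2) - 1/S)/(1 - 1/S) where S is the clone
    count (0 for a single-clone sample by convention of the limit).
    """
    by = list(by)
    rows = []
    for key, grp in sizes.groupby(by, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        n_units = int(grp["size"].sum())
        if n_units == 0:
            log.warning("clonality: empty group %s skipped", key)
            continue
        p = grp["size"].to_numpy(dtype=float) / n_units
        simpson = float((p**2).sum())
        n_clones = int(len(grp))
        if scaled:
            simpson = 1.0 if n_clones == 1 else (simpson - 1 / n_clones) / (1 - 1 / n_clones)
        rows.append(
            dict(zip(by, key))
            | {
                "simpson": simpson,
                "mean_clone_size": n_units / n_clones,
                "n_clones": n_clones,
                "n_units": n_units,
            }
        )
    return pd.DataFrame(rows)


def compare_clonality(
    results: pd.DataFrame,
    manifest: pd.DataFrame,
    time_point: str | None = None,
    metric: str = "simpson",
):
    """One-tailed Wilcoxon: responders more clonal than non-responders.

    ``results`` is a clonality table whose samples are joined to the
    manifest's response labels (restricted to ``time_point`` when the
    manifest carries one).
    """
    merged = results.merge(manifest, on="sample_id", how="inner")
    if time_point is not None:
        merged = merged[merged["time_point"] == time_point]
    resp = merged.loc[merged["response_label"] == "responder", metric]
    nonresp = merged.loc[merged["response_label"] == "non_responder", metric]
    if resp.empty or nonresp.empty:
        raise InputError("both response groups must be present at the time point")
    return wilcoxon_one_tailed(resp.to_numpy(), nonresp.to_numpy(), "greater")
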