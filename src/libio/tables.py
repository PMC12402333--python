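"""Tabular inputs: cell annotations, clonotype tables, cohort manifests.

All three are carried as validated ``pandas.DataFrame`` objects — the
field's lingua franca — with module-level readers/writers for their TSV
representations and helpers that enforce the schema contracts the rest
of the pipeline relies on.
"""

from __future__ import annotations

import logging
import os
import re

import pandas as pd

from .errors import IntegrityError, SchemaError

log = logging.getLogger("libio")

CHAINS = ("TRA", "TRB", "IGH", "IGK", "IGL", "paired")

ANNOTATION_COLUMNS = [
    "cell_id",
    "sample_id",
    "subject_id",
    "time_point",
    "cell_type",
    "mito_fraction",
    "n_genes_detected",
]

CLONOTYPE_COLUMNS = ["unit_id", "sample_id", "chain", "cdr3_nt"]

MANIFEST_COLUMNS = ["sample_id", "subject_id", "response_label", "modality", "timing"]


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


# ---------------------------------------------------------------------------
# cell annotations


def validate_annotations(ann: pd.DataFrame, matrix=None) -> pd.DataFrame:
    _require_columns(ann, ANNOTATION_COLUMNS, "cell annotation table")
    if ann["cell_id"].duplicated().any():
        dups = ann.loc[ann["cell_id"].duplicated(), "cell_id"].tolist()
        raise IntegrityError(f"duplicate cell ids in annotation: {dups[:10]}")
    mito = ann["mito_fraction"].astype(float)
    if ((mito < 0) | (mito > 1)).any():
        raise IntegrityError("mito_fraction outside [0, 1]")
    if matrix is not None:
        missing = set(ann["cell_id"]) - set(matrix.obs_ids)
        extra = set(matrix.obs_ids) - set(ann["cell_id"])
        if missing or extra:
            raise IntegrityError(
                f"annotation/matrix mismatch: {len(missing)} annotated cells absent "
                f"from matrix, {len(extra)} matrix cells unannotated"
            )
    return ann


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "sample_id": str, "subject_id": str})
    return validate_annotations(ann)


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clonotypes


def clonotype_key(chain: str, cdr3_nt: str) -> str:
    """Canonical within-chain nucleotide-level clone identity."""
    return f"{chain}:{cdr3_nt.upper()}"


def paired_key(keys) -> str:
    """Combine per-chain keys of one cell into an order-free paired key."""
    return "|".join(sorted(keys))


def read_clonotypes(path) -> pd.DataFrame:
    """Read an AIRR-style clonotype TSV into a record table.

    Required columns: ``unit_id`` (cell barcode or read id), ``sample_id``,
    ``chain``, ``cdr3_nt``.  Optional: ``subject_id``, ``cell_type``.
    Rows with an empty CDR3 are dropped (count logged).  Each record gets
    a canonical ``clonotype_key`` = ``CHAIN:CDR3NT`` (upper-cased).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, CLONOTYPE_COLUMNS, os.fspath(path))
    n0 = len(df)
    df = df[df["cdr3_nt"].str.strip() != ""].copy()
    dropped = n0 - len(df)
    if dropped:
        log.info("read_clonotypes: dropped %d rows with empty CDR3", dropped)
    df.attrs["n_dropped_empty_cdr3"] = dropped
    bad = set(df["chain"]) - set(CHAINS)
    if bad:
        raise SchemaError(f"unknown chain value(s): {sorted(bad)}")
    dup = df.duplicated(subset=["sample_id", "unit_id", "chain"])
    if dup.any():
        raise IntegrityError(
            f"(unit_id, chain) not unique within sample for {int(dup.sum())} rows"
        )
    df["clonotype_key"] = [
        clonotype_key(c, s) for c, s in zip(df["chain"], df["cdr3_nt"])
    ]
    if "subject_id" not in df.columns:
        df["subject_id"] = df["sample_id"]
    if "cell_type" not in df.columns:
        df["cell_type"] = ""
    return df.reset_index(drop=True)


def write_clonotypes(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if c != "clonotype_key"]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# response labels and the manifest

_RECIST_RESPONDER = {"CR", "PR"}
_RECIST_NONRESPONDER = {"SD", "PD"}
_NUM_RE = re.compile(r"^\s*([-+]?\d+(?:\.\d+)?)\s*%?\s*$")


def derive_response_label(raw_response) -> str:
    """Map a RECIST code or tumor-shrinkage percentage to a response class.

    CR/PR → responder; SD/PD → non_responder; shrinkage strictly greater
    than 50% → responder, 50% or less → non_responder; anything that
    parses as neither → ``unknown``.
    """
    if raw_response is None or (isinstance(raw_response, float) and pd.isna(raw_response)):
        return "unknown"
    s = str(raw_response).strip()
    up = s.upper()
    if up in _RECIST_RESPONDER:
        return "responder"
    if up in _RECIST_NONRESPONDER:
        return "non_responder"
    m = _NUM_RE.match(s)
    if m:
        return "responder" if float(m.group(1)) > 50.0 else "non_responder"
    return "unknown"


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    manifest = manifest.copy()
    if "response_label" not in manifest.columns and "raw_response" in manifest.columns:
        manifest["response_label"] = manifest["raw_response"].map(derive_response_label)
    _require_columns(manifest, MANIFEST_COLUMNS, "cohort manifest")
    if manifest["sample_id"].duplicated().any():
        raise IntegrityError("duplicate sample ids in manifest")
    bad = set(manifest["response_label"]) - {"responder", "non_responder", "unknown"}
    if bad:
        raise IntegrityError(f"invalid response labels: {sorted(bad)}")
    if "raw_response" in manifest.columns:
        derived = manifest["raw_response"].map(derive_response_label)
        clash = derived[(derived != "unknown") & (derived != manifest["response_label"])]
        if len(clash):
            raise IntegrityError("response_label disagrees with raw_response for some samples")
    return manifest


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ortholog map


def read_ortholog_map(path) -> pd.DataFrame:
    """Two-column mouse→human symbol map (TSV, header ``mouse\\thuman``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["mouse", "human"], "ortholog map")
    return df
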