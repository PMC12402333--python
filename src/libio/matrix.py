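"""Gene-by-observation expression container and its on-disk formats.

The :class:`ExpressionMatrix` is the substrate for every expression
operation in the pipeline: QC, normalization, pseudobulk aggregation,
differential expression, and single-sample gene-set scoring.  It is a
thin, validated wrapper around a dense ``pandas.DataFrame`` (rows =
genes, columns = observations, i.e. cells or samples) plus a tag
recording what kind of values it holds — raw counts, log-normalized
expression, TPM, or pseudobulk averages — so that transforms can check
they are applied on the scale they expect.

Two disk formats are supported: a dense TSV with a header row of
observation ids and gene ids in the first column, and a MatrixMarket
coordinate triplet (``matrix.mtx`` plus ``genes.tsv``/``barcodes.tsv``
sidecars, the common sparse single-cell exchange layout).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, IntegrityError

VALUE_KINDS = ("counts", "lognorm", "tpm", "pseudobulk")


def _check_unique(ids, what: str) -> None:
    ser = pd.Series(ids)
    dup = ser[ser.duplicated()].unique()
    if len(dup):
        raise IntegrityError(f"duplicate {what} identifiers: {list(dup)[:10]}")


@dataclass
class ExpressionMatrix:
    """Dense genes × observations matrix with a value-kind tag.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by gene id, columns by observation id (cell or
        sample). All entries must be finite and non-negative.
    value_kind : str
        One of ``counts``, ``lognorm``, ``tpm``, ``pseudobulk``.
    """

    values: pd.DataFrame
    value_kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise IntegrityError(f"unknown value_kind {self.value_kind!r}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "observation")
        arr = self.values.to_numpy()
        if arr.size and (not np.all(np.isfinite(arr)) or arr.min() < 0):
            raise IntegrityError("expression values must be finite and >= 0")

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def obs_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.value_kind, dict(self.meta))

    def subset_obs(self, obs) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(obs)], self.value_kind, dict(self.meta))

    def with_values(self, values: pd.DataFrame, value_kind: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, value_kind or self.value_kind, dict(self.meta))


# ---------------------------------------------------------------------------
# dense TSV


def read_dense_tsv(path: str | os.PathLike, value_kind: str) -> ExpressionMatrix:
    """Read a dense TSV (header = observation ids, first column = gene ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse dense TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: dense TSV has no observation columns (line 1)")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), value_kind)


def write_dense_tsv(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# MatrixMarket triplet


def read_mtx_triplet(path: str | os.PathLike, value_kind: str) -> ExpressionMatrix:
    """Read ``matrix.mtx`` with ``genes.tsv`` / ``barcodes.tsv`` sidecars.

    ``path`` may point at the ``.mtx`` file or at the directory holding
    the triplet.  The matrix is gene-major (rows = genes).
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        mtx = os.path.join(path, "matrix.mtx")
    else:
        mtx = path
        path = os.path.dirname(path)
    genes_f = os.path.join(path, "genes.tsv")
    obs_f = os.path.join(path, "barcodes.tsv")
    for f in (mtx, genes_f, obs_f):
        if not os.path.exists(f):
            raise FormatError(f"missing MTX triplet component: {f}")
    _validate_mtx_header(mtx)
    try:
        mat = scipy.io.mmread(mtx)
    except Exception as exc:
        raise FormatError(f"{mtx}: malformed MatrixMarket file: {exc}") from exc
    genes = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str).tolist()
    obs = pd.read_csv(obs_f, sep="\t", header=None)[0].astype(str).tolist()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(genes), len(obs)):
        raise FormatError(
            f"{mtx}: matrix is {dense.shape} but sidecars declare "
            f"{len(genes)} genes x {len(obs)} observations"
        )
    df = pd.DataFrame(dense, index=genes, columns=obs)
    return ExpressionMatrix(df, value_kind)


def _validate_mtx_header(mtx: str) -> None:
    """Check the declared entry count against the body line count."""
    n_entries = None
    body = 0
    with open(mtx) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("%"):
                continue
            if n_entries is None:
                parts = s.split()
                if len(parts) != 3:
                    raise FormatError(f"{mtx}: malformed size header at line {lineno}")
                n_entries = int(parts[2])
            else:
                body += 1
    if n_entries is None:
        raise FormatError(f"{mtx}: no size header found")
    if body != n_entries:
        raise FormatError(
            f"{mtx}: header declares {n_entries} entries but body has {body}"
        )


def write_mtx_triplet(matrix: ExpressionMatrix, directory: str | os.PathLike) -> None:
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.values.to_numpy())
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), sparse, precision=10)
    pd.Series(matrix.gene_ids).to_csv(
        os.path.join(directory, "genes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(matrix.obs_ids).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", index=False, header=False
    )


def read_expression(path, format: str, value_kind: str) -> ExpressionMatrix:
    """Dispatch on ``format`` ∈ {mtx_triplet, dense_tsv}."""
    if format == "dense_tsv":
        return read_dense_tsv(path, value_kind)
    if format == "mtx_triplet":
        return read_mtx_triplet(path, value_kind)
    raise FormatError(f"unknown expression format {format!r}")


def write_expression(matrix: ExpressionMatrix, path, format: str) -> None:
    if format == "dense_tsv":
        write_dense_tsv(matrix, path)
    elif format == "mtx_triplet":
        write_mtx_triplet(matrix, path)
    else:
        raise FormatError(f"unknown expression format {format!r}")
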