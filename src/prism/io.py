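"""Readers and writers for the standard formats the tool touches.

Counts travel either as dense TSV (first column gene ids, header row unit
ids, '.' decimal, no NA) or as a CellRanger-style MatrixMarket triplet
(matrix.mtx + feature and barcode lists).  All outputs are TSV with enough
digits that write-then-read preserves at least nine significant digits and
repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datamodel import (
    CellLabels,
    CountMatrix,
    DecompositionResult,
    FormatError,
    ValidationError,
)

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_labels",
    "write_labels",
    "align_labels",
    "align_genes",
    "write_decomposition",
]

logger = logging.getLogger("prism")

_FLOAT_FMT = "%.12g"  # >= 9 significant digits survive a round-trip


def read_counts_tsv(path, kind: str = "bulk") -> CountMatrix:
    """Read a dense genes x units TSV into a :class:`CountMatrix`.

    The first column holds gene ids, the header row unit ids.  Non-numeric
    body cells (including 'NA') are reported with their row/column
    coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no genes")
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no units")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            conv = pd.to_numeric(df[col], errors="coerce")
            i = int(np.flatnonzero(conv.isna().to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} at gene "
                f"{df.index[i]!r} (row {i + 2}), unit {col!r} "
                f"(column {j + 2})"
            ) from None
    return CountMatrix(
        values, [str(g) for g in df.index], [str(u) for u in df.columns],
        kind=kind,
    )


def write_counts_tsv(counts: CountMatrix, path) -> None:
    """Write a :class:`CountMatrix` as dense TSV (inverse of the reader)."""
    df = pd.DataFrame(
        counts.values, index=counts.gene_ids, columns=counts.unit_ids
    )
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="gene_id")


def _read_id_list(path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_counts_mtx(
    matrix_path,
    features_path,
    barcodes_path,
    transpose: bool | None = None,
) -> CountMatrix:
    """Read a CellRanger-style MatrixMarket triplet as single-cell counts.

    ``features_path`` and ``barcodes_path`` are plain-text lists (one id
    per line; extra tab-separated columns beyond the first are ignored).
    Orientation is genes x cells; ``transpose=None`` detects a transposed
    matrix heuristically when the id-list lengths disambiguate it.
    """
    matrix_path = Path(matrix_path)
    try:
        mat = spio.mmread(matrix_path)
    except Exception as exc:
        raise FormatError(f"{matrix_path}: invalid MatrixMarket file: {exc}")
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    genes = _read_id_list(features_path)
    cells = _read_id_list(barcodes_path)
    nr, nc = mat.shape
    if transpose is None:
        if (nr, nc) == (len(genes), len(cells)):
            transpose = False
        elif (nr, nc) == (len(cells), len(genes)):
            transpose = True
            logger.info(
                "%s: matrix is cells x genes; transposing", matrix_path
            )
        else:
            transpose = False  # fall through to the dimension check
    if transpose:
        mat = mat.T
        nr, nc = mat.shape
    if nr != len(genes):
        raise FormatError(
            f"{features_path}: {len(genes)} features for a matrix with "
            f"{nr} rows ({matrix_path})"
        )
    if nc != len(cells):
        raise FormatError(
            f"{barcodes_path}: {len(cells)} barcodes for a matrix with "
            f"{nc} columns ({matrix_path})"
        )
    if np.any(mat < 0):
        raise ValidationError(f"{matrix_path}: negative entries")
    return CountMatrix(mat, genes, cells, kind="single_cell")


def write_counts_mtx(counts: CountMatrix, out_dir) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        out / "matrix.mtx", sparse.coo_matrix(counts.values), precision=17
    )
    (out / "features.tsv").write_text(
        "".join(g + "\n" for g in counts.gene_ids)
    )
    (out / "barcodes.tsv").write_text(
        "".join(u + "\n" for u in counts.unit_ids)
    )


def read_labels(path) -> CellLabels:
    """Read a two-column (unit id, label) TSV, optional header.

    A first line whose fields are 'unit_id' and 'label' (case-insensitive)
    is treated as a header.  Type names are ordered by first appearance.
    """
    path = Path(path)
    units: list[str] = []
    labs: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{ln}: expected two tab-separated columns"
                )
            if ln == 1 and parts[0].lower() in ("unit_id", "cell", "barcode") \
                    and parts[1].lower() in ("label", "cell_type", "type"):
                continue
            units.append(parts[0])
            labs.append(parts[1])
    if not units:
        raise ValidationError(f"{path}: no labels")
    seen: dict[str, str] = {}
    for u, l in zip(units, labs):
        if u in seen:
            raise ValidationError(
                f"{path}: unit {u!r} listed more than once "
                f"(labels {seen[u]!r} and {l!r})"
            )
        seen[u] = l
    return CellLabels(units, labs)


def write_labels(labels: CellLabels, path) -> None:
    with open(path, "w") as fh:
        fh.write("unit_id\tlabel\n")
        for u, l in zip(labels.unit_ids, labels.labels):
            fh.write(f"{u}\t{l}\n")


def align_labels(
    counts: CountMatrix, labels: CellLabels
) -> tuple[CountMatrix, CellLabels]:
    """Restrict counts and labels to their shared units, in count order.

    Units present on only one side are dropped with a warning.  Idempotent;
    an empty intersection is an error.
    """
    label_pos = {u: i for i, u in enumerate(labels.unit_ids)}
    keep = [j for j, u in enumerate(counts.unit_ids) if u in label_pos]
    if not keep:
        raise ValidationError("no units shared between counts and labels")
    dropped_counts = counts.n_units - len(keep)
    dropped_labels = len(labels.unit_ids) - len(keep)
    if dropped_counts:
        lost = [u for u in counts.unit_ids if u not in label_pos]
        logger.warning(
            "align_labels: dropping %d unlabelled unit(s) from counts: %s",
            dropped_counts, ", ".join(lost[:10]),
        )
    if dropped_labels:
        present = set(counts.unit_ids)
        lost = [u for u in labels.unit_ids if u not in present]
        logger.warning(
            "align_labels: dropping %d label(s) without counts: %s",
            dropped_labels, ", ".join(lost[:10]),
        )
    if not dropped_counts and not dropped_labels and all(
        counts.unit_ids[j] == labels.unit_ids[j] for j in range(len(keep))
    ):
        return counts, labels
    new_counts = counts.select_units(keep)
    new_labels = labels.select_units(
        [label_pos[counts.unit_ids[j]] for j in keep]
    )
    return new_counts, new_labels


def align_genes(
    reference: CountMatrix, bulk: CountMatrix
) -> tuple[CountMatrix, CountMatrix]:
    """Restrict both matrices to shared gene ids, in reference order.

    The joint model needs one shared gene index; genes absent from either
    side are dropped with a logged count.
    """
    bulk_pos = {g: i for i, g in enumerate(bulk.gene_ids)}
    keep_ref = [i for i, g in enumerate(reference.gene_ids) if g in bulk_pos]
    if not keep_ref:
        raise ValidationError("no genes shared between reference and bulk")
    n_drop_ref = reference.n_genes - len(keep_ref)
    n_drop_bulk = bulk.n_genes - len(keep_ref)
    if n_drop_ref or n_drop_bulk:
        logger.warning(
            "align_genes: keeping %d shared gene(s); dropped %d from the "
            "reference and %d from the bulk",
            len(keep_ref), n_drop_ref, n_drop_bulk,
        )
    ref2 = reference.select_genes(keep_ref)
    bulk2 = bulk.select_genes(
        [bulk_pos[reference.gene_ids[i]] for i in keep_ref]
    )
    return ref2, bulk2


def _safe_name(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-." else "_" for c in name)


def write_decomposition(
    result: DecompositionResult, out_dir, metadata: dict | None = None
) -> list[Path]:
    """Write one decomposition to ``out_dir``.

    Emits ``composition.tsv`` (cell types x replicates), ``scale.tsv``,
    one ``allocations_<type>.tsv`` per cell type (genes x replicates),
    the adapted profiles ``X.tsv`` / ``T.tsv`` and ``metadata.json``
    recording convergence, iteration count and any caller-supplied run
    parameters.  Numeric formatting is fixed, so identical results produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _frame(df: pd.DataFrame, name: str, index_label: str):
        p = out / name
        df.to_csv(p, sep="\t", float_format=_FLOAT_FMT,
                  index_label=index_label)
        written.append(p)

    _frame(
        pd.DataFrame(result.composition, index=result.type_names,
                     columns=result.replicate_ids),
        "composition.tsv", "cell_type",
    )
    _frame(
        pd.DataFrame(result.scale[None, :], index=["scale"],
                     columns=result.replicate_ids),
        "scale.tsv", "quantity",
    )
    for li, tname in enumerate(result.type_names):
        _frame(
            pd.DataFrame(result.allocations[:, li, :],
                         index=result.gene_ids,
                         columns=result.replicate_ids),
            f"allocations_{_safe_name(tname)}.tsv", "gene_id",
        )
    _frame(
        pd.DataFrame(result.X, index=result.gene_ids,
                     columns=result.type_names),
        "X.tsv", "gene_id",
    )
    _frame(
        pd.DataFrame(result.T, index=result.gene_ids,
                     columns=result.type_names),
        "T.tsv", "gene_id",
    )
    meta = {
        "sample_id": result.sample_id,
        "converged": bool(result.converged),
        "n_iter": int(result.n_iter),
        "loglik_first": float(result.loglik_trace[0]),
        "loglik_last": float(result.loglik_trace[-1]),
        "n_genes": len(result.gene_ids),
        "n_types": len(result.type_names),
        "replicates": result.replicate_ids,
    }
    if metadata:
        meta["run"] = metadata
    p = out / "metadata.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written
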