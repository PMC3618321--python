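"""Reading, writing and filtering of gene-set collections and matrices.

Formats are plain text: GMT for gene sets (one set per line, tab
separated: name, description, members) and TSV for expression / score
matrices (first column identifiers, header row of sample IDs, optional
``#`` comment lines).  Gene identifiers are matched by exact,
case-sensitive string equality throughout; any identifier translation is
the caller's responsibility.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import (
    CONTINUOUS,
    COUNTS,
    EnrichmentMatrix,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "apply_size_filter",
    "iqr_filter",
    "read_expression",
    "write_expression",
    "write_scores",
    "read_scores",
]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line must carry at least three tab-separated fields: set name,
    description, and one or more gene identifiers.  Member order is
    preserved; duplicate members within a line are dropped with a
    warning; a duplicate set name across lines is a hard error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            # trailing empty fields (e.g. from spreadsheet exports) are ignored
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name, description, *members = fields
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning(
                    "%s:%d: dropped %d duplicate member(s) in set %r",
                    path, lineno, len(members) - len(unique), name,
                )
            sets.append(GeneSet(name=name, description=description, members=tuple(unique)))
    return GeneSetCollection(sets=sets, provenance=str(path))


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to GMT; inverse of :func:`read_gmt`."""
    with Path(path).open("w") as fh:
        for s in gsc:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def apply_size_filter(
    gsc: GeneSetCollection,
    expr: ExpressionMatrix,
    min_size: int = 10,
    max_size: int = 500,
) -> GeneSetCollection:
    """Map sets onto the expression matrix and drop out-of-size sets.

    Members are first intersected with ``expr.gene_ids`` (order
    preserved); sets whose mapped size falls outside
    ``[min_size, max_size]`` (both bounds kept) are removed.  The default
    bounds 10 and 500 are the conventional non-specific filter for
    pathway collections.  The operation is idempotent.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if min_size > max_size:
        raise ValueError("min_size must not exceed max_size")
    present = set(expr.gene_ids)
    kept: list[GeneSet] = []
    n_removed = 0
    for s in gsc:
        mapped = tuple(g for g in s.members if g in present)
        if min_size <= len(mapped) <= max_size:
            kept.append(GeneSet(name=s.name, description=s.description, members=mapped))
        else:
            n_removed += 1
    if n_removed:
        logger.info(
            "size filter [%d, %d]: removed %d of %d gene sets after mapping",
            min_size, max_size, n_removed, len(gsc),
        )
    if not kept:
        raise ValueError("no gene sets survive size filtering")
    return GeneSetCollection(sets=kept, provenance=gsc.provenance)


def iqr_filter(expr: ExpressionMatrix, drop_fraction: float = 0.5) -> ExpressionMatrix:
    """Drop the least variable genes as measured by the interquartile range.

    The ``floor(p * drop_fraction)`` genes with the lowest IQR across
    samples are removed; the survivors keep their original row order.
    Ties at the cut boundary are resolved in favour of earlier rows.
    Intended for continuous (e.g. log2 microarray) data as a
    non-specific variance filter before scoring.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    if expr.value_kind != CONTINUOUS:
        raise ValueError("iqr_filter expects continuous expression values")
    if drop_fraction == 0:
        return expr
    p = expr.n_genes
    k = math.floor(p * drop_fraction)
    if k == 0:
        return expr
    iqr = np.percentile(expr.values, 75, axis=1) - np.percentile(expr.values, 25, axis=1)
    # primary key: IQR ascending; among ties, later rows drop first so
    # earlier rows are preferentially kept
    order = np.lexsort((-np.arange(p), iqr))
    dropped = set(order[:k].tolist())
    keep = np.array([i for i in range(p) if i not in dropped], dtype=int)
    logger.info("IQR filter: dropped %d of %d genes (fraction %.3g)", k, p, drop_fraction)
    return expr.subset_genes(keep)


def _read_matrix_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    # a header row is mandatory; if every column label parses as a number
    # the file almost certainly lacks one
    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if all(_numeric(str(c)) for c in df.columns):
        raise ValueError(f"{path}: missing header row (all column labels are numeric)")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        if converted.isna().any():
            row = df.index[converted.isna().argmax()]
            raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")
        out[col] = converted
    return out


def read_expression(path: str | Path, value_kind: str = CONTINUOUS) -> ExpressionMatrix:
    """Read a genes x samples TSV into an :class:`ExpressionMatrix`.

    ``value_kind="counts"`` additionally enforces non-negative integer
    entries; a fractional cell is reported with its coordinates.
    """
    df = _read_matrix_frame(path)
    try:
        return ExpressionMatrix.from_frame(df, value_kind=value_kind)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV at 12 significant digits."""
    expr.to_frame().to_csv(path, sep="\t", float_format="%.12g", index_label="gene_id")


def write_scores(em: EnrichmentMatrix, path: str | Path) -> None:
    """Write an enrichment-score matrix as TSV with a reproducibility header."""
    with Path(path).open("w") as fh:
        fh.write(f"# method={em.method}\n")
        fh.write(f"# params={em.params_json()}\n")
        em.to_frame().to_csv(fh, sep="\t", float_format="%.12g", index_label="gene_set")


def read_scores(path: str | Path) -> EnrichmentMatrix:
    """Read a score TSV written by :func:`write_scores`."""
    import json

    method = ""
    params: dict = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("method="):
                method = body[len("method="):]
            elif body.startswith("params="):
                params = json.loads(body[len("params="):])
    df = _read_matrix_frame(path)
    return EnrichmentMatrix(
        scores=df.to_numpy(dtype=float),
        set_names=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        method=method,
        params=params,
    )
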