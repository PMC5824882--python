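"""Readers and writers for expression matrices and metadata tables.

Dense matrices travel as UTF-8 tab-separated text (first column gene ids,
header row sample ids). Sparse single-cell matrices can additionally be
stored as MatrixMarket triplets with ``genes.txt``/``cells.txt`` sidecars.
Metadata and result tables are TSV throughout.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import DEFAULT_GATES, ExpressionMatrix, validate_metadata

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_expression_mtx",
    "write_expression_mtx",
    "read_metadata",
    "write_metadata",
]


def read_expression(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a dense genes-x-samples TSV into an :class:`ExpressionMatrix`.

    Row and column order are preserved from the file. Duplicate ids,
    non-numeric cells, missing values and negative TPM values are hard
    errors (the first offending coordinate is named).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    _find_duplicate(gene_ids, "gene", path)
    _find_duplicate(sample_ids, "sample", path)
    values = np.empty(raw.shape, dtype=np.float64)
    for j, col in enumerate(raw.columns):
        strings = raw[col].to_numpy(dtype=object)
        try:
            # numpy's parser is correctly rounded (exact round-trips)
            converted = strings.astype(np.float64)
        except (ValueError, TypeError):
            converted = None
        if converted is None or np.isnan(converted).any():
            for i, cell in enumerate(strings):
                try:
                    v = float(cell)
                except (ValueError, TypeError):
                    v = np.nan
                if np.isnan(v):
                    raise ValueError(
                        f"{path}: non-numeric or missing value {cell!r} at "
                        f"gene {gene_ids[i]!r} (row {i + 2}), sample "
                        f"{sample_ids[j]!r} (column {j + 2})"
                    )
            raise AssertionError("unreachable")
        values[:, j] = converted
    return ExpressionMatrix(gene_ids, sample_ids, values, scale)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a dense TSV; round-trips exactly through :func:`read_expression`."""
    # repr formatting guarantees exact float round-trips
    m.to_frame().to_csv(
        path,
        sep="\t",
        index_label="gene_id",
        float_format=lambda v: repr(float(v)),
    )


def write_expression_mtx(m: ExpressionMatrix, outdir: str | Path) -> None:
    """Write MatrixMarket triplets plus ``genes.txt``/``cells.txt`` sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(m.values)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sparse)
    (outdir / "genes.txt").write_text("\n".join(m.gene_ids) + "\n")
    (outdir / "cells.txt").write_text("\n".join(m.sample_ids) + "\n")


def read_expression_mtx(indir: str | Path, scale: str) -> ExpressionMatrix:
    indir = Path(indir)
    values = scipy.io.mmread(str(indir / "matrix.mtx")).toarray()
    gene_ids = (indir / "genes.txt").read_text().splitlines()
    sample_ids = (indir / "cells.txt").read_text().splitlines()
    return ExpressionMatrix(gene_ids, sample_ids, values, scale)


def read_metadata(
    path: str | Path,
    gate_vocabulary: Sequence[str] = DEFAULT_GATES,
    matrix: ExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Read and validate a sample metadata TSV.

    If ``matrix`` is given, metadata rows referencing samples absent from
    it are retained but logged as warnings (join consistency is the
    caller's decision).
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    meta = validate_metadata(meta, gate_vocabulary)
    if matrix is not None:
        known = set(matrix.sample_ids)
        orphans = [s for s in meta["sample_id"] if s not in known]
        for s in orphans[:10]:
            logger.warning("metadata sample %r not present in matrix", s)
        if len(orphans) > 10:
            logger.warning("... and %d more orphan samples", len(orphans) - 10)
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def _find_duplicate(ids: list[str], what: str, path) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"{path}: duplicate {what} identifier {x!r}")
        seen.add(x)
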