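"""Reading and writing count matrices and edge lists.

Two on-disk layouts are supported for counts:

* delimited text (``.csv`` / ``.tsv``): genes in rows, a header row of cell
  identifiers, gene identifiers in the first column;
* MatrixMarket (``.mtx``): integer triplet matrix plus two sidecar text
  files ``<stem>.genes.txt`` and ``<stem>.cells.txt`` with one label per
  line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .model_core import ExpressionCounts

__all__ = ["read_counts", "write_counts"]


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".genes.txt"), stem.with_suffix(".cells.txt")


def read_counts(path) -> ExpressionCounts:
    """Load a genes x cells count matrix; format inferred from the suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".csv", ".tsv", ".txt"):
        sep = "\t" if suffix == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        bad = df.columns[df.isna().any() | ~df.map(np.isreal).all()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric or missing entries in column {bad[0]!r}")
        return ExpressionCounts(
            values=df.to_numpy(),
            gene_ids=list(df.index.astype(str)),
            cell_ids=list(df.columns.astype(str)),
        )
    if suffix == ".mtx":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        genes_path, cells_path = _sidecars(path)
        gene_ids = cell_ids = None
        if genes_path.exists():
            gene_ids = genes_path.read_text().split()
        if cells_path.exists():
            cell_ids = cells_path.read_text().split()
        return ExpressionCounts(values=mat, gene_ids=gene_ids, cell_ids=cell_ids)
    raise ValueError(f"unrecognized counts format: {path.suffix!r}")


def write_counts(counts: ExpressionCounts, path) -> None:
    """Write counts in the format implied by the path suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".csv", ".tsv"):
        sep = "\t" if suffix == ".tsv" else ","
        df = pd.DataFrame(counts.values, index=counts.gene_ids, columns=counts.cell_ids)
        df.to_csv(path, sep=sep)
        return
    if suffix == ".mtx":
        spio.mmwrite(path, sparse.coo_matrix(counts.values), field="integer")
        genes_path, cells_path = _sidecars(path)
        genes_path.write_text("\n".join(counts.gene_ids) + "\n")
        cells_path.write_text("\n".join(counts.cell_ids) + "\n")
        return
    raise ValueError(f"unrecognized counts format: {path.suffix!r}")
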