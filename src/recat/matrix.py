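"""Expression matrices, gene catalogs and their on-disk formats.

The central container is :class:`ExpressionMatrix`, a genes x cells matrix
with named axes, a unit tag (counts / TPM / FPKM) and a layer tag recording
where it sits in the raw -> normalized -> log2 processing chain.  Dense
TSV/CSV (first column gene ids, header row cell ids) and MatrixMarket
coordinate files (with ``genes.txt`` / ``cells.txt`` sidecars) are supported.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

VALID_UNITS = ("counts", "TPM", "FPKM")
VALID_LAYERS = ("raw", "normalized", "log2")
PEAK_STAGES = ("G1", "G1/S", "S", "G2", "G2/M", "M")

# only forward moves along the processing chain are legal
_LAYER_ORDER = {layer: i for i, layer in enumerate(VALID_LAYERS)}


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x cells expression matrix with named axes.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_cells)
        Nonnegative expression values.
    gene_ids, cell_ids : sequences of unique strings.
    unit : {"counts", "TPM", "FPKM"}
    layer : {"raw", "normalized", "log2"}
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    unit: str = "TPM"
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise ValidationError("negative expression values")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.layer not in VALID_LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {VALID_LAYERS}")

    # -- convenience ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def with_layer(self, values: np.ndarray, layer: str) -> "ExpressionMatrix":
        """Return a copy carrying new values at a later processing layer."""
        if _LAYER_ORDER[layer] < _LAYER_ORDER[self.layer]:
            raise ValidationError(f"illegal layer transition {self.layer} -> {layer}")
        return ExpressionMatrix(values, list(self.gene_ids), list(self.cell_ids), self.unit, layer)

    def subset_genes(self, keep: Sequence[int]) -> "ExpressionMatrix":
        keep = list(keep)
        return ExpressionMatrix(
            self.values[keep, :], [self.gene_ids[i] for i in keep],
            list(self.cell_ids), self.unit, self.layer,
        )

    def subset_cells(self, keep: Sequence[int]) -> "ExpressionMatrix":
        keep = list(keep)
        return ExpressionMatrix(
            self.values[:, keep], list(self.gene_ids),
            [self.cell_ids[i] for i in keep], self.unit, self.layer,
        )


@dataclass
class GeneCatalog:
    """Cycle-gene catalog: gene id, stage of peak expression, confidence rank.

    Mirrors a Cyclebase-style list where every gene carries a recorded
    "peaktime" stage out of the six-stage partition of the cycle.
    """

    table: pd.DataFrame  # columns: gene, peak_stage, rank

    def __post_init__(self) -> None:
        required = {"gene", "peak_stage", "rank"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"catalog needs columns {sorted(required)}")
        if self.table["gene"].duplicated().any():
            dup = self.table["gene"][self.table["gene"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate catalog gene id {dup!r}")
        bad = set(self.table["peak_stage"]) - set(PEAK_STAGES)
        if bad:
            raise ValidationError(f"unknown peak stages {sorted(bad)}")
        if (self.table["rank"] <= 0).any():
            raise ValidationError("catalog ranks must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene"])

    def genes_for_stage(self, stage: str) -> list[str]:
        return list(self.table.loc[self.table["peak_stage"] == stage, "gene"])

    def top_ranked(self, n_per_stage: int, stages: Sequence[str] = PEAK_STAGES) -> "GeneCatalog":
        """Derived view: the n highest-ranked genes per peak stage."""
        parts = []
        for stage in stages:
            sub = self.table[self.table["peak_stage"] == stage].nsmallest(n_per_stage, "rank")
            parts.append(sub)
        return GeneCatalog(pd.concat(parts, ignore_index=True))


@dataclass
class QcReport:
    cells_in: int
    cells_kept: int
    genes_in: int
    genes_kept: int
    detected_genes_per_cell: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cells_kept > self.cells_in or self.genes_kept > self.genes_in:
            raise ValidationError("kept counts exceed input counts")
        if min(self.cells_in, self.cells_kept, self.genes_in, self.genes_kept) < 0:
            raise ValidationError("negative QC counts")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression(
    path: str | os.PathLike,
    format: str | None = None,
    unit: str = "TPM",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    ``format`` is one of ``tsv``, ``csv`` or ``mtx``; when omitted it is
    inferred from the file suffix.  MTX input expects ``genes.txt`` and
    ``cells.txt`` name files next to the matrix.  ``transpose`` handles
    cells x genes dialects on disk.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as err:  # pragma: no cover - message path
            raise ValidationError(f"malformed {format} file {path}: {err}") from err
        values = df.to_numpy(dtype=float)
        genes, cells = list(df.index.astype(str)), list(df.columns.astype(str))
    elif format == "mtx":
        for sidecar in ("genes.txt", "cells.txt"):
            if not (path.parent / sidecar).exists():
                raise FileNotFoundError(f"MTX sidecar {sidecar} missing next to {path}")
        mat = spio.mmread(path)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        genes = (path.parent / "genes.txt").read_text().split()
        cells = (path.parent / "cells.txt").read_text().split()
    else:
        raise ValueError(f"unknown format {format!r}")
    if transpose:
        values = values.T
        genes, cells = cells, genes
    return ExpressionMatrix(values, genes, cells, unit=unit, layer="raw")


def write_expression_tsv(mat: ExpressionMatrix, path: str | os.PathLike) -> None:
    mat.to_frame().to_csv(path, sep="\t", index_label="gene")


def write_expression_mtx(mat: ExpressionMatrix, path: str | os.PathLike) -> None:
    path = Path(path)
    spio.mmwrite(str(path), sparse.coo_matrix(mat.values))
    (path.parent / "genes.txt").write_text("\n".join(mat.gene_ids) + "\n")
    (path.parent / "cells.txt").write_text("\n".join(mat.cell_ids) + "\n")


def read_catalog(path: str | os.PathLike) -> GeneCatalog:
    """Read a 3-column catalog TSV (gene, peak_stage, rank)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return GeneCatalog(df[["gene", "peak_stage", "rank"]])


def write_catalog(catalog: GeneCatalog, path: str | os.PathLike) -> None:
    catalog.table.to_csv(path, sep="\t", index=False)


def read_labels(path: str | os.PathLike) -> pd.Series:
    """Per-cell labels as a TSV with columns (cell, label)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return pd.Series(df["label"].to_numpy(), index=df["cell"].astype(str), name="label")
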