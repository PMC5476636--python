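"""Quality control, depth normalization and cycle-gene selection.

The preprocessing chain for TPM/FPKM data: keep cells with more than
``min_genes`` genes expressed above ``min_expr`` (strictly), drop genes whose
mean expression falls below ``min_mean``, rescale cells by median-of-ratios
size factors, log2(x+1)-transform, and restrict to the cycle-gene catalog.
For count data the same operations apply but the cell-QC thresholds are
dataset-specific and must be supplied by the caller.
"""

from __future__ import annotations

import warnings

import numpy as np

from .matrix import ExpressionMatrix, GeneCatalog, QcReport, ValidationError


def qc_filter_cells(
    mat: ExpressionMatrix, min_genes: int = 4000, min_expr: float = 2.0
) -> tuple[ExpressionMatrix, QcReport]:
    """Keep cells with strictly more than ``min_genes`` genes strictly above ``min_expr``.

    The defaults (4000 genes above expression 2) are the eligibility rule for
    TPM/FPKM data; both bounds are strict ("more than", "exceeding").
    """
    if mat.layer != "raw":
        raise ValidationError("cell QC operates on the raw layer")
    detected = (mat.values > min_expr).sum(axis=0)
    keep = np.flatnonzero(detected > min_genes)
    if keep.size == 0:
        raise ValidationError(
            f"no eligible cells: no cell has more than {min_genes} genes above {min_expr}"
        )
    report = QcReport(
        cells_in=mat.n_cells,
        cells_kept=int(keep.size),
        genes_in=mat.n_genes,
        genes_kept=mat.n_genes,
        detected_genes_per_cell={c: int(d) for c, d in zip(mat.cell_ids, detected)},
    )
    return mat.subset_cells(keep), report


def qc_filter_genes(mat: ExpressionMatrix, min_mean: float = 2.0) -> ExpressionMatrix:
    """Keep genes whose mean expression across cells is >= ``min_mean``.

    The boundary is inclusive: only genes with mean strictly lower than the
    threshold are considered uninformative and dropped.
    """
    if mat.layer != "raw":
        raise ValidationError("gene QC operates on the raw layer")
    means = mat.values.mean(axis=1)
    keep = np.flatnonzero(means >= min_mean)
    if keep.size == 0:
        raise ValidationError(f"no genes with mean expression >= {min_mean}")
    return mat.subset_genes(keep)


def deseq_size_factors(mat: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios size factors (DESeq convention).

    Reference genes are those expressed (> 0) in every cell; the factor of
    cell j is the median over reference genes of e_gj / geomean_g(e_g.).
    """
    if mat.layer != "raw":
        raise ValidationError("size factors are computed on the raw layer")
    positive_everywhere = np.all(mat.values > 0, axis=1)
    if not positive_everywhere.any():
        raise ValidationError(
            "no gene is expressed in every cell; relax gene QC before computing size factors"
        )
    ref = mat.values[positive_everywhere, :]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.exp(np.log(ref) - log_geomean[:, None])
    return np.median(ratios, axis=0)


def normalize(mat: ExpressionMatrix, size_factors: np.ndarray | None = None) -> ExpressionMatrix:
    """Divide each cell by its size factor; tags the ``normalized`` layer."""
    if size_factors is None:
        size_factors = deseq_size_factors(mat)
    size_factors = np.asarray(size_factors, dtype=float)
    if size_factors.shape != (mat.n_cells,) or np.any(size_factors <= 0):
        raise ValidationError("size factors must be positive, one per cell")
    return mat.with_layer(mat.values / size_factors[None, :], "normalized")


def log_transform(mat: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform; tags the ``log2`` layer."""
    if mat.layer == "log2":
        raise ValidationError("matrix is already log-transformed")
    return mat.with_layer(np.log2(mat.values + 1.0), "log2")


def subset_to_catalog(
    mat: ExpressionMatrix, catalog: GeneCatalog, case_insensitive: bool = False
) -> ExpressionMatrix:
    """Restrict to genes present in the catalog, preserving matrix gene order.

    Matching is exact and case-sensitive by default; ``case_insensitive``
    enables a lower-cased fallback for mismatched id schemes.
    """
    if case_insensitive:
        wanted = {g.lower() for g in catalog.gene_ids}
        keep = [i for i, g in enumerate(mat.gene_ids) if g.lower() in wanted]
    else:
        wanted = set(catalog.gene_ids)
        keep = [i for i, g in enumerate(mat.gene_ids) if g in wanted]
    if not keep:
        examples = ", ".join(catalog.gene_ids[:3])
        raise ValidationError(
            f"no overlap between matrix genes and catalog (catalog starts: {examples}); "
            "check id schemes or use case_insensitive=True"
        )
    missing = len(catalog.gene_ids) - len(keep)
    if missing:
        warnings.warn(f"{missing} catalog genes absent from the matrix", stacklevel=2)
    return mat.subset_genes(keep)


def preprocess(
    mat: ExpressionMatrix,
    catalog: GeneCatalog | None = None,
    min_genes: int | None = None,
    min_expr: float = 2.0,
    min_mean: float = 2.0,
    size_factor_normalize: bool = True,
) -> tuple[ExpressionMatrix, QcReport]:
    """Full chain: cell QC -> gene QC -> size factors -> log2 -> catalog subset.

    ``min_genes`` defaults to 4000 for TPM/FPKM input; for counts the caller
    must choose thresholds appropriate to the protocol.
    """
    if min_genes is None:
        if mat.unit == "counts":
            raise ValidationError(
                "cell QC thresholds for count data are dataset-specific; pass min_genes explicitly"
            )
        min_genes = 4000
    mat, report = qc_filter_cells(mat, min_genes=min_genes, min_expr=min_expr)
    mat = qc_filter_genes(mat, min_mean=min_mean)
    report.genes_kept = mat.n_genes
    if size_factor_normalize:
        mat = normalize(mat)
    mat = log_transform(mat)
    if catalog is not None:
        mat = subset_to_catalog(mat, catalog)
    return mat, report
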