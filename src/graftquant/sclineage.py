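"""Single-cell QC filtering and lineage-gene partitioning of DE tables.

Two rule sets from the graft-rejection transcriptomics workflow:

1. UMI count-matrix QC: keep genes expressed (count > 0) in more than 10
   cells; then keep cells whose mitochondrial UMI fraction is at most 0.3%
   and whose detected-gene count lies in [300, 4000] inclusive. The gene
   filter runs first, and detected-gene counts are taken after it.

2. DELG partitioning: from a gene-level differential-expression table for
   a rejection-vs-no-rejection contrast, the differentially expressed
   lineage genes (DELGs) are the endothelial or tubular-epithelial lineage
   genes with |logFC| > 0.2 and adjusted P < 1e-8 (both strict). The
   endothelial/epithelial composition of the DELG lists is compared
   between two contrasts (e.g. AMR vs TCMR) by a chi-square test on the
   2x2 lineage x contrast table without continuity correction.

Clustering, annotation, normalization models and DE fitting are consumed
as inputs (established implementations), never re-derived here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "CountMatrix",
    "LineageGeneSets",
    "DelgResult",
    "QCResult",
    "NormalizationError",
    "qc_filter",
    "lognormalize",
    "delg_partition",
    "delg_contrast_chi2",
    "MITO_PREFIX",
]

MITO_PREFIX = "MT-"


class NormalizationError(ValueError):
    """A cell has zero total counts; log-normalization undefined."""


@dataclass
class CountMatrix:
    """Sparse gene x cell integer UMI counts with names and mito flags."""

    counts: sparse.csr_matrix  # genes x cells
    genes: list[str]
    barcodes: list[str]
    mito: np.ndarray | None = None  # bool per gene

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("counts shape does not match gene/barcode lists")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene names must be unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("cell barcodes must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be >= 0")
        if self.mito is None:
            self.mito = np.array(
                [g.upper().startswith(MITO_PREFIX) for g in self.genes], dtype=bool
            )
        else:
            self.mito = np.asarray(self.mito, dtype=bool)
            if self.mito.size != len(self.genes):
                raise ValueError("mito flags must match gene count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class LineageGeneSets:
    """Disjoint endothelial and tubular-epithelial lineage gene lists."""

    endothelial: tuple[str, ...]
    epithelial: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.endothelial or not self.epithelial:
            raise ValueError("lineage lists must be non-empty")
        if set(self.endothelial) & set(self.epithelial):
            raise ValueError("lineage lists must be disjoint")


@dataclass(frozen=True)
class QCResult:
    matrix: CountMatrix
    gene_kept: np.ndarray
    cell_kept: np.ndarray
    n_genes_removed: int
    n_cells_removed: int
    empty: bool


@dataclass(frozen=True)
class DelgResult:
    """DELG list and lineage composition for one contrast."""

    contrast: str
    delgs: tuple[str, ...]
    n_endothelial: int
    n_epithelial: int
    pct_endothelial: float = field(default=float("nan"))
    pct_epithelial: float = field(default=float("nan"))
    undefined: bool = False

    def __post_init__(self) -> None:
        n = self.n_endothelial + self.n_epithelial
        if n > 0:
            object.__setattr__(self, "pct_endothelial", 100.0 * self.n_endothelial / n)
            object.__setattr__(self, "pct_epithelial", 100.0 * self.n_epithelial / n)
        else:
            object.__setattr__(self, "undefined", True)


def qc_filter(
    matrix: CountMatrix,
    min_cells_per_gene: int = 10,
    min_genes: int = 300,
    max_genes: int = 4000,
    mito_max: float = 0.003,
) -> QCResult:
    """Apply the gene filter, then the cell filters.

    Genes are kept iff expressed in strictly more than ``min_cells_per_gene``
    cells. Cells are kept iff the mitochondrial UMI fraction is <=
    ``mito_max`` (strictly greater removes) AND the detected-gene count,
    computed after gene filtering, lies in [min_genes, max_genes] inclusive.
    """
    counts = matrix.counts
    cells_per_gene = np.asarray((counts > 0).sum(axis=1)).ravel()
    gene_kept = cells_per_gene > min_cells_per_gene

    sub = counts[gene_kept]
    mito_sub = matrix.mito[gene_kept]
    detected = np.asarray((sub > 0).sum(axis=0)).ravel()
    totals = np.asarray(sub.sum(axis=0)).ravel()
    mito_counts = np.asarray(sub[mito_sub].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    cell_kept = (
        (mito_frac <= mito_max) & (detected >= min_genes) & (detected <= max_genes)
    )

    filtered = CountMatrix(
        sub[:, cell_kept],
        [g for g, k in zip(matrix.genes, gene_kept) if k],
        [b for b, k in zip(matrix.barcodes, cell_kept) if k],
        mito_sub,
    )
    return QCResult(
        matrix=filtered,
        gene_kept=gene_kept,
        cell_kept=cell_kept,
        n_genes_removed=int((~gene_kept).sum()),
        n_cells_removed=int((~cell_kept).sum()),
        empty=not bool(cell_kept.any()),
    )


def lognormalize(matrix: CountMatrix, scale: float = 1e4) -> sparse.csr_matrix:
    """Per-cell library-size normalization: ln(1 + count / total * scale)."""
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    if np.any(totals == 0):
        raise NormalizationError("cell with zero total counts")
    norm = matrix.counts.multiply(scale / totals[None, :]).tocsr()
    norm.data = np.log1p(norm.data)
    return norm


def delg_partition(
    de_table: pd.DataFrame,
    lineage_sets: LineageGeneSets,
    contrast: str = "",
    lfc_min: float = 0.2,
    adjp_max: float = 1e-8,
    gene_column: str = "gene",
    lfc_column: str = "logFC",
    adjp_column: str = "adj_p",
) -> DelgResult:
    """Select the lineage genes passing the DE thresholds (both strict)."""
    tab = de_table[[gene_column, lfc_column, adjp_column]].dropna()
    lineage = set(lineage_sets.endothelial) | set(lineage_sets.epithelial)
    passing = tab[
        tab[gene_column].isin(lineage)
        & (tab[lfc_column].abs() > lfc_min)
        & (tab[adjp_column] < adjp_max)
    ]
    delgs = tuple(sorted(passing[gene_column].unique()))
    endo = set(lineage_sets.endothelial)
    n_endo = sum(g in endo for g in delgs)
    return DelgResult(
        contrast=contrast,
        delgs=delgs,
        n_endothelial=n_endo,
        n_epithelial=len(delgs) - n_endo,
    )


def delg_contrast_chi2(a: DelgResult, b: DelgResult) -> dict[str, float]:
    """Chi-square test (no continuity correction) on the 2x2 table of
    lineage composition (endothelial/epithelial) across two contrasts."""
    table = np.array(
        [
            [a.n_endothelial, a.n_epithelial],
            [b.n_endothelial, b.n_epithelial],
        ]
    )
    if table.sum(axis=1).min() == 0:
        raise ValueError("each contrast needs at least one DELG")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
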