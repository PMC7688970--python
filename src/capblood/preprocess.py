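"""Gene filtering and per-cell fraction normalization.

Two filters bracket cell typing: before typing, genes whose maximum
per-cell count is below 3 are discarded; after typing, genes detected in
fewer than 10% of the cells of every cell type are discarded.

Normalization divides each gene's count in a cell by the cell's total
count, giving per-cell transcript fractions (each row sums to one). A
separate visualization transform ``log(scale * f + 1)`` with scale 5000 is
used for display and as the input convention for the debris-removal PCA —
never for the statistical tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import CellAnnotation, CountMatrix

logger = logging.getLogger(__name__)

VIZ_SCALE = 5000.0


@dataclass
class NormalizedMatrix:
    """Row-stochastic transcript fractions with provenance to raw counts."""

    fractions: sp.csr_matrix
    barcodes: np.ndarray
    gene_ids: np.ndarray
    gene_names: np.ndarray
    source: CountMatrix | None = None

    @property
    def n_barcodes(self) -> int:
        return self.fractions.shape[0]

    @property
    def n_genes(self) -> int:
        return self.fractions.shape[1]

    def subset_barcodes(self, idx) -> "NormalizedMatrix":
        idx = np.asarray(idx)
        return NormalizedMatrix(
            self.fractions[idx], self.barcodes[idx], self.gene_ids,
            self.gene_names, self.source,
        )


def filter_genes_pre(matrix: CountMatrix, min_max_count: int = 3) -> CountMatrix:
    """Drop genes whose maximum count across cells is below ``min_max_count``."""
    if matrix.n_genes == 0:
        return matrix
    if matrix.n_barcodes == 0:
        # no cell reaches any count: every gene fails the max-count rule
        return matrix.subset_genes(np.zeros(matrix.n_genes, dtype=bool))
    col_max = matrix.counts.max(axis=0).toarray().ravel()
    keep = col_max >= min_max_count
    logger.info("pre-filter: %d/%d genes retained", keep.sum(), keep.size)
    return matrix.subset_genes(keep)


def filter_genes_post(
    matrix: CountMatrix,
    annotation: CellAnnotation,
    min_fraction: float = 0.10,
) -> CountMatrix:
    """Keep genes detected in >= ``min_fraction`` of cells of some cell type."""
    kept = annotation.kept()
    typed = kept.dropna(subset=["cell_type"])
    if typed.empty:
        raise ValueError("no typed cells; run cell typing first")
    bc_pos = {b: i for i, b in enumerate(matrix.barcodes)}
    binary = matrix.counts.astype(bool).astype(np.int8)
    keep = np.zeros(matrix.n_genes, dtype=bool)
    for cell_type, grp in typed.groupby("cell_type"):
        rows = [bc_pos[b] for b in grp.index if b in bc_pos]
        if not rows:
            continue
        if len(rows) == 1:
            logger.warning(
                "cell type %r has a single cell; 10%% rule is trivially met "
                "by any expressed gene (small denominator)", cell_type
            )
        detected = np.asarray(binary[rows].sum(axis=0)).ravel() / len(rows)
        keep |= detected >= min_fraction
    logger.info("post-filter: %d/%d genes retained", keep.sum(), keep.size)
    return matrix.subset_genes(keep)


def normalize(matrix: CountMatrix) -> NormalizedMatrix:
    """Per-cell transcript fractions: counts divided by the cell's total."""
    totals = matrix.total_umis()
    nonzero = totals > 0
    if not nonzero.all():
        logger.warning(
            "%d barcodes with zero total counts dropped", int((~nonzero).sum())
        )
    mat = matrix.subset_barcodes(np.flatnonzero(nonzero))
    inv = sp.diags(1.0 / mat.total_umis())
    fractions = sp.csr_matrix(inv @ mat.counts)
    return NormalizedMatrix(
        fractions, mat.barcodes, mat.gene_ids, mat.gene_names, source=matrix
    )


def viz_transform(values, scale: float = VIZ_SCALE):
    """``log(scale * f + 1)`` (natural log); display / PCA-input convention.

    Accepts a sparse matrix (returned sparse; zeros map to zero), an ndarray,
    or a NormalizedMatrix (its fractions are transformed).
    """
    if isinstance(values, NormalizedMatrix):
        values = values.fractions
    if sp.issparse(values):
        out = values.copy().astype(float)
        out.data = np.log1p(scale * out.data)
        return out
    return np.log1p(scale * np.asarray(values, dtype=float))
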