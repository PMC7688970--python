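"""Embedding, clustering, and marker-based annotation of cell types.

Cells are clustered by Ward agglomerative clustering in a low-dimensional
embedding. The default embedding is a 10-component PCA of the
visualization-transformed transcript fractions; a precomputed latent space
(e.g. a batch-conditioned autoencoder trained externally) can be substituted
through :func:`external_embedding`, which is the supported path for batch
correction.

The cluster count is scanned from ``k_min`` upward: at each k every cluster
is annotated by marker-panel score and the scan stops at the first k where
every panel cell type is the top annotation of at least one cluster.
Clusters sharing an annotation are merged into a single cell type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .io import CellAnnotation
from .preprocess import NormalizedMatrix, viz_transform

logger = logging.getLogger(__name__)

DEFAULT_PANEL = {
    "CD4 T cells": ["CD4", "IL7R", "TRAC", "CCR7", "LTB"],
    "CD8 T cells": ["CD8A", "CD8B", "GZMK", "CCL5", "KLRG1"],
    "NK cells": ["NKG7", "GNLY", "KLRD1", "GZMB", "PRF1"],
    "CD14+ Monocytes": ["CD14", "LYZ", "S100A8", "S100A9", "VCAN"],
    "CD16+ Monocytes": ["FCGR3A", "MS4A7", "LST1", "CDKN1C", "CSF1R"],
    "B cells": ["MS4A1", "CD79A", "CD79B", "IGHM", "BANK1"],
}


@dataclass
class Embedding:
    """Low-dimensional coordinates per barcode, tagged by provenance."""

    barcodes: np.ndarray
    coordinates: np.ndarray
    method: str  # "internal-PCA" | "external"

    def __post_init__(self) -> None:
        if len(self.barcodes) != self.coordinates.shape[0]:
            raise ValueError("barcode / coordinate length mismatch")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite embedding coordinates")


def embed(normalized: NormalizedMatrix, d: int = 10, seed: int = 0) -> Embedding:
    """PCA of the viz-transformed fractions into ``d`` dimensions."""
    if normalized.n_barcodes < d + 1:
        raise ValueError(f"need at least {d + 1} cells for a {d}-dim embedding")
    dense = np.asarray(viz_transform(normalized).todense())
    d_eff = min(d, min(dense.shape) - 1)
    coords = PCA(n_components=d_eff, random_state=seed).fit_transform(dense)
    return Embedding(normalized.barcodes, coords, "internal-PCA")


def external_embedding(path_or_df, normalized: NormalizedMatrix) -> Embedding:
    """Load a precomputed latent space; barcodes must match the data."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep="\t", index_col=0)
    missing = set(normalized.barcodes) - set(df.index)
    if missing:
        raise ValueError(
            f"external embedding is missing {len(missing)} barcodes"
        )
    coords = df.loc[list(normalized.barcodes)].to_numpy(dtype=float)
    return Embedding(normalized.barcodes, coords, "external")


def score_cluster_annotation(
    cluster_means: pd.DataFrame, panel: dict
) -> pd.DataFrame:
    """Score every cluster against every panel cell type.

    ``cluster_means`` is clusters x genes mean normalized expression. Each
    marker gene is standardized across clusters; a cluster's score for a
    type is the mean standardized expression of that type's markers.
    Returns a clusters x types score frame.
    """
    scores = {}
    for cell_type, genes in panel.items():
        present = [g for g in genes if g in cluster_means.columns]
        if not present:
            raise ValueError(f"no marker genes of {cell_type!r} in the data")
        sub = cluster_means[present]
        sd = sub.std(axis=0, ddof=0).replace(0.0, 1.0)
        z = (sub - sub.mean(axis=0)) / sd
        scores[cell_type] = z.mean(axis=1)
    return pd.DataFrame(scores)


def _annotate_clusters(score_frame: pd.DataFrame, panel: dict) -> pd.Series:
    """Argmax annotation per cluster; ties broken by panel order."""
    order = list(panel)
    ann = {}
    for cid, row in score_frame.iterrows():
        best = row.max()
        winners = [t for t in order if np.isclose(row[t], best)]
        if len(winners) > 1:
            warnings.warn(
                f"cluster {cid}: tie between {winners}; first panel type kept"
            )
        ann[cid] = winners[0]
    return pd.Series(ann)


def _cluster_mean_expression(
    normalized: NormalizedMatrix, labels: np.ndarray
) -> pd.DataFrame:
    rows = []
    ids = np.unique(labels)
    for cid in ids:
        member = normalized.fractions[labels == cid]
        rows.append(np.asarray(member.mean(axis=0)).ravel())
    return pd.DataFrame(rows, index=ids, columns=normalized.gene_ids)


def cluster_cells(
    embedding: Embedding,
    normalized: NormalizedMatrix,
    annotation: CellAnnotation,
    panel: dict | None = None,
    k_min: int = 13,
    k_max: int = 15,
) -> CellAnnotation:
    """Cluster, annotate, and merge into cell types; incrementing stop rule.

    Scans k from ``k_min`` to ``k_max``; stops at the first k where every
    panel type is the argmax annotation of at least one cluster. If no k
    succeeds, the k annotating the most distinct types is used, with a
    warning. Returns the annotation with ``cell_type`` filled for the
    embedded barcodes.
    """
    panel = DEFAULT_PANEL if panel is None else panel
    if embedding.coordinates.shape[0] < k_max:
        raise ValueError(f"fewer cells than k_max={k_max}")
    Z = linkage(embedding.coordinates, method="ward")

    best = None  # (n_types, k, labels, cluster_annotation)
    for k in range(k_min, k_max + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        means = _cluster_mean_expression(normalized, labels)
        scores = score_cluster_annotation(means, panel)
        cluster_ann = _annotate_clusters(scores, panel)
        found = set(cluster_ann)
        if best is None or len(found) > best[0]:
            best = (len(found), k, labels, cluster_ann)
        if found == set(panel):
            logger.info("cell typing: all %d types separable at k=%d", len(panel), k)
            break
    else:
        warnings.warn(
            f"no k in {k_min}..{k_max} separated all panel types; "
            f"using k={best[1]} with {best[0]} types"
        )
    _, k, labels, cluster_ann = best
    per_cell = pd.Series(
        cluster_ann.loc[labels].to_numpy(dtype=object),
        index=pd.Index(embedding.barcodes),
    )
    return annotation.with_cell_types(per_cell)
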