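"""Cluster-based barcode-dropoff debris removal.

Empty and debris-containing droplets are separated from cells in three
steps. First a UMI-count threshold is chosen on a 50-UMI grid as the
largest threshold retaining more than the expected number of cells;
barcodes below it are discarded outright. The retained barcodes are then
clustered (PCA on log-transformed counts, Ward agglomerative clustering,
cluster number chosen over 6..15 by silhouette). For every cluster a
barcode dropoff trace — the fraction of its barcodes whose total UMI count
survives each grid threshold — is computed, and the traces themselves are
clustered into two groups. The group whose traces drop off faster (smaller
mean normalized area under the trace) is called debris and all its
barcodes are removed.

The silhouette direction is configurable: the conventional choice is to
maximize the score; a literal mode minimizing it is available
(``paper_literal_silhouette=True``) because the source protocol phrases the
selection as a minimization, which contradicts the score's definition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io import CountMatrix

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = range(6, 16)
DEFAULT_STEP = 50


class DegenerateInputError(ValueError):
    """Raised when clustering input admits no meaningful cluster choice."""


@dataclass
class DropoffTrace:
    """Barcode survival census of one cluster over the UMI threshold grid."""

    cluster_id: int
    thresholds: np.ndarray
    remaining: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds)
        self.remaining = np.asarray(self.remaining)
        if np.any(np.diff(self.remaining) > 0):
            raise ValueError("dropoff trace must be non-increasing")

    @property
    def size(self) -> int:
        return int(self.remaining.max(initial=0))

    @property
    def normalized(self) -> np.ndarray:
        return self.remaining / self.remaining[0] if self.remaining[0] else self.remaining.astype(float)

    @property
    def auc(self) -> float:
        """Mean normalized survival over the grid; small = fast dropoff."""
        return float(self.normalized.mean())


@dataclass
class DebrisCall:
    """Per-barcode partition into kept cells, debris, and below-threshold."""

    labels: pd.Series  # index barcode -> {"cell", "debris", "below_threshold"}
    threshold: int
    chosen_k: int
    cluster_classes: dict  # cluster id -> "cells" | "debris"

    def kept_barcodes(self) -> np.ndarray:
        return self.labels.index[self.labels == "cell"].to_numpy(dtype=object)


def select_umi_threshold(
    matrix: CountMatrix, expected_cells: int, step: int = DEFAULT_STEP
) -> int:
    """Largest grid threshold keeping more than ``expected_cells`` barcodes."""
    totals = matrix.total_umis()
    if expected_cells < 0:
        raise ValueError("expected_cells must be >= 0")
    if len(totals) < max(expected_cells, 1):
        raise ValueError(
            f"only {len(totals)} barcodes for expected_cells={expected_cells}"
        )
    best = None
    for t in range(0, int(totals.max()) + step, step):
        if (totals >= t).sum() > expected_cells:
            best = t
        else:
            break
    if best is None:
        raise ValueError(
            "no threshold retains more than the expected number of cells"
        )
    return best


def cluster_retained(
    matrix: CountMatrix,
    k_range=DEFAULT_K_RANGE,
    n_pcs: int = 20,
    paper_literal_silhouette: bool = False,
    seed: int = 0,
) -> tuple:
    """PCA + Ward clustering of retained barcodes; k chosen by silhouette.

    Returns ``(labels, chosen_k)`` with integer labels starting at 1.
    """
    k_range = list(k_range)
    if min(k_range) < 2:
        raise ValueError("cluster range must start at k >= 2")
    n = matrix.n_barcodes
    if n < max(k_range) + 1:
        raise ValueError(f"{n} barcodes is too few for k up to {max(k_range)}")

    logged = matrix.counts.copy().astype(float)
    logged.data = np.log1p(logged.data)  # log(count + 1), zeros stay zero
    dense = np.asarray(logged.todense())
    if np.allclose(dense, dense[0]):
        raise DegenerateInputError(
            "all barcodes identical after log transform; silhouette undefined"
        )
    d = min(n_pcs, min(dense.shape) - 1)
    coords = PCA(n_components=d, random_state=seed).fit_transform(dense)
    Z = linkage(coords, method="ward")

    best_k, best_score, best_labels = None, None, None
    sign = -1.0 if paper_literal_silhouette else 1.0
    for k in k_range:
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = sign * silhouette_score(coords, labels)
        if best_score is None or score > best_score:
            best_k, best_score, best_labels = k, score, labels
    if best_k is None:
        raise DegenerateInputError("no k produced at least two clusters")
    logger.info("debris clustering chose k=%d", best_k)
    return best_labels, best_k


def compute_dropoff_traces(
    matrix: CountMatrix, labels: np.ndarray, step: int = DEFAULT_STEP
) -> list:
    """Per-cluster barcode survival census on the global 0..max grid."""
    totals = matrix.total_umis()
    grid = np.arange(0, int(totals.max()) + step, step)
    traces = []
    for cid in np.unique(labels):
        member = totals[labels == cid]
        if member.size == 0:
            warnings.warn(f"cluster {cid} is empty; excluded from traces")
            continue
        # survival census is strictly-above: a barcode sitting exactly at a
        # threshold has dropped off at that threshold
        remaining = (member[None, :] > grid[:, None]).sum(axis=1)
        traces.append(DropoffTrace(int(cid), grid, remaining))
    return traces


def classify_trace_groups(traces) -> dict:
    """Two-way cluster the dropoff traces; the fast-dropoff group is debris.

    Returns ``{cluster_id: "cells" | "debris"}``. Identical traces yield no
    debris call (with a warning); an exact tie in mean area-under-trace is
    broken by labelling the group containing the smallest cluster id debris.
    """
    if len(traces) < 2:
        raise ValueError("need at least two cluster traces")
    mat = np.vstack([t.normalized for t in traces])
    if np.allclose(mat, mat[0]):
        warnings.warn("all dropoff traces identical; no debris called")
        return {t.cluster_id: "cells" for t in traces}
    Z = linkage(mat, method="ward")
    groups = fcluster(Z, t=2, criterion="maxclust")
    auc = np.array([t.auc for t in traces])
    mean_auc = {g: auc[groups == g].mean() for g in np.unique(groups)}
    g1, g2 = sorted(mean_auc)
    if np.isclose(mean_auc[g1], mean_auc[g2]):
        first = min(t.cluster_id for t in traces)
        debris_group = groups[[t.cluster_id for t in traces].index(first)]
        warnings.warn("trace groups tie on area-under-trace; "
                      "group of lowest cluster id called debris")
    else:
        debris_group = min(mean_auc, key=mean_auc.get)
    return {
        t.cluster_id: ("debris" if g == debris_group else "cells")
        for t, g in zip(traces, groups)
    }


def remove_debris(
    matrix: CountMatrix,
    expected_cells: int,
    step: int = DEFAULT_STEP,
    k_range=DEFAULT_K_RANGE,
    n_pcs: int = 20,
    paper_literal_silhouette: bool = False,
    seed: int = 0,
) -> DebrisCall:
    """Run the full dropoff-trace pipeline and partition all barcodes."""
    threshold = select_umi_threshold(matrix, expected_cells, step)
    totals = matrix.total_umis()
    above = totals >= threshold
    retained = matrix.subset_barcodes(np.flatnonzero(above))
    labels, k = cluster_retained(
        retained, k_range, n_pcs, paper_literal_silhouette, seed
    )
    traces = compute_dropoff_traces(retained, labels, step)
    classes = classify_trace_groups(traces)

    call = pd.Series("below_threshold", index=pd.Index(matrix.barcodes), dtype=object)
    is_debris = np.array([classes[c] == "debris" for c in labels])
    call.loc[retained.barcodes[~is_debris]] = "cell"
    call.loc[retained.barcodes[is_debris]] = "debris"
    logger.info(
        "debris removal: threshold=%d, k=%d, kept %d / %d barcodes",
        threshold, k, int((call == "cell").sum()), len(call),
    )
    return DebrisCall(call, threshold, k, classes)
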