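"""The mean-expression tensor every statistical test consumes.

For each gene g, subject s, cell type c and sample (session) k, the tensor
holds the arithmetic mean of the per-cell transcript fractions over the
cells with that (s, c, k); entries backed by fewer than ``min_cells`` cells
are masked. A pooled mode collapses all cell types into a single
"POPULATION" type, which is how whole-population diurnality is assessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellAnnotation, SampleDesign, session_key
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

POPULATION = "POPULATION"
DEFAULT_MIN_CELLS = 3


@dataclass
class MeanExpressionTensor:
    """mu[g, s, c, k] mean fractions with an (s, c, k) availability mask."""

    mu: np.ndarray  # genes x subjects x cell types x samples
    mask: np.ndarray  # bool, subjects x cell types x samples
    n_cells: np.ndarray  # int, subjects x cell types x samples
    genes: np.ndarray
    subjects: np.ndarray
    cell_types: np.ndarray
    sample_keys: np.ndarray
    min_cells: int

    @property
    def n_genes(self) -> int:
        return self.mu.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (gene, subject, cell_type, sample, mean, n_cells)."""
        s_idx, c_idx, k_idx = np.nonzero(self.mask)
        frames = []
        for s, c, k in zip(s_idx, c_idx, k_idx):
            frames.append(
                pd.DataFrame(
                    {
                        "gene": self.genes,
                        "subject": self.subjects[s],
                        "cell_type": self.cell_types[c],
                        "sample": self.sample_keys[k],
                        "mean": self.mu[:, s, c, k],
                        "n_cells": int(self.n_cells[s, c, k]),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def build_tensor(
    normalized: NormalizedMatrix,
    annotation: CellAnnotation,
    design: SampleDesign,
    min_cells: int = DEFAULT_MIN_CELLS,
    pooled: bool = False,
) -> MeanExpressionTensor:
    """Average fractions over cells per (subject, cell type, sample).

    Debris, unassigned, and untyped barcodes are excluded. With
    ``pooled=True`` all typed cells collapse into one POPULATION type.
    """
    kept = annotation.kept()
    kept = kept.dropna(subset=["subject", "day", "session", "cell_type"])
    kept = kept[kept.index.isin(normalized.barcodes)]
    if kept.empty:
        raise ValueError("no typed, subject-assigned, kept cells")

    cell_types = (
        np.array([POPULATION], dtype=object)
        if pooled
        else np.array(sorted(kept["cell_type"].unique()), dtype=object)
    )
    subjects = design.subjects
    keys = np.array(design.session_keys, dtype=object)

    bc_pos = {b: i for i, b in enumerate(normalized.barcodes)}
    sub_pos = {s: i for i, s in enumerate(subjects)}
    ct_pos = {c: i for i, c in enumerate(cell_types)}
    key_pos = {k: i for i, k in enumerate(keys)}

    G = normalized.n_genes
    S, C, K = len(subjects), len(cell_types), len(keys)
    mu = np.zeros((G, S, C, K))
    n_cells = np.zeros((S, C, K), dtype=int)

    cell_keys = [session_key(int(d), s) for d, s in zip(kept["day"], kept["session"])]
    group_cols = pd.DataFrame(
        {
            "s": [sub_pos[x] for x in kept["subject"]],
            "c": 0 if pooled else [ct_pos[x] for x in kept["cell_type"]],
            "k": [key_pos[x] for x in cell_keys],
            "row": [bc_pos[b] for b in kept.index],
        }
    )
    for (s, c, k), grp in group_cols.groupby(["s", "c", "k"]):
        rows = grp["row"].to_numpy()
        n_cells[s, c, k] = rows.size
        mu[:, s, c, k] = np.asarray(
            normalized.fractions[rows].mean(axis=0)
        ).ravel()

    mask = n_cells >= min_cells
    dead = [
        cell_types[c]
        for c in range(C)
        if not mask[:, c, :].any()
    ]
    for ct in dead:
        logger.warning("cell type %r has no unmasked entries; it will be "
                       "excluded from tests", ct)
    return MeanExpressionTensor(
        mu, mask, n_cells, np.asarray(normalized.gene_ids, dtype=object),
        subjects, cell_types, keys, min_cells,
    )
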