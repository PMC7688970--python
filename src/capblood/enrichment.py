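"""Weighted pathway and category enrichment of the top varying genes.

Genes ranked most diurnal and most subject-specific (top n of each axis,
by minimum p over cell types; union) are tested against the remaining
tested genes (the background) for over-representation in each pathway of a
GMT-defined database. To normalize for promiscuous pathway membership,
each gene carries weight 1 / (number of pathways containing it); the
enrichment statistic is a two-proportion z-test on the weighted counts,
with the weighted set totals acting as the effective sample sizes. The
same statistic applied to category-pooled weighted counts gives a
category-level enrichment, with categories taken from a sidecar table that
can regroup the database's top-level classes (e.g. splitting disease
pathways into immune-relevant subclasses).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import two_proportion_z

logger = logging.getLogger(__name__)

DEFAULT_CATEGORY = "Other"


@dataclass
class PathwayDB:
    """Pathway id -> (name, category, gene set) with category regrouping."""

    pathways: dict  # id -> {"name": str, "category": str, "genes": set}

    def __post_init__(self) -> None:
        for pid, rec in self.pathways.items():
            if not rec["genes"]:
                raise ValueError(f"pathway {pid} has an empty gene set")

    @property
    def categories(self) -> list:
        return sorted({rec["category"] for rec in self.pathways.values()})

    def membership_counts(self) -> pd.Series:
        """Number of pathways containing each gene."""
        counts: dict = {}
        for rec in self.pathways.values():
            for g in rec["genes"]:
                counts[g] = counts.get(g, 0) + 1
        return pd.Series(counts, dtype=int)


def load_gmt(path, category_sidecar=None) -> PathwayDB:
    """Read a GMT gene-set file plus an optional category sidecar TSV.

    GMT lines are ``id <tab> description <tab> gene...``; the sidecar has
    columns ``pathway_id`` and ``category``. Pathways without a category
    are assigned "Other" with a warning.
    """
    categories = {}
    if category_sidecar is not None:
        side = pd.read_csv(category_sidecar, sep="\t")
        categories = dict(zip(side["pathway_id"], side["category"]))
    pathways: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        pid, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if pid in pathways:
            raise ValueError(f"duplicate pathway id {pid!r}")
        if pid not in categories:
            warnings.warn(f"pathway {pid} has no category; assigned "
                          f"{DEFAULT_CATEGORY!r}")
        pathways[pid] = {
            "name": name,
            "category": categories.get(pid, DEFAULT_CATEGORY),
            "genes": set(genes),
        }
    return PathwayDB(pathways)


def gene_weights(db: PathwayDB, genes_in_data) -> pd.Series:
    """1 / pathway-membership count for each data gene in >= 1 pathway.

    Genes absent from the data, or in no pathway, are excluded from the
    test universe.
    """
    counts = db.membership_counts()
    present = counts.index.intersection(pd.Index(genes_in_data))
    return 1.0 / counts.loc[present].sort_index()


def select_top_genes(diurnal_results, subject_results, n: int = 250):
    """Union of the top-n most diurnal and top-n most subject-specific genes.

    Ranking is by each gene's minimum p over cell types. Ties at the n-th
    p-value are all included (with a warning). Returns
    ``(top_set, background)`` over the union of tested genes.
    """
    tops = []
    for res in (diurnal_results, subject_results):
        per_gene = res.per_gene()["p"].sort_values(kind="mergesort")
        if len(per_gene) < n:
            warnings.warn(
                f"only {len(per_gene)} tested genes for a top-{n} selection"
            )
            tops.append(set(per_gene.index))
            continue
        cutoff = per_gene.iloc[n - 1]
        chosen = per_gene[per_gene <= cutoff]
        if len(chosen) > n:
            warnings.warn(
                f"{len(chosen) - n} genes tied at the top-{n} p-value; all kept"
            )
        tops.append(set(chosen.index))
    top_set = tops[0] | tops[1]
    universe = set(diurnal_results.frame["gene"]) | set(
        subject_results.frame["gene"]
    )
    return top_set, universe - top_set


@dataclass
class EnrichmentResults:
    """Weighted two-proportion enrichment per pathway and per category."""

    pathway_frame: pd.DataFrame
    category_frame: pd.DataFrame
    n_top: int
    n_background: int

    def summary(self) -> str:
        lines = [
            "EnrichmentResults",
            "=" * 48,
            f"top-set genes (weighted universe): {self.n_top}",
            f"background genes                  : {self.n_background}",
            "",
            "categories:",
            self.category_frame.to_string(
                float_format=lambda v: f"{v:.3g}"
            ),
        ]
        return "\n".join(lines)


def enrich(db: PathwayDB, top_set, background, weights: pd.Series) -> EnrichmentResults:
    """Weighted two-proportion z-test per pathway and per category.

    ``weights`` maps genes to 1/membership weights (see
    :func:`gene_weights`); genes without a weight are ignored. Pathways
    with zero weighted presence in both sets are reported with z = 0 and a
    flag.
    """
    w = weights
    top = [g for g in top_set if g in w.index]
    bg = [g for g in background if g in w.index]
    w_top, w_bg = float(w.loc[top].sum()), float(w.loc[bg].sum())
    if w_bg <= 0:
        raise ValueError("background has no weighted genes")
    top_s, bg_s = set(top), set(bg)

    path_rows, cat_counts = [], {}
    for pid, rec in sorted(db.pathways.items()):
        genes = rec["genes"]
        c_top = float(w.loc[[g for g in genes if g in top_s]].sum())
        c_bg = float(w.loc[[g for g in genes if g in bg_s]].sum())
        empty = c_top == 0 and c_bg == 0
        if empty:
            z, p = 0.0, 1.0
        else:
            z, p = two_proportion_z(c_top, w_top, c_bg, w_bg)
        n_genes = len([g for g in genes if g in w.index])
        path_rows.append(
            {
                "pathway": pid,
                "name": rec["name"],
                "category": rec["category"],
                "n_genes": n_genes,
                "weighted_top": c_top,
                "weighted_background": c_bg,
                "top_proportion": c_top / w_top if w_top else np.nan,
                "background_proportion": c_bg / w_bg,
                "z": z,
                "p": p,
                "empty": empty,
            }
        )
        cat = rec["category"]
        a, b = cat_counts.get(cat, (0.0, 0.0))
        cat_counts[cat] = (a + c_top, b + c_bg)

    cat_rows = []
    for cat, (c_top, c_bg) in sorted(cat_counts.items()):
        z, p = (0.0, 1.0) if (c_top == 0 and c_bg == 0) else two_proportion_z(
            c_top, w_top, c_bg, w_bg
        )
        cat_rows.append(
            {"category": cat, "weighted_top": c_top, "weighted_background": c_bg,
             "z": z, "p": p}
        )
    return EnrichmentResults(
        pd.DataFrame(path_rows).set_index("pathway"),
        pd.DataFrame(cat_rows).set_index("category"),
        n_top=len(top),
        n_background=len(bg),
    )


class EnrichmentModel:
    """Model wrapper: ranks the top genes and fits the weighted enrichment."""

    def __init__(self, db: PathwayDB, diurnal_results, subject_results,
                 n_top: int = 250):
        self.db = db
        self.diurnal_results = diurnal_results
        self.subject_results = subject_results
        self.n_top = n_top

    def fit(self) -> EnrichmentResults:
        top, background = select_top_genes(
            self.diurnal_results, self.subject_results, self.n_top
        )
        universe = top | background
        weights = gene_weights(self.db, universe)
        return enrich(self.db, top, background, weights)
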