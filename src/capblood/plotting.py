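"""Static figure exports for the headline result layouts.

Two scatter layouts: diurnality magnitude (population Z vs best per-type
Z, marker size = expression abundance) and specificity magnitude (log2 F
between cell types vs between subjects).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def diurnal_scatter(celltype_results, population_results, abundance=None, ax=None):
    """Population-level vs best per-type signed Z per gene.

    ``abundance`` (optional Series, percent of cells expressing) scales the
    markers. Returns the matplotlib Axes.
    """
    ct = celltype_results.per_gene()
    pop = population_results.per_gene()
    genes = ct.index.intersection(pop.index)
    x = pop.loc[genes, "z"]
    y = ct.loc[genes, "z"]
    size = 20.0
    if abundance is not None:
        size = 2.0 + abundance.reindex(genes).fillna(0.0).to_numpy()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    sig = ct.loc[genes, "significant"] | pop.loc[genes, "significant"]
    ax.scatter(x[~sig], y[~sig], s=size if np.isscalar(size) else size[~sig.to_numpy()],
               c="lightgray", alpha=0.6, linewidths=0)
    ax.scatter(x[sig], y[sig], s=size if np.isscalar(size) else size[sig.to_numpy()],
               c="crimson", alpha=0.7, linewidths=0)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("population AM-vs-PM Z")
    ax.set_ylabel("best cell-type AM-vs-PM Z")
    return ax


def specificity_scatter(celltype_axis_results, subject_axis_results, ax=None):
    """log2 F between cell types (x) vs between subjects (y) per gene."""
    x = celltype_axis_results.per_gene()["log2F"]
    y = subject_axis_results.per_gene()["log2F"]
    genes = x.index.intersection(y.index)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    sig = subject_axis_results.per_gene().loc[genes, "significant"]
    ax.scatter(x[genes][~sig], y[genes][~sig], s=10, c="lightgray",
               alpha=0.6, linewidths=0)
    ax.scatter(x[genes][sig], y[genes][sig], s=10, c="royalblue",
               alpha=0.7, linewidths=0)
    ax.set_xlabel("cell-type specificity (log2 F)")
    ax.set_ylabel("subject specificity (log2 F)")
    return ax


def enrichment_bubble(results, ax=None):
    """Category-level z (large markers) with member pathways (small)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    cats = results.category_frame
    order = {c: i for i, c in enumerate(cats.index)}
    paths = results.pathway_frame
    ax.scatter(
        [order[c] for c in paths["category"]], paths["z"],
        s=4 + 2 * paths["n_genes"], c="steelblue", alpha=0.5, linewidths=0,
    )
    ax.scatter(range(len(cats)), cats["z"], s=250, c="navy", alpha=0.8,
               linewidths=0)
    ax.set_xticks(range(len(cats)))
    ax.set_xticklabels(cats.index, rotation=45, ha="right")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("enrichment z")
    return ax
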