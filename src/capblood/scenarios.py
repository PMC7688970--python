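"""Benchmark scenarios exercising the pipeline against planted ground truth.

Each scenario builds a :class:`~capblood.simulate.SimConfig` describing one
study condition — a global null, planted diurnal/subject effects, a pure
composition shift, planted debris, a typing mixture — runs the relevant
pipeline stages, and scores the outcome against the truth registry. The
scenarios are used both by the acceptance test suite and by the standalone
acceptance script; problem sizes are chosen so a full sweep runs on one CPU
in minutes (see the methods note for the sizes and their rationale).
"""

from __future__ import annotations

import numpy as np

from .celltype import cluster_cells, embed
from .debris import remove_debris
from .diffexpr import (
    CellTypeSpecificityModel,
    DiurnalModel,
    SubjectSpecificityModel,
    abundance_shift_test,
    classify_diurnal,
    CLASS_POPULATION_ONLY,
)
from .preprocess import filter_genes_pre, normalize
from .pseudobulk import build_tensor
from .simulate import (
    CellTypeSpec,
    SimConfig,
    design_from_config,
    generate_dataset,
    marker_panel,
    true_annotation,
)


def _stat_stages(config: SimConfig):
    """Generate data and build the cell-type and pooled tensors using the
    ground-truth annotation (isolates the statistics from typing)."""
    matrix, ann, truth = generate_dataset(config)
    ann = true_annotation(ann, truth)
    design = design_from_config(config)
    matrix = filter_genes_pre(matrix)
    norm = normalize(matrix)
    tensor = build_tensor(norm, ann, design)
    pooled = build_tensor(norm, ann, design, pooled=True)
    return truth, design, tensor, pooled


# ---------------------------------------------------------------------------
# Null type-I error


def null_config(seed: int, n_genes: int = 2000, cells_per_sample: int = 60) -> SimConfig:
    """No planted effects anywhere: identical cell types, no diurnal,
    subject, shift, or debris structure. Session-level biological noise
    stays on (it is noise, not signal)."""
    types = [
        CellTypeSpec("T cells", 0.5),
        CellTypeSpec("Monocytes", 0.3),
        CellTypeSpec("B cells", 0.2),
    ]
    return SimConfig(
        n_genes=n_genes,
        cell_types=types,
        cells_per_sample=cells_per_sample,
        celltype_profile_sd=0.0,
        n_diurnal_global=0,
        n_diurnal_celltype=0,
        n_subject_specific=0,
        abundance_shift=None,
        debris=None,
        seed=seed,
    )


def run_null_typei(seed: int, n_reps: int = 200, n_genes: int = 2000) -> dict:
    """Fraction of genes flagged (q < 0.05) by each procedure under the null."""
    flagged = {"diurnal": 0, "subject": 0, "celltype": 0}
    total_genes = 0
    for rep in range(n_reps):
        config = null_config(seed + rep, n_genes=n_genes)
        _, design, tensor, _ = _stat_stages(config)
        total_genes += tensor.n_genes
        flagged["diurnal"] += DiurnalModel(tensor, design).fit().n_significant()
        flagged["subject"] += SubjectSpecificityModel(tensor, design).fit().n_significant()
        flagged["celltype"] += CellTypeSpecificityModel(tensor, design).fit().n_significant()
    out = {k: v / total_genes for k, v in flagged.items()}
    out["n_genes_tested"] = total_genes
    out["binomial_3se"] = 3.0 * np.sqrt(0.05 * 0.95 / total_genes)
    return out


# ---------------------------------------------------------------------------
# Planted-effect recovery


def recovery_config(seed: int, n_genes: int = 1000, cells_per_sample: int = 400) -> SimConfig:
    """Planted diurnal (20 global + 20 NK-restricted) and 20 subject genes at
    log2FC 2; no composition shift or debris, so detection is attributable
    to the planted expression effects alone."""
    return SimConfig(
        n_genes=n_genes,
        cells_per_sample=cells_per_sample,
        abundance_shift=None,
        debris=None,
        seed=seed,
    )


def run_recovery(seed: int) -> dict:
    """Recovery of planted effects at FDR 0.05 plus the dilution phenomenon:
    genes diurnal only in a minor cell type are found per-type, not pooled."""
    config = recovery_config(seed)
    truth, design, tensor, pooled = _stat_stages(config)
    diurnal = DiurnalModel(tensor, design).fit()
    pop = DiurnalModel(pooled, design).fit()
    subject = SubjectSpecificityModel(tensor, design).fit()

    planted = set(truth.diurnal_genes)
    restricted = {
        g for g, info in truth.diurnal_genes.items() if info["cell_types"] != "ALL"
    }
    glob = planted - restricted
    sig_ct = set(diurnal.significant_genes())
    sig_pop = set(pop.significant_genes())
    sig_subj = set(subject.significant_genes())
    planted_subject = set(truth.subject_genes)
    null_genes = (
        set(tensor.genes) - planted - planted_subject
    )
    return {
        "diurnal_recovery": len(sig_ct & planted) / len(planted),
        "global_recovery": len(sig_ct & glob) / len(glob),
        "restricted_recovery_celltype": len(sig_ct & restricted) / len(restricted),
        "restricted_flagged_pooled": len(sig_pop & restricted) / len(restricted),
        "subject_recovery": len(sig_subj & planted_subject) / len(planted_subject),
        "null_flagged_diurnal": len(sig_ct & null_genes) / len(null_genes),
        "n_planted_diurnal": len(planted),
        "n_planted_subject": len(planted_subject),
    }


# ---------------------------------------------------------------------------
# Abundance-shift confound


def confound_config(seed: int, n_genes: int = 400, cells_per_sample: int = 600) -> SimConfig:
    """A pure composition confound: B-cell abundance rises AM -> PM while no
    gene changes expression within any cell type. Fifteen strongly
    B-dominant genes are planted as B markers (64x, emulating
    essentially B-exclusive genes) so the population-level test has
    something to be fooled by."""
    types = [
        CellTypeSpec("CD4 T cells", 0.32, ("CD4", "IL7R"), 4.0),
        CellTypeSpec("CD8 T cells", 0.20, ("CD8A", "CD8B"), 4.0),
        CellTypeSpec("NK cells", 0.08, ("NKG7", "GNLY"), 4.0),
        CellTypeSpec("CD14+ Monocytes", 0.20, ("CD14", "LYZ"), 4.0),
        CellTypeSpec("CD16+ Monocytes", 0.06, ("FCGR3A", "MS4A7"), 4.0),
        CellTypeSpec("B cells", 0.14, confound_b_markers(), 6.0),
    ]
    return SimConfig(
        n_genes=n_genes,
        cell_types=types,
        cells_per_sample=cells_per_sample,
        n_diurnal_global=0,
        n_diurnal_celltype=0,
        n_subject_specific=0,
        abundance_shift=("B cells", 0.10, 0.16),
        debris=None,
        seed=seed,
    )


def run_confound_once(seed: int) -> dict:
    """One composition-confound replicate.

    Success mirrors the abundance-artifact logic gene-for-gene: at least
    one B-dominant gene must be flagged by the population test and end up
    classified as a population-only abundance suspect, no per-type test
    may flag any B-dominant gene, and the one-sided abundance test must
    detect the afternoon B-cell increase.
    """
    config = confound_config(seed)
    matrix, ann, truth = generate_dataset(config)
    ann = true_annotation(ann, truth)
    design = design_from_config(config)
    matrix = filter_genes_pre(matrix)
    norm = normalize(matrix)
    tensor = build_tensor(norm, ann, design)
    pooled = build_tensor(norm, ann, design, pooled=True)
    diurnal = DiurnalModel(tensor, design).fit()
    pop = DiurnalModel(pooled, design).fit()

    b_genes = set(tensor.genes) & set(confound_b_markers())
    sig_pop = set(pop.significant_genes()) & b_genes
    sig_ct = set(diurnal.significant_genes()) & b_genes
    _, p_shift = abundance_shift_test(ann, design, "B cells")
    classes = classify_diurnal(diurnal, pop)
    pop_only = set(
        classes.index[classes["classification"] == CLASS_POPULATION_ONLY]
    )
    return {
        "pooled_flag_frac": len(sig_pop) / len(b_genes),
        "celltype_flag_frac": len(sig_ct) / len(b_genes),
        "abundance_p": p_shift,
        "classified_population_only": len(sig_pop & pop_only) == len(sig_pop),
        "success": (
            len(sig_pop & pop_only) >= 1
            and len(sig_ct) == 0
            and p_shift < 0.05
        ),
    }


def confound_b_markers() -> tuple:
    return (
        "MS4A1", "CD79A", "CD79B", "IGHM", "BANK1",
        "TNFRSF13B", "BLK", "FCRL1", "CD19", "TCL1A",
        "IGHD", "FCER2", "PAX5", "VPREB3", "BLNK",
    )


def run_confound(seed: int, n_reps: int = 50) -> dict:
    reps = [run_confound_once(seed + i) for i in range(n_reps)]
    return {
        "success_rate": float(np.mean([r["success"] for r in reps])),
        "median_abundance_p": float(np.median([r["abundance_p"] for r in reps])),
        "mean_pooled_flag_frac": float(np.mean([r["pooled_flag_frac"] for r in reps])),
        "mean_celltype_flag_frac": float(
            np.mean([r["celltype_flag_frac"] for r in reps])
        ),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Debris removal


def debris_config(seed: int, n_genes: int = 300, cells_per_sample: int = 100) -> SimConfig:
    return SimConfig(
        n_genes=n_genes,
        cells_per_sample=cells_per_sample,
        n_diurnal_global=0,
        n_diurnal_celltype=0,
        n_subject_specific=0,
        abundance_shift=None,
        seed=seed,
    )


def run_debris_once(seed: int) -> dict:
    """One debris replicate: planted ambient barcodes vs the dropoff pipeline.

    The expected-cells parameter emulates the protocol's deliberate
    overshoot (the loading target exceeds the recovered cell count), so the
    UMI threshold retains debris for the trace stage to classify.
    """
    config = debris_config(seed)
    matrix, ann, truth = generate_dataset(config)
    n_cells_true = matrix.n_barcodes - len(truth.debris_barcodes)
    expected = int(round(1.15 * n_cells_true))
    call = remove_debris(matrix, expected_cells=expected, seed=seed)
    removed = call.labels != "cell"
    is_debris = call.labels.index.isin(truth.debris_barcodes)
    return {
        "debris_removed_frac": float(removed[is_debris].mean()),
        "cells_removed_frac": float(removed[~is_debris].mean()),
        "threshold": call.threshold,
        "k": call.chosen_k,
    }


def run_debris(seed: int, n_seeds: int = 10) -> dict:
    reps = [run_debris_once(seed + i) for i in range(n_seeds)]
    return {
        "min_debris_removed_frac": float(
            min(r["debris_removed_frac"] for r in reps)
        ),
        "max_cells_removed_frac": float(
            max(r["cells_removed_frac"] for r in reps)
        ),
        "mean_debris_removed_frac": float(
            np.mean([r["debris_removed_frac"] for r in reps])
        ),
        "mean_cells_removed_frac": float(
            np.mean([r["cells_removed_frac"] for r in reps])
        ),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Cell typing


def typing_config(seed: int, n_genes: int = 500, cells_per_sample: int = 100) -> SimConfig:
    return SimConfig(
        n_genes=n_genes,
        cells_per_sample=cells_per_sample,
        n_diurnal_global=0,
        n_diurnal_celltype=0,
        n_subject_specific=0,
        abundance_shift=None,
        debris=None,
        seed=seed,
    )


def run_typing(seed: int) -> dict:
    """Six-type mixture: embedding + 13-15 cluster scan + marker annotation
    scored for per-cell accuracy against the planted types."""
    config = typing_config(seed)
    matrix, ann, truth = generate_dataset(config)
    design = design_from_config(config)
    matrix = filter_genes_pre(matrix)
    norm = normalize(matrix)
    emb = embed(norm, d=10, seed=seed)
    typed = cluster_cells(emb, norm, ann, marker_panel(config))
    called = typed.df.loc[list(norm.barcodes), "cell_type"]
    true_labels = [truth.celltype_of_barcode[b] for b in norm.barcodes]
    accuracy = float(np.mean([c == t for c, t in zip(called, true_labels)]))
    return {
        "accuracy": accuracy,
        "n_types_found": int(called.nunique()),
        "n_types_true": len(config.cell_types),
        "n_cells": len(called),
    }
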