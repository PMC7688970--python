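"""End-to-end orchestration: one config, staged outputs, a run summary.

Stage order follows the analysis protocol: simulate/ingest -> debris
removal -> pre-typing gene filter -> embedding + cell typing -> post-typing
gene filter -> normalization -> pseudobulk tensor -> diurnal (per-type and
population) + subject and cell-type specificity tests -> classification ->
optional pathway enrichment. Every stage persists a TSV intermediate and a
structured log line; a run is idempotent given its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .celltype import DEFAULT_PANEL, cluster_cells, embed, external_embedding
from .debris import remove_debris
from .diffexpr import (
    CellTypeSpecificityModel,
    DiurnalModel,
    SubjectSpecificityModel,
    abundance_shift_test,
    celltype_sample_fractions,
    classify_diurnal,
)
from .enrichment import EnrichmentModel, load_gmt
from .io import read_metadata, read_tenx_dir, write_tenx_dir
from .preprocess import filter_genes_post, filter_genes_pre, normalize
from .pseudobulk import build_tensor
from .simulate import (
    DebrisSpec,
    SimConfig,
    generate_dataset,
    marker_panel,
)

logger = logging.getLogger(__name__)

STAGES = (
    "ingest",
    "debris",
    "filter",
    "celltype",
    "pseudobulk",
    "diurnal",
    "subject",
    "pathways",
)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; mirrors the YAML layout."""

    input_dir: str | None = None
    simulate: dict | None = None  # SimConfig fields
    expected_cells: int | None = None
    debris_enabled: bool = True
    paper_literal_silhouette: bool = False
    min_max_count: int = 3
    min_type_fraction: float = 0.10
    embedding_dim: int = 10
    external_embedding: str | None = None
    typing_k_min: int = 13
    typing_k_max: int = 15
    markers: dict | None = None
    min_cells: int = 3
    fdr: float = 0.05
    n_top: int = 250
    gmt: str | None = None
    category_sidecar: str | None = None
    abundance_shift_celltype: str | None = "B cells"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("specify exactly one of input_dir / simulate")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        raw = dict(self.simulate or {})
        raw.setdefault("seed", self.seed)
        if "debris" in raw and isinstance(raw["debris"], dict):
            raw["debris"] = DebrisSpec(**raw["debris"])
        if "missing_samples" in raw:
            raw["missing_samples"] = tuple(
                tuple(m) for m in raw["missing_samples"]
            )
        return SimConfig(**raw)


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)
    logger.info("wrote %s (%d rows)", path.name, len(df))


def run_all(config: RunConfig, out_dir, upto: str = "pathways") -> dict:
    """Execute the pipeline up to (and including) stage ``upto``.

    Returns the run summary (also persisted as ``summary.json``).
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": _version, "seed": config.seed, "stages": {}}
    stop = STAGES.index(upto)

    # --- ingest / simulate --------------------------------------------
    if config.simulate is not None:
        sim = config.sim_config()
        matrix, annotation, truth = generate_dataset(sim)
        sim_dir = out / "simulated"
        write_tenx_dir(matrix, annotation, sim_dir)
        truth.to_json(sim_dir / "truth.json")
        panel = config.markers or marker_panel(sim)
        expected = config.expected_cells
        if expected is None:
            # deliberate overshoot of the design's cell target, mirroring the
            # protocol's expected-count convention: the UMI threshold must
            # retain some debris for the trace stage to classify, otherwise
            # the two-way trace split has only cell clusters to cut
            target = sim.cells_per_sample * sim.n_subjects * sim.n_days * 2
            expected = int(round(1.15 * target))
        matrix = read_tenx_dir(sim_dir)  # round-trip: one ingest path
        annotation, design = read_metadata(sim_dir / "metadata.tsv", matrix)
    else:
        matrix = read_tenx_dir(config.input_dir)
        annotation, design = read_metadata(
            Path(config.input_dir) / "metadata.tsv", matrix
        )
        panel = config.markers or DEFAULT_PANEL
        expected = config.expected_cells
        if expected is None:
            raise ValueError("expected_cells is required for real input")
    summary["stages"]["ingest"] = {
        "barcodes": matrix.n_barcodes,
        "genes": matrix.n_genes,
        "subjects": list(design.subjects),
        "samples": design.session_keys,
    }
    if stop == STAGES.index("ingest"):
        return _finish(summary, out)

    # --- debris removal -----------------------------------------------
    if config.debris_enabled:
        call = remove_debris(
            matrix,
            expected_cells=expected,
            paper_literal_silhouette=config.paper_literal_silhouette,
            seed=config.seed,
        )
        _write(
            call.labels.rename("call").to_frame(), out / "debris_calls.tsv",
            index_label="barcode",
        )
        keep = call.kept_barcodes()
        debris_flags = pd.Series(
            call.labels != "cell", index=call.labels.index
        )
        annotation = annotation.with_debris(debris_flags)
        keep_idx = np.flatnonzero(pd.Index(matrix.barcodes).isin(keep))
        matrix = matrix.subset_barcodes(keep_idx)
        summary["stages"]["debris"] = {
            "threshold": call.threshold,
            "k": call.chosen_k,
            "kept_barcodes": matrix.n_barcodes,
        }
    else:
        summary["stages"]["debris"] = {"skipped": True,
                                       "kept_barcodes": matrix.n_barcodes}
    if stop == STAGES.index("debris"):
        return _finish(summary, out)

    # --- pre-typing gene filter ---------------------------------------
    matrix = filter_genes_pre(matrix, config.min_max_count)
    summary["stages"]["filter"] = {"genes_after_prefilter": matrix.n_genes}
    if stop == STAGES.index("filter"):
        return _finish(summary, out)

    # --- embedding + cell typing --------------------------------------
    normalized = normalize(matrix)
    if config.external_embedding:
        emb = external_embedding(config.external_embedding, normalized)
    else:
        emb = embed(normalized, d=config.embedding_dim, seed=config.seed)
    annotation = cluster_cells(
        emb, normalized, annotation, panel,
        k_min=config.typing_k_min, k_max=config.typing_k_max,
    )
    typed = annotation.df.loc[list(matrix.barcodes), "cell_type"]
    _write(
        typed.rename("cell_type").to_frame(), out / "cell_types.tsv",
        index_label="barcode",
    )
    counts_per_type = typed.value_counts().sort_index()
    summary["stages"]["celltype"] = {
        "cells_per_type": counts_per_type.to_dict()
    }

    # post-typing gene filter, then final normalization
    matrix = filter_genes_post(matrix, annotation, config.min_type_fraction)
    normalized = normalize(matrix)
    summary["stages"]["filter"]["genes_after_postfilter"] = matrix.n_genes
    if stop == STAGES.index("celltype"):
        return _finish(summary, out)

    # --- pseudobulk ----------------------------------------------------
    tensor = build_tensor(normalized, annotation, design, config.min_cells)
    tensor_pooled = build_tensor(
        normalized, annotation, design, config.min_cells, pooled=True
    )
    _write(tensor.to_frame(), out / "pseudobulk.tsv", index=False)
    summary["stages"]["pseudobulk"] = {
        "cell_types": list(tensor.cell_types),
        "unmasked_entries": int(tensor.mask.sum()),
    }
    if stop == STAGES.index("pseudobulk"):
        return _finish(summary, out)

    # --- diurnal -------------------------------------------------------
    diurnal = DiurnalModel(tensor, design).fit(config.fdr)
    pop = DiurnalModel(tensor_pooled, design).fit(config.fdr)
    classes = classify_diurnal(diurnal, pop)
    _write(diurnal.frame, out / "diurnal_celltype.tsv", index=False)
    _write(pop.frame, out / "diurnal_population.tsv", index=False)
    _write(classes, out / "diurnal_classification.tsv")
    fractions = celltype_sample_fractions(annotation, design)
    _write(fractions, out / "celltype_fractions.tsv")
    summary["stages"]["diurnal"] = {
        "significant_celltype": diurnal.n_significant(),
        "significant_population": pop.n_significant(),
        "classes": classes["classification"].value_counts().to_dict(),
    }
    shift_ct = config.abundance_shift_celltype
    if shift_ct and shift_ct in fractions.columns:
        t_shift, p_shift = abundance_shift_test(annotation, design, shift_ct)
        summary["stages"]["diurnal"]["abundance_shift"] = {
            "cell_type": shift_ct, "t": t_shift, "p": p_shift,
        }
    if stop == STAGES.index("diurnal"):
        return _finish(summary, out)

    # --- specificity ---------------------------------------------------
    subject = SubjectSpecificityModel(tensor, design).fit(config.fdr)
    ctspec = CellTypeSpecificityModel(tensor, design).fit(config.fdr)
    _write(subject.frame, out / "subject_specificity.tsv", index=False)
    _write(ctspec.frame, out / "celltype_specificity.tsv", index=False)
    summary["stages"]["subject"] = {
        "significant_subject": subject.n_significant(),
        "significant_celltype_axis": ctspec.n_significant(),
    }
    if stop == STAGES.index("subject"):
        return _finish(summary, out)

    # --- pathways ------------------------------------------------------
    if config.gmt:
        db = load_gmt(config.gmt, config.category_sidecar)
        res = EnrichmentModel(db, diurnal, subject, config.n_top).fit()
        _write(res.pathway_frame, out / "enrichment_pathways.tsv")
        _write(res.category_frame, out / "enrichment_categories.tsv")
        summary["stages"]["pathways"] = {
            "n_pathways": len(res.pathway_frame),
            "n_top_genes": res.n_top,
        }
    else:
        summary["stages"]["pathways"] = {"skipped": True}
    return _finish(summary, out)


def _finish(summary: dict, out: Path) -> dict:
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=str)
    )
    return summary
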