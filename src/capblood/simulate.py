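"""Synthetic multi-subject, multi-session single-cell count data.

Emulates a pooled-capillary-blood study design: a small cohort sampled every
morning (AM) and afternoon (PM) over consecutive days, with ~6 major PBMC
cell types, planted diurnal genes (global and cell-type-restricted), planted
subject-specific genes, an optional AM->PM abundance shift in one cell type,
and low-UMI debris barcodes drawn from the ambient profile.

Counts follow a gamma-Poisson (negative binomial) model per gene per cell:
the expected count is ``library_size x p[g]`` where ``p`` is the cell's
gene-proportion vector. Proportions start from a shared lognormal gene
weight vector and receive multiplicative effects on the rate scale —
cell-type profile noise, marker up-regulation, subject effects, diurnal
AM/PM effects, and per-(gene, subject, session) biological session noise —
before renormalization to sum to one, which keeps downstream fraction-based
normalization meaningful.

All randomness flows from the single ``seed`` in :class:`SimConfig`;
identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    CellAnnotation,
    CountMatrix,
    SampleDesign,
    empty_annotation,
)


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class CellTypeSpec:
    """One simulated cell type: mixture fraction and its marker genes."""

    name: str
    baseline_fraction: float
    marker_genes: tuple = ()
    marker_log2fc: float = 4.0


@dataclass
class DebrisSpec:
    """Debris droplets: ambient-profile barcodes at a fraction of cell UMIs."""

    n_debris_barcodes: int = 600
    umi_scale_factor: float = 0.1
    ambient_mixing: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.umi_scale_factor < 1:
            raise ConfigError("umi_scale_factor must be in (0, 1)")
        if not 0 <= self.ambient_mixing <= 1:
            raise ConfigError("ambient_mixing must be in [0, 1]")


def default_cell_types() -> list:
    """Six major PBMC types with canonical, mutually disjoint marker genes."""
    return [
        CellTypeSpec("CD4 T cells", 0.30, ("CD4", "IL7R", "TRAC", "CCR7", "LTB")),
        CellTypeSpec("CD8 T cells", 0.20, ("CD8A", "CD8B", "GZMK", "CCL5", "KLRG1")),
        CellTypeSpec("NK cells", 0.08, ("NKG7", "GNLY", "KLRD1", "GZMB", "PRF1")),
        CellTypeSpec("CD14+ Monocytes", 0.20, ("CD14", "LYZ", "S100A8", "S100A9", "VCAN")),
        CellTypeSpec("CD16+ Monocytes", 0.06, ("FCGR3A", "MS4A7", "LST1", "CDKN1C", "CSF1R")),
        CellTypeSpec("B cells", 0.16, ("MS4A1", "CD79A", "CD79B", "IGHM", "BANK1")),
    ]


@dataclass
class SimConfig:
    """Study-design and noise parameters for the generator.

    Defaults mirror the emulated study: 4 subjects sampled AM and PM over
    3 consecutive days (24 subject-sessions), 6 PBMC cell types, and a
    B-cell abundance increase in the afternoon.
    """

    n_subjects: int = 4
    n_days: int = 3
    n_genes: int = 1000
    cell_types: list = field(default_factory=default_cell_types)
    cells_per_sample: int = 1000
    library_size_log_mean: float = math.log(2500.0)
    library_size_log_sd: float = 0.35
    nb_dispersion: float = 0.3
    celltype_profile_sd: float = 0.3
    session_noise_sd: float = 0.2
    composition_concentration: float = 500.0
    n_diurnal_global: int = 20
    n_diurnal_celltype: int = 20
    diurnal_celltype: str = "NK cells"
    n_subject_specific: int = 20
    diurnal_log2fc: float = 2.0
    subject_log2fc: float = 2.0
    abundance_shift: tuple | None = ("B cells", 0.10, 0.16)
    debris: DebrisSpec | None = field(default_factory=DebrisSpec)
    missing_samples: tuple = ()  # (subject, day, "AM"|"PM")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_days, self.n_genes, self.cells_per_sample) < 1:
            raise ConfigError("counts must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        fr = [ct.baseline_fraction for ct in self.cell_types]
        if abs(sum(fr) - 1.0) > 1e-8:
            raise ConfigError(f"baseline fractions sum to {sum(fr)}, not 1")
        markers = [g for ct in self.cell_types for g in ct.marker_genes]
        if len(markers) != len(set(markers)):
            raise ConfigError("marker lists overlap across cell types")
        if self.abundance_shift is not None:
            name, am, pm = self.abundance_shift
            if name not in {ct.name for ct in self.cell_types}:
                raise ConfigError(f"abundance_shift type {name!r} unknown")
            if not (0 < am < 1 and 0 < pm < 1):
                raise ConfigError("abundance-shift fractions must be in (0,1)")
        n_planted = (
            self.n_diurnal_global + self.n_diurnal_celltype + self.n_subject_specific
        )
        if n_planted + len(markers) > self.n_genes:
            raise ConfigError("not enough genes for planted effects and markers")

    @property
    def subjects(self) -> list:
        return [f"S{i + 1}" for i in range(self.n_subjects)]

    @property
    def sessions(self) -> list:
        return [(d, s) for d in range(1, self.n_days + 1) for s in ("AM", "PM")]


@dataclass
class SyntheticTruth:
    """Planted-effect registry used as the downstream acceptance oracle."""

    diurnal_genes: dict  # gene -> {"cell_types": [..] or "ALL", "direction": "AM"|"PM"}
    subject_genes: dict  # gene -> {"subject", "cell_type", "direction": "up"|"down"}
    shifted_celltype: str | None
    debris_barcodes: set
    celltype_of_barcode: dict

    def to_json(self, path) -> None:
        payload = {
            "diurnal_genes": self.diurnal_genes,
            "subject_genes": self.subject_genes,
            "shifted_celltype": self.shifted_celltype,
            "debris_barcodes": sorted(self.debris_barcodes),
            "celltype_of_barcode": self.celltype_of_barcode,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            d["diurnal_genes"],
            d["subject_genes"],
            d["shifted_celltype"],
            set(d["debris_barcodes"]),
            d["celltype_of_barcode"],
        )


def _gene_names(config: SimConfig) -> tuple:
    """Gene id/symbol lists; marker genes carry their canonical symbols."""
    ids = [f"GENE{i:05d}" for i in range(config.n_genes)]
    names = list(ids)
    markers = [g for ct in config.cell_types for g in ct.marker_genes]
    for i, sym in enumerate(markers):
        names[i] = sym
        ids[i] = sym  # markers are addressed by symbol throughout
    return np.array(ids, dtype=object), np.array(names, dtype=object), markers


def _composition(config: SimConfig, session: str) -> np.ndarray:
    """Target cell-type fractions for one session, shift applied."""
    frac = np.array([ct.baseline_fraction for ct in config.cell_types], float)
    if config.abundance_shift is not None:
        name, am, pm = config.abundance_shift
        idx = [ct.name for ct in config.cell_types].index(name)
        target = am if session == "AM" else pm
        others = 1.0 - frac[idx]
        frac = frac * (1.0 - target) / others
        frac[idx] = target
    return frac


def generate_dataset(config: SimConfig):
    """Simulate one study: returns ``(CountMatrix, CellAnnotation, SyntheticTruth)``.

    The annotation carries subject/day/session per barcode (what real
    demultiplexing provides); true cell types and debris identities live in
    the truth registry only.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids, gene_names, markers = _gene_names(config)
    G = config.n_genes
    types = config.cell_types
    T = len(types)
    type_names = [ct.name for ct in types]

    # --- static gene architecture -------------------------------------
    base = rng.lognormal(mean=0.0, sigma=1.5, size=G)
    type_mult = np.ones((T, G))
    if config.celltype_profile_sd > 0:
        type_mult *= rng.lognormal(0.0, config.celltype_profile_sd, size=(T, G))
    id_to_col = {g: i for i, g in enumerate(gene_ids)}
    for t, ct in enumerate(types):
        for g in ct.marker_genes:
            type_mult[t, id_to_col[g]] *= 2.0 ** ct.marker_log2fc

    # --- planted effects ----------------------------------------------
    n_marker = len(markers)
    cursor = n_marker
    diurnal: dict = {}
    subject_genes: dict = {}
    # global diurnal genes, alternating direction
    for i in range(config.n_diurnal_global):
        g = gene_ids[cursor]
        cursor += 1
        diurnal[g] = {
            "cell_types": "ALL",
            "direction": "AM" if i % 2 == 0 else "PM",
        }
    for i in range(config.n_diurnal_celltype):
        g = gene_ids[cursor]
        cursor += 1
        diurnal[g] = {
            "cell_types": [config.diurnal_celltype],
            "direction": "AM" if i % 2 == 0 else "PM",
        }
    for i in range(config.n_subject_specific):
        g = gene_ids[cursor]
        cursor += 1
        subject_genes[g] = {
            "subject": config.subjects[i % config.n_subjects],
            "cell_type": type_names[i % T],
            "direction": "up" if i % 2 == 0 else "down",
        }

    # diurnal multiplier per (session-class, type, gene): half effect each way
    half = 2.0 ** (config.diurnal_log2fc / 2.0)
    diurnal_mult = {"AM": np.ones((T, G)), "PM": np.ones((T, G))}
    for g, info in diurnal.items():
        col = id_to_col[g]
        t_idx = (
            range(T)
            if info["cell_types"] == "ALL"
            else [type_names.index(n) for n in info["cell_types"]]
        )
        hi, lo = ("AM", "PM") if info["direction"] == "AM" else ("PM", "AM")
        for t in t_idx:
            diurnal_mult[hi][t, col] *= half
            diurnal_mult[lo][t, col] /= half

    subject_mult = {s: np.ones((T, G)) for s in config.subjects}
    for g, info in subject_genes.items():
        col = id_to_col[g]
        t = type_names.index(info["cell_type"])
        fc = 2.0 ** config.subject_log2fc
        subject_mult[info["subject"]][t, col] *= fc if info["direction"] == "up" else 1 / fc

    # --- per-sample generation ----------------------------------------
    missing = {(s, d, ses) for s, d, ses in config.missing_samples}
    blocks, barcodes, ann_rows = [], [], []
    celltype_of_barcode: dict = {}
    ambient_accum = np.zeros(G)
    bc_counter = 0
    shape = 1.0 / config.nb_dispersion

    for subject in config.subjects:
        for day, session in config.sessions:
            if (subject, day, session) in missing:
                continue
            frac = _composition(config, session)
            if config.composition_concentration and config.composition_concentration > 0:
                frac = rng.dirichlet(frac * config.composition_concentration)
            n_per_type = rng.multinomial(config.cells_per_sample, frac)
            type_idx = np.repeat(np.arange(T), n_per_type)

            expr = base[None, :] * type_mult * subject_mult[subject] * diurnal_mult[session]
            if config.session_noise_sd > 0:
                expr = expr * rng.lognormal(0.0, config.session_noise_sd, size=G)[None, :]
            expr = expr / expr.sum(axis=1, keepdims=True)

            n_cells = type_idx.size
            lib = rng.lognormal(
                config.library_size_log_mean, config.library_size_log_sd, size=n_cells
            )
            rate = lib[:, None] * expr[type_idx]
            rate = rate * rng.gamma(shape, config.nb_dispersion, size=rate.shape)
            counts = rng.poisson(rate)
            blocks.append(sp.csr_matrix(counts))
            ambient_accum += counts.sum(axis=0)

            for t in type_idx:
                bc = f"BC{bc_counter:07d}"
                bc_counter += 1
                barcodes.append(bc)
                celltype_of_barcode[bc] = type_names[t]
                ann_rows.append((bc, subject, day, session))

    # --- debris barcodes ----------------------------------------------
    debris_barcodes: set = set()
    if config.debris is not None and config.debris.n_debris_barcodes > 0:
        spec = config.debris
        ambient = ambient_accum / ambient_accum.sum()
        profile = (1 - spec.ambient_mixing) * ambient + spec.ambient_mixing / G
        profile = profile / profile.sum()
        n_deb = spec.n_debris_barcodes
        lib = rng.lognormal(
            config.library_size_log_mean + math.log(spec.umi_scale_factor),
            config.library_size_log_sd,
            size=n_deb,
        )
        rate = lib[:, None] * profile[None, :]
        rate = rate * rng.gamma(shape, config.nb_dispersion, size=rate.shape)
        counts = rng.poisson(rate)
        blocks.append(sp.csr_matrix(counts))
        present = [
            (s, d, ses)
            for s in config.subjects
            for d, ses in config.sessions
            if (s, d, ses) not in missing
        ]
        for i in range(n_deb):
            bc = f"BC{bc_counter:07d}"
            bc_counter += 1
            barcodes.append(bc)
            debris_barcodes.add(bc)
            _, day, session = present[i % len(present)]
            ann_rows.append((bc, None, day, session))  # ambient: no subject

    counts = sp.csr_matrix(sp.vstack(blocks)).astype(np.int64)
    matrix = CountMatrix(counts, np.array(barcodes, dtype=object), gene_ids, gene_names)

    ann = empty_annotation(matrix.barcodes)
    rows = pd.DataFrame(
        ann_rows, columns=["barcode", "subject", "day", "session"]
    ).set_index("barcode")
    ann.df.loc[rows.index, "subject"] = rows["subject"].astype(object)
    ann.df.loc[rows.index, "day"] = rows["day"].astype("Int64")
    ann.df.loc[rows.index, "session"] = rows["session"].astype(object)

    truth = SyntheticTruth(
        diurnal_genes=diurnal,
        subject_genes=subject_genes,
        shifted_celltype=(
            config.abundance_shift[0] if config.abundance_shift is not None else None
        ),
        debris_barcodes=debris_barcodes,
        celltype_of_barcode=celltype_of_barcode,
    )
    return matrix, ann, truth


def design_from_config(config: SimConfig) -> SampleDesign:
    """The sample design implied by a config (before any data are drawn)."""
    missing = {(s, d, ses) for s, d, ses in config.missing_samples}
    subjects = np.array(config.subjects, dtype=object)
    sessions = config.sessions
    present = np.array(
        [
            [(s, d, ses) not in missing for d, ses in sessions]
            for s in subjects
        ]
    )
    return SampleDesign(subjects, sessions, present)


def true_annotation(annotation: CellAnnotation, truth: SyntheticTruth) -> CellAnnotation:
    """Annotation with ground-truth cell types and debris flags filled in.

    Convenience for exercising the statistical stages in isolation from
    debris removal and cell typing.
    """
    df = annotation.df.copy()
    ct = pd.Series(truth.celltype_of_barcode)
    df.loc[ct.index, "cell_type"] = ct.astype(object)
    df.loc[list(truth.debris_barcodes), "debris"] = True
    return CellAnnotation(df)


def marker_panel(config: SimConfig) -> dict:
    """The marker panel implied by the config's cell-type specs."""
    return {ct.name: list(ct.marker_genes) for ct in config.cell_types}
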