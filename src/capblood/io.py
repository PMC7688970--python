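"""Core data containers and standard-format I/O.

The on-disk layout follows the 10x Genomics v2 convention: a Matrix Market
triplet file with genes as rows and barcodes as columns, plus ``barcodes.tsv``
and ``features.tsv`` name lists. Internally the matrix is always oriented
barcodes x genes; the transpose happens exactly once, at the disk boundary.

Sample bookkeeping lives in :class:`SampleDesign`: the ordered (day, AM/PM)
session grid, the subject x session availability mask, and the per-subject
count of present sessions that the AM/PM renormalization weights by.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

SESSIONS = ("AM", "PM")

MATRIX_FILE = "matrix.mtx"
BARCODES_FILE = "barcodes.tsv"
FEATURES_FILE = "features.tsv"
METADATA_FILE = "metadata.tsv"


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


@dataclass
class CountMatrix:
    """Sparse raw UMI counts, barcodes x genes, with name lists.

    Gene identity is keyed by ``gene_ids`` (unique); ``gene_names`` carries
    display symbols and may contain duplicates.
    """

    counts: sp.csr_matrix
    barcodes: np.ndarray
    gene_ids: np.ndarray
    gene_names: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        n_bc, n_g = self.counts.shape
        if len(self.barcodes) != n_bc:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for a {n_bc}-row matrix"
            )
        if len(self.gene_ids) != n_g or len(self.gene_names) != n_g:
            raise FormatError(
                f"gene list length does not match {n_g} matrix columns"
            )
        if len(set(self.barcodes)) != n_bc:
            raise FormatError("duplicate barcodes")
        if len(set(self.gene_ids)) != n_g:
            raise FormatError("duplicate gene ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def total_umis(self) -> np.ndarray:
        """Per-barcode total UMI count."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_barcodes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            self.counts[idx], self.barcodes[idx], self.gene_ids, self.gene_names
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            self.counts[:, idx],
            self.barcodes,
            self.gene_ids[idx],
            self.gene_names[idx],
        )

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)


def session_key(day: int, session: str) -> str:
    return f"D{day}-{session}"


@dataclass
class SampleDesign:
    """Subjects, the chronological session grid, and availability.

    ``present[j, k]`` flags whether subject j contributed sample k;
    ``n_sessions_per_subject`` (N_s) are its row sums. ``is_am`` and
    ``is_pm`` are the AM/PM indicator vectors over sessions and always
    sum to one per session.
    """

    subjects: np.ndarray
    sessions: list  # (day, "AM"|"PM"), chronological
    present: np.ndarray  # bool, subjects x sessions

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.present = np.asarray(self.present, dtype=bool)
        for _, ses in self.sessions:
            if ses not in SESSIONS:
                raise FormatError(f"session label {ses!r} not in {SESSIONS}")
        if self.present.shape != (len(self.subjects), len(self.sessions)):
            raise FormatError("present mask shape mismatch")

    @property
    def session_keys(self) -> list:
        return [session_key(d, s) for d, s in self.sessions]

    @property
    def is_am(self) -> np.ndarray:
        return np.array([s == "AM" for _, s in self.sessions])

    @property
    def is_pm(self) -> np.ndarray:
        return ~self.is_am

    @property
    def n_sessions_per_subject(self) -> np.ndarray:
        return self.present.sum(axis=1)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_samples(self) -> int:
        return len(self.sessions)


@dataclass
class CellAnnotation:
    """Per-barcode subject / session / cell-type / debris bookkeeping.

    Backed by a DataFrame indexed by barcode with columns ``subject``,
    ``day``, ``session``, ``cell_type`` (NA until typed) and ``debris``.
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject", "day", "session", "cell_type", "debris")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise FormatError(f"annotation missing column {col!r}")
        if self.df.index.has_duplicates:
            raise FormatError("duplicate barcodes in annotation")

    @property
    def barcodes(self) -> np.ndarray:
        return self.df.index.to_numpy(dtype=object)

    @property
    def session_keys(self) -> pd.Series:
        keys = (
            "D"
            + self.df["day"].astype("Int64").astype(str)
            + "-"
            + self.df["session"].astype(str)
        )
        keys[self.df["day"].isna() | self.df["session"].isna()] = pd.NA
        return keys

    def subset(self, barcodes) -> "CellAnnotation":
        return CellAnnotation(self.df.loc[list(barcodes)].copy())

    def with_cell_types(self, labels: pd.Series) -> "CellAnnotation":
        df = self.df.copy()
        df.loc[labels.index, "cell_type"] = labels
        return CellAnnotation(df)

    def with_debris(self, debris: pd.Series) -> "CellAnnotation":
        df = self.df.copy()
        df.loc[debris.index, "debris"] = debris.astype(bool)
        return CellAnnotation(df)

    def kept(self) -> pd.DataFrame:
        """Rows for non-debris barcodes."""
        return self.df[~self.df["debris"].astype(bool)]


def empty_annotation(barcodes) -> CellAnnotation:
    df = pd.DataFrame(
        {
            "subject": pd.array([pd.NA] * len(barcodes), dtype=object),
            "day": pd.array([pd.NA] * len(barcodes), dtype="Int64"),
            "session": pd.array([pd.NA] * len(barcodes), dtype=object),
            "cell_type": pd.array([pd.NA] * len(barcodes), dtype=object),
            "debris": np.zeros(len(barcodes), dtype=bool),
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    return CellAnnotation(df)


# ---------------------------------------------------------------------------
# 10x-style directory I/O


def write_tenx_dir(matrix: CountMatrix, annotation, path) -> Path:
    """Write a 10x v2-style directory (.mtx + tsv lists, genes-as-rows).

    ``annotation`` may be None; if given, a ``metadata.tsv`` with barcode,
    subject, day, session columns is written alongside.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # 10x files store genes x barcodes
    mmwrite(
        str(path / MATRIX_FILE),
        sp.coo_matrix(matrix.counts.T),
        field="integer",
    )
    pd.Series(matrix.barcodes).to_csv(
        path / BARCODES_FILE, sep="\t", index=False, header=False
    )
    pd.DataFrame(
        {
            "id": matrix.gene_ids,
            "name": matrix.gene_names,
            "type": "Gene Expression",
        }
    ).to_csv(path / FEATURES_FILE, sep="\t", index=False, header=False)
    if annotation is not None:
        if set(annotation.barcodes) != set(matrix.barcodes):
            raise FormatError("annotation and matrix barcode sets differ")
        meta = annotation.df.loc[list(matrix.barcodes), ["subject", "day", "session"]]
        meta = meta.reset_index().rename(columns={"index": "barcode"})
        meta.columns = ["barcode", "subject", "day", "session"]
        meta.to_csv(path / METADATA_FILE, sep="\t", index=False)
    return path


def read_tenx_dir(path) -> CountMatrix:
    """Read a 10x v2-style directory into a barcodes x genes CountMatrix."""
    path = Path(path)
    for fname in (MATRIX_FILE, BARCODES_FILE, FEATURES_FILE):
        if not (path / fname).exists():
            raise FormatError(f"missing {fname} in {path}")
    mat = mmread(str(path / MATRIX_FILE))
    if mat.size and not np.issubdtype(np.asarray(mat.data).dtype, np.integer):
        if not np.allclose(mat.data, np.round(mat.data)):
            raise FormatError("non-integer entries in count matrix")
    mat = sp.csr_matrix(mat.T).astype(np.int64)  # to barcodes x genes
    if (path / BARCODES_FILE).stat().st_size:
        barcodes = pd.read_csv(
            path / BARCODES_FILE, sep="\t", header=None
        )[0].to_numpy(dtype=object)
    else:
        barcodes = np.array([], dtype=object)
    if (path / FEATURES_FILE).stat().st_size:
        feats = pd.read_csv(path / FEATURES_FILE, sep="\t", header=None)
    else:
        feats = pd.DataFrame(columns=[0, 1])
    if mat.shape[0] != len(barcodes):
        raise FormatError(
            f"matrix has {mat.shape[0]} barcodes, list has {len(barcodes)}"
        )
    if mat.shape[1] != len(feats):
        raise FormatError(
            f"matrix has {mat.shape[1]} genes, feature list has {len(feats)}"
        )
    ids = feats[0].to_numpy(dtype=object)
    names = (feats[1] if 1 in feats.columns else feats[0]).to_numpy(dtype=object)
    return CountMatrix(mat, barcodes, ids, names)


def read_metadata(path, matrix: CountMatrix):
    """Read the per-barcode metadata TSV and derive the sample design.

    Returns ``(CellAnnotation, SampleDesign)``. Metadata barcodes absent
    from the matrix are ignored with a warning; matrix barcodes absent from
    the metadata stay unassigned.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"barcode": str, "subject": str})
    required = {"barcode", "subject", "day", "session"}
    if not required.issubset(meta.columns):
        raise FormatError(f"metadata needs columns {sorted(required)}")
    bad = set(meta["session"].dropna()) - set(SESSIONS)
    if bad:
        raise FormatError(f"session values outside AM/PM: {sorted(bad)}")

    known = set(matrix.barcodes)
    extra = ~meta["barcode"].isin(known)
    if extra.any():
        warnings.warn(
            f"{int(extra.sum())} metadata barcodes not in matrix; ignored"
        )
        meta = meta[~extra]
    ann = empty_annotation(matrix.barcodes)
    meta = meta.set_index("barcode")
    ann.df.loc[meta.index, "subject"] = meta["subject"].astype(object)
    ann.df.loc[meta.index, "day"] = meta["day"].astype("Int64")
    ann.df.loc[meta.index, "session"] = meta["session"].astype(object)
    design = design_from_annotation(ann)
    return ann, design


def design_from_annotation(annotation: CellAnnotation) -> SampleDesign:
    """Enumerate observed subjects and (day, session) pairs chronologically."""
    df = annotation.df.dropna(subset=["subject", "day", "session"])
    subjects = np.array(sorted(df["subject"].unique()), dtype=object)
    sessions = sorted(
        {(int(d), s) for d, s in zip(df["day"], df["session"])},
        key=lambda t: (t[0], t[1]),  # AM < PM lexicographically
    )
    ses_idx = {s: i for i, s in enumerate(sessions)}
    sub_idx = {s: i for i, s in enumerate(subjects)}
    present = np.zeros((len(subjects), len(sessions)), dtype=bool)
    for (sub, d, s), _ in df.groupby(["subject", "day", "session"]):
        present[sub_idx[sub], ses_idx[(int(d), s)]] = True
    return SampleDesign(subjects, sessions, present)
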