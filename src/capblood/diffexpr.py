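"""Diurnal and specificity testing on the pseudobulk tensor.

The testing layer is organised as fitted models: each Model is built from a
:class:`~capblood.pseudobulk.MeanExpressionTensor` and a sample design, and
``fit()`` returns a Results object carrying the per-(gene, cell type)
statistics, BH-corrected q-values, and a ``summary()`` table.

Diurnal testing first removes stable between-subject differences by
renormalizing each subject's trace to a zero equally weighted AM/PM mean:

    mu'[g,s,c,k] = mu[g,s,c,k] - (mean_AM mu[g,s,c,.] + mean_PM mu[g,s,c,.]) / 2

and then compares the pooled AM and PM mu' values with a two-tailed
classical t-test per (gene, cell type). Benjamini-Hochberg correction is
applied jointly over the whole gene x cell-type grid. The per-gene plotting
statistic is the signed Z-score at the minimum p over cell types.

Subject and cell-type specificity use one-way ANOVAs on the per-sample
means, with the log2 F at minimum p as the plotting statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import CellAnnotation, SampleDesign, session_key
from .pseudobulk import MeanExpressionTensor, POPULATION
from .stats import (
    bh_correct,
    oneway_anova,
    pooled_ttest,
    signed_z_from_p,
    two_proportion_z,  # noqa: F401  (re-exported with the stats surface)
)

logger = logging.getLogger(__name__)

CLASS_BOTH = "both"
CLASS_CELLTYPE = "celltype_specific"
CLASS_POPULATION_ONLY = "population_only_abundance_suspect"
CLASS_NONE = "none"


# ---------------------------------------------------------------------------
# Eq-style AM/PM renormalization


def renormalize_am_pm(
    tensor: MeanExpressionTensor, design: SampleDesign
) -> MeanExpressionTensor:
    """Subtract each subject's equally weighted AM/PM mean per (gene, cell type).

    Subjects lacking an unmasked sample in either session class are masked
    out entirely for that cell type (the offset is undefined for them).
    """
    is_am = design.is_am
    mu = tensor.mu.copy()
    mask = tensor.mask.copy()
    S, C, K = mask.shape
    for s in range(S):
        for c in range(C):
            avail = mask[s, c]
            am, pm = avail & is_am, avail & ~is_am
            if not am.any() or not pm.any():
                if avail.any():
                    mask[s, c] = False
                continue
            offset = 0.5 * (
                mu[:, s, c, am].mean(axis=1) + mu[:, s, c, pm].mean(axis=1)
            )
            mu[:, s, c, avail] -= offset[:, None]
    return replace(tensor, mu=mu, mask=mask)


def _pooled_class_values(tensor, design, c: int, am: bool) -> np.ndarray:
    """mu values (genes x observations) for one session class, pooled over subjects."""
    sel = design.is_am if am else design.is_pm
    cols = []
    S = tensor.mask.shape[0]
    for s in range(S):
        ks = np.flatnonzero(tensor.mask[s, c] & sel)
        for k in ks:
            cols.append(tensor.mu[:, s, c, k])
    return np.column_stack(cols) if cols else np.empty((tensor.n_genes, 0))


# ---------------------------------------------------------------------------
# Results containers


class _ResultsBase:
    """Shared surface: long-format frame, per-gene min-p view, summary."""

    stat_col: str = "stat"

    def __init__(self, frame: pd.DataFrame, fdr: float):
        self.frame = frame
        self.fdr = fdr

    def per_gene(self) -> pd.DataFrame:
        """One row per gene: the cell type attaining the minimum p."""
        f = self.frame.dropna(subset=["p"]).sort_values(["p", "cell_type"])
        return f.groupby("gene", sort=True).head(1).set_index("gene").sort_index()

    def significant_genes(self) -> list:
        sig = self.frame[self.frame["significant"]]
        return sorted(sig["gene"].unique())

    def n_significant(self) -> int:
        return len(self.significant_genes())

    def summary(self) -> str:
        f = self.frame
        lines = [
            f"{type(self).__name__}",
            "=" * 48,
            f"tests run            : {int(f['p'].notna().sum())}",
            f"genes tested         : {f['gene'].nunique()}",
            f"cell types           : {sorted(f['cell_type'].unique())}",
            f"FDR level            : {self.fdr}",
            f"significant tests    : {int(f['significant'].sum())}",
            f"significant genes    : {self.n_significant()}",
        ]
        top = self.per_gene().head(10)
        if len(top):
            lines += ["", "top genes (min p over cell types):",
                      top.to_string(max_cols=8, float_format=lambda v: f"{v:.3g}")]
        return "\n".join(lines)


class DiurnalResults(_ResultsBase):
    """Per-(gene, cell type) AM-vs-PM t, signed Z, p, q."""

    stat_col = "t"


class SpecificityResults(_ResultsBase):
    """Per-(gene, cell type) one-way ANOVA F, log2 F, p, q."""

    stat_col = "F"

    def __init__(self, frame: pd.DataFrame, fdr: float, axis: str):
        super().__init__(frame, fdr)
        self.axis = axis


# ---------------------------------------------------------------------------
# Models


class DiurnalModel:
    """AM-vs-PM differential expression per cell type.

    Parameters
    ----------
    tensor : MeanExpressionTensor
        Pseudobulk means; pass a pooled tensor for the population-level test.
    design : SampleDesign
    renormalize : bool
        Apply the per-subject AM/PM renormalization before testing
        (default True, as specified by the procedure).
    """

    def __init__(self, tensor, design, renormalize: bool = True):
        self.tensor = tensor
        self.design = design
        self.renormalize = renormalize

    def fit(self, fdr: float = 0.05) -> DiurnalResults:
        tensor = (
            renormalize_am_pm(self.tensor, self.design)
            if self.renormalize
            else self.tensor
        )
        rows = []
        for c, cell_type in enumerate(tensor.cell_types):
            am = _pooled_class_values(tensor, self.design, c, am=True)
            pm = _pooled_class_values(tensor, self.design, c, am=False)
            if am.shape[1] < 2 or pm.shape[1] < 2:
                warnings.warn(
                    f"cell type {cell_type!r}: fewer than two AM or PM "
                    "samples after masking; excluded from the diurnal test"
                )
                continue
            t, p, degen = pooled_ttest(am, pm)
            z = signed_z_from_p(p, np.sign(am.mean(axis=1) - pm.mean(axis=1)))
            rows.append(
                pd.DataFrame(
                    {
                        "gene": tensor.genes,
                        "cell_type": cell_type,
                        "n_am": am.shape[1],
                        "n_pm": pm.shape[1],
                        "mean_am": am.mean(axis=1),
                        "mean_pm": pm.mean(axis=1),
                        "t": t,
                        "z": z,
                        "p": p,
                        "degenerate": degen,
                    }
                )
            )
        if not rows:
            raise ValueError("no cell type had enough AM and PM samples")
        frame = pd.concat(rows, ignore_index=True)
        # joint BH over the full gene x cell-type grid
        frame["q"], frame["significant"] = bh_correct(frame["p"], fdr)
        return DiurnalResults(frame, fdr)


class SubjectSpecificityModel:
    """One-way ANOVA across subjects of per-sample means, per cell type."""

    def __init__(self, tensor, design):
        self.tensor = tensor
        self.design = design

    def fit(self, fdr: float = 0.05) -> SpecificityResults:
        t = self.tensor
        rows = []
        for c, cell_type in enumerate(t.cell_types):
            groups, n_ok = [], 0
            for s in range(len(t.subjects)):
                ks = np.flatnonzero(t.mask[s, c])
                if ks.size == 0:
                    continue
                groups.append(t.mu[:, s, c, ks])
                if ks.size >= 2:
                    n_ok += 1
            if len(groups) < 2 or n_ok < 2:
                warnings.warn(
                    f"cell type {cell_type!r}: fewer than two subjects with "
                    "two samples; excluded from the subject-specificity test"
                )
                continue
            F, p, degen = oneway_anova(groups)
            rows.append(_anova_frame(t.genes, cell_type, groups, F, p, degen))
        if not rows:
            raise ValueError("no cell type eligible for the subject test")
        frame = pd.concat(rows, ignore_index=True)
        frame["q"], frame["significant"] = bh_correct(frame["p"], fdr)
        return SpecificityResults(frame, fdr, axis="subject")


class CellTypeSpecificityModel:
    """One-way ANOVA across cell types of per-sample means, per gene."""

    def __init__(self, tensor, design):
        self.tensor = tensor
        self.design = design

    def fit(self, fdr: float = 0.05) -> SpecificityResults:
        t = self.tensor
        if len(t.cell_types) < 2:
            raise ValueError("cell-type specificity needs at least two cell types")
        groups, kept_types = [], []
        for c, cell_type in enumerate(t.cell_types):
            s_idx, k_idx = np.nonzero(t.mask[:, c, :])
            if s_idx.size < 2:
                warnings.warn(
                    f"cell type {cell_type!r}: fewer than two samples; "
                    "excluded from the cell-type specificity test"
                )
                continue
            groups.append(t.mu[:, s_idx, c, k_idx])
            kept_types.append(cell_type)
        if len(groups) < 2:
            raise ValueError("fewer than two cell types with samples")
        F, p, degen = oneway_anova(groups)
        frame = _anova_frame(t.genes, "ALL", groups, F, p, degen)
        frame["q"], frame["significant"] = bh_correct(frame["p"], fdr)
        return SpecificityResults(frame, fdr, axis="cell-type")


def _anova_frame(genes, cell_type, groups, F, p, degen) -> pd.DataFrame:
    with np.errstate(divide="ignore"):
        log2F = np.where(F > 0, np.log2(np.where(F > 0, F, 1.0)), -np.inf)
    return pd.DataFrame(
        {
            "gene": genes,
            "cell_type": cell_type,
            "n_groups": len(groups),
            "n_obs": int(sum(g.shape[1] for g in groups)),
            "F": F,
            "log2F": log2F,
            "p": p,
            "degenerate": degen,
        }
    )


# ---------------------------------------------------------------------------
# Classification and composition tests


def classify_diurnal(
    celltype_results: DiurnalResults, population_results: DiurnalResults
) -> pd.DataFrame:
    """Cross the per-type and population-level calls per gene.

    Genes significant per-type only are cell-type-specific diurnal genes;
    genes significant at the population level only are flagged as suspected
    abundance-shift artifacts; both / none complete the partition.
    """
    ct = celltype_results.frame
    sig_ct = ct[ct["significant"]].groupby("gene")["cell_type"].apply(list)
    pop_sig = set(population_results.significant_genes())
    genes = sorted(
        set(ct["gene"].unique()) | set(population_results.frame["gene"].unique())
    )
    rows = []
    for g in genes:
        in_ct = g in sig_ct.index
        in_pop = g in pop_sig
        if in_ct and in_pop:
            cls = CLASS_BOTH
        elif in_ct:
            cls = CLASS_CELLTYPE
        elif in_pop:
            cls = CLASS_POPULATION_ONLY
        else:
            cls = CLASS_NONE
        rows.append(
            {
                "gene": g,
                "classification": cls,
                "cell_types": ",".join(sig_ct[g]) if in_ct else "",
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def celltype_sample_fractions(
    annotation: CellAnnotation, design: SampleDesign
) -> pd.DataFrame:
    """Cell-type composition per sample: rows (subject, sample), columns types."""
    kept = annotation.kept().dropna(subset=["subject", "day", "session", "cell_type"])
    if kept.empty:
        raise ValueError("no typed cells")
    keys = [session_key(int(d), s) for d, s in zip(kept["day"], kept["session"])]
    tab = pd.crosstab(
        index=[kept["subject"], pd.Series(keys, index=kept.index, name="sample")],
        columns=kept["cell_type"],
    )
    return tab.div(tab.sum(axis=1), axis=0)


def abundance_shift_test(
    annotation: CellAnnotation,
    design: SampleDesign,
    cell_type: str,
    direction: str = "PM>AM",
):
    """One-sided t-test for a session-class shift in a type's abundance.

    Per-(subject, sample) fractions of the given cell type are compared
    between PM and AM samples; ``direction`` "PM>AM" tests for afternoon
    enrichment. Returns ``(t, p)``.
    """
    fractions = celltype_sample_fractions(annotation, design)
    if cell_type not in fractions.columns:
        raise ValueError(f"cell type {cell_type!r} absent from annotation")
    values = fractions[cell_type]
    is_pm = values.index.get_level_values("sample").str.endswith("PM")
    pm, am = values[is_pm].to_numpy(), values[~is_pm].to_numpy()
    if len(pm) < 2 or len(am) < 2:
        raise ValueError("need at least two AM and two PM samples")
    if direction == "PM>AM":
        t, p, _ = pooled_ttest(pm[None, :], am[None, :], alternative="greater")
    elif direction == "AM>PM":
        t, p, _ = pooled_ttest(am[None, :], pm[None, :], alternative="greater")
    else:
        raise ValueError("direction must be 'PM>AM' or 'AM>PM'")
    return float(t[0]), float(p[0])


def compare_cohort_fractions(
    cohort_a: pd.DataFrame, cohort_b: pd.DataFrame, fdr: float = 0.05
) -> pd.DataFrame:
    """Two-sided t-test of per-sample cell-type fractions between cohorts.

    Inputs are samples x cell-type fraction tables. Cell types present in
    only one cohort are skipped with a warning; BH correction runs across
    the compared cell types.
    """
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise ValueError("each cohort needs at least two samples")
    shared = [c for c in cohort_a.columns if c in cohort_b.columns]
    skipped = (set(cohort_a.columns) | set(cohort_b.columns)) - set(shared)
    if skipped:
        warnings.warn(f"cell types in only one cohort skipped: {sorted(skipped)}")
    rows = []
    for ct in shared:
        t, p, _ = pooled_ttest(
            cohort_a[ct].to_numpy()[None, :], cohort_b[ct].to_numpy()[None, :]
        )
        rows.append({"cell_type": ct, "t": float(t[0]), "p": float(p[0])})
    out = pd.DataFrame(rows).set_index("cell_type")
    out["q"], out["significant"] = bh_correct(out["p"], fdr)
    return out


def expression_abundance(normalized, annotation: CellAnnotation) -> pd.Series:
    """Largest percent of cells in any one cell type expressing each gene."""
    kept = annotation.kept().dropna(subset=["cell_type"])
    kept = kept[kept.index.isin(normalized.barcodes)]
    bc_pos = {b: i for i, b in enumerate(normalized.barcodes)}
    binary = normalized.fractions.astype(bool).astype(np.int8)
    best = np.zeros(normalized.n_genes)
    for _, grp in kept.groupby("cell_type"):
        rows = [bc_pos[b] for b in grp.index]
        pct = np.asarray(binary[rows].mean(axis=0)).ravel() * 100.0
        best = np.maximum(best, pct)
    return pd.Series(best, index=pd.Index(normalized.gene_ids, name="gene"))
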