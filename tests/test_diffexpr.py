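"""AM/PM renormalization, diurnal and specificity models, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from capblood.diffexpr import (
    CLASS_BOTH,
    CLASS_CELLTYPE,
    CLASS_NONE,
    CLASS_POPULATION_ONLY,
    CellTypeSpecificityModel,
    DiurnalModel,
    SubjectSpecificityModel,
    abundance_shift_test,
    classify_diurnal,
    compare_cohort_fractions,
    expression_abundance,
    renormalize_am_pm,
)
from capblood.io import SampleDesign
from capblood.preprocess import normalize
from capblood.pseudobulk import MeanExpressionTensor, build_tensor


def make_tensor(mu, mask=None, genes=None):
    """mu: genes x subjects x celltypes x samples."""
    mu = np.asarray(mu, dtype=float)
    G, S, C, K = mu.shape
    if mask is None:
        mask = np.ones((S, C, K), dtype=bool)
    return MeanExpressionTensor(
        mu=mu,
        mask=np.asarray(mask, dtype=bool),
        n_cells=np.where(mask, 10, 0),
        genes=np.array(genes or [f"g{i}" for i in range(G)], dtype=object),
        subjects=np.array([f"S{j+1}" for j in range(S)], dtype=object),
        cell_types=np.array([f"T{c+1}" for c in range(C)], dtype=object),
        sample_keys=np.array([f"D{k//2+1}-{'AM' if k % 2 == 0 else 'PM'}"
                              for k in range(K)], dtype=object),
        min_cells=1,
    )


def design_for(n_subjects, n_days):
    sessions = [(d, s) for d in range(1, n_days + 1) for s in ("AM", "PM")]
    return SampleDesign(
        np.array([f"S{j+1}" for j in range(n_subjects)], dtype=object),
        sessions,
        np.ones((n_subjects, len(sessions)), dtype=bool),
    )


class TestRenormalization:
    def test_hand_arithmetic(self):
        # AM means {2, 4}, PM mean {6}: offset (3 + 6)/2 = 4.5
        mu = np.array([[[[2.0, 6.0, 4.0, 6.0]]]])  # AM, PM, AM, PM
        mask = np.array([[[True, True, True, False]]])
        design = design_for(1, 2)
        out = renormalize_am_pm(make_tensor(mu, mask), design)
        np.testing.assert_allclose(
            out.mu[0, 0, 0, :3], [-2.5, 1.5, -0.5], rtol=1e-12
        )

    def test_constant_trace_maps_to_zero(self):
        mu = np.full((3, 2, 2, 6), 0.7)
        design = design_for(2, 3)
        out = renormalize_am_pm(make_tensor(mu), design)
        np.testing.assert_allclose(out.mu[:, out.mask], 0.0, atol=1e-15)

    def test_balanced_am_pm_mean_is_zero_identity(self, small_typed):
        matrix, ann, truth, design = small_typed
        tensor = build_tensor(normalize(matrix), ann, design)
        out = renormalize_am_pm(tensor, design)
        is_am = design.is_am
        S, C, _ = out.mask.shape
        for s in range(S):
            for c in range(C):
                avail = out.mask[s, c]
                if not avail.any():
                    continue
                am = out.mu[:, s, c, avail & is_am].mean(axis=1)
                pm = out.mu[:, s, c, avail & ~is_am].mean(axis=1)
                np.testing.assert_allclose(am / 2 + pm / 2, 0.0, atol=1e-12)

    def test_subject_missing_one_class_masked_out(self):
        mu = np.ones((1, 1, 1, 4))
        mask = np.array([[[True, False, True, False]]])  # AM only
        out = renormalize_am_pm(make_tensor(mu, mask), design_for(1, 2))
        assert not out.mask.any()


class TestDiurnalModel:
    def test_identical_am_pm_gives_t0_p1(self):
        vals = np.array([0.1, 0.2, 0.3])
        mu = np.zeros((1, 1, 1, 6))
        mu[0, 0, 0, ::2] = vals  # AM
        mu[0, 0, 0, 1::2] = vals  # PM identical
        res = DiurnalModel(make_tensor(mu), design_for(1, 3),
                           renormalize=False).fit()
        row = res.frame.iloc[0]
        assert row["t"] == 0 and row["p"] == 1

    def test_matches_textbook_ttest_without_renormalization(self):
        am = np.array([-1.0, -2.0, -1.5, -1.2])
        pm = np.array([1.0, 2.0, 1.5, 1.2])
        mu = np.zeros((1, 1, 1, 8))
        mu[0, 0, 0, ::2] = am
        mu[0, 0, 0, 1::2] = pm
        res = DiurnalModel(make_tensor(mu), design_for(1, 4),
                           renormalize=False).fit()
        ref = ss.ttest_ind(am, pm)
        np.testing.assert_allclose(res.frame["t"].iloc[0], ref.statistic,
                                   rtol=1e-10)
        np.testing.assert_allclose(res.frame["p"].iloc[0], ref.pvalue,
                                   rtol=1e-10)

    def test_z_sign_follows_am_minus_pm(self):
        mu = np.zeros((2, 2, 1, 6))
        rng = np.random.default_rng(0)
        base = rng.normal(size=(2, 2, 1, 6)) * 0.1
        mu = base.copy()
        mu[0, :, :, ::2] += 2.0  # gene0 higher in AM
        mu[1, :, :, 1::2] += 2.0  # gene1 higher in PM
        res = DiurnalModel(make_tensor(mu), design_for(2, 3)).fit()
        f = res.frame.set_index("gene")
        assert f.loc["g0", "z"] > 0 > f.loc["g1", "z"]

    def test_per_gene_takes_minimum_p_across_types(self):
        rng = np.random.default_rng(1)
        mu = rng.normal(size=(3, 2, 3, 6)) * 0.1
        mu[0, :, 2, ::2] += 5.0  # strong effect for gene0 in T3 only
        res = DiurnalModel(make_tensor(mu), design_for(2, 3)).fit()
        per = res.per_gene()
        assert per.loc["g0", "cell_type"] == "T3"
        f = res.frame
        assert per.loc["g0", "p"] == f[f["gene"] == "g0"]["p"].min()

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        mu = np.abs(rng.normal(size=(4, 2, 2, 6)))
        d = design_for(2, 3)
        r1 = DiurnalModel(make_tensor(mu), d).fit()
        r2 = DiurnalModel(make_tensor(mu * 1e4), d).fit()
        np.testing.assert_allclose(r1.frame["t"], r2.frame["t"], rtol=1e-9)
        np.testing.assert_allclose(r1.frame["p"], r2.frame["p"], rtol=1e-9)

    def test_population_equals_celltype_on_single_type_data(self, toy,
                                                            annotation_for):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5, size=(48, 30)) + 1
        m = toy(counts)
        subj = ["S1", "S2"] * 24
        day = [1 + (i // 4) % 3 for i in range(48)]
        ses = ["AM", "AM", "PM", "PM"] * 12
        ann = annotation_for(m, subject=subj, day=day, session=ses,
                             cell_type=["T"] * 48)
        from capblood.io import design_from_annotation

        design = design_from_annotation(ann)
        norm = normalize(m)
        t_ct = build_tensor(norm, ann, design, min_cells=1)
        t_pool = build_tensor(norm, ann, design, min_cells=1, pooled=True)
        r_ct = DiurnalModel(t_ct, design).fit()
        r_pool = DiurnalModel(t_pool, design).fit()
        np.testing.assert_allclose(r_ct.frame["t"], r_pool.frame["t"],
                                   rtol=1e-12)


class TestSpecificityModels:
    def test_subject_anova_matches_scipy(self):
        rng = np.random.default_rng(4)
        mu = rng.normal(size=(5, 3, 1, 6))
        d = design_for(3, 3)
        res = SubjectSpecificityModel(make_tensor(mu), d).fit()
        for i in range(5):
            ref = ss.f_oneway(mu[i, 0, 0], mu[i, 1, 0], mu[i, 2, 0])
            row = res.frame[res.frame["gene"] == f"g{i}"].iloc[0]
            np.testing.assert_allclose(row["F"], ref.statistic, rtol=1e-10)
            np.testing.assert_allclose(row["p"], ref.pvalue, rtol=1e-10)

    def test_constant_distinct_subjects_degenerate(self):
        mu = np.zeros((1, 4, 1, 6))
        for j in range(4):
            mu[0, j, 0, :] = j + 1.0
        res = SubjectSpecificityModel(make_tensor(mu), design_for(4, 3)).fit()
        row = res.frame.iloc[0]
        assert np.isinf(row["F"]) and row["degenerate"]
        assert row["p"] == np.nextafter(0.0, 1.0)

    def test_log2f_is_log2_of_f(self):
        rng = np.random.default_rng(5)
        mu = rng.normal(size=(3, 3, 1, 6))
        res = SubjectSpecificityModel(make_tensor(mu), design_for(3, 3)).fit()
        ok = res.frame["F"] > 0
        np.testing.assert_allclose(
            res.frame.loc[ok, "log2F"], np.log2(res.frame.loc[ok, "F"]),
            rtol=1e-12,
        )

    def test_celltype_axis_detects_marker_gene(self):
        rng = np.random.default_rng(6)
        mu = np.abs(rng.normal(size=(10, 2, 3, 6))) * 0.05 + 0.5
        mu[0, :, 1, :] += 3.0  # gene0 high in T2 across all samples
        res = CellTypeSpecificityModel(make_tensor(mu), design_for(2, 3)).fit()
        f = res.frame.set_index("gene")
        assert f.loc["g0", "significant"]
        assert f.loc["g0", "F"] == res.frame["F"].max()

    def test_single_cell_type_rejected(self):
        mu = np.ones((2, 2, 1, 6))
        with pytest.raises(ValueError, match="two cell types"):
            CellTypeSpecificityModel(make_tensor(mu), design_for(2, 3)).fit()


class TestClassification:
    def _results(self, genes, sig):
        frame = pd.DataFrame(
            {
                "gene": genes,
                "cell_type": "T1",
                "p": [0.001 if s else 0.9 for s in sig],
                "q": [0.01 if s else 0.95 for s in sig],
                "significant": sig,
            }
        )
        from capblood.diffexpr import DiurnalResults

        return DiurnalResults(frame, 0.05)

    def test_four_way_partition(self):
        genes = ["a", "b", "c", "d"]
        ct = self._results(genes, [True, True, False, False])
        pop = self._results(genes, [True, False, True, False])
        out = classify_diurnal(ct, pop)
        assert out.loc["a", "classification"] == CLASS_BOTH
        assert out.loc["b", "classification"] == CLASS_CELLTYPE
        assert out.loc["c", "classification"] == CLASS_POPULATION_ONLY
        assert out.loc["d", "classification"] == CLASS_NONE


class TestAbundanceShift:
    def _annotation(self, annotation_for, toy, am_b, pm_b, n=40):
        counts = np.ones((n * 6, 2), dtype=int)
        m = toy(counts)
        rows = []
        for k, (day, ses) in enumerate(
            [(d, s) for d in (1, 2, 3) for s in ("AM", "PM")]
        ):
            frac = am_b if ses == "AM" else pm_b
            n_b = int(round(frac * n))
            rows += [("S1", day, ses, "B")] * n_b
            rows += [("S1", day, ses, "T")] * (n - n_b)
        df = pd.DataFrame(rows, columns=["subject", "day", "session",
                                         "cell_type"])
        ann = annotation_for(m, subject=df["subject"], day=df["day"],
                             session=df["session"], cell_type=df["cell_type"])
        from capblood.io import design_from_annotation

        return ann, design_from_annotation(ann)

    def test_identical_fractions_p_half(self, annotation_for, toy):
        ann, design = self._annotation(annotation_for, toy, 0.25, 0.25)
        _, p = abundance_shift_test(ann, design, "B")
        assert p == pytest.approx(0.5)

    def test_direction_reversal_complements_p(self, annotation_for, toy):
        ann, design = self._annotation(annotation_for, toy, 0.20, 0.35)
        _, p_fwd = abundance_shift_test(ann, design, "B", "PM>AM")
        _, p_rev = abundance_shift_test(ann, design, "B", "AM>PM")
        np.testing.assert_allclose(p_fwd + p_rev, 1.0, rtol=1e-10)
        assert p_fwd < 0.05

    def test_unknown_cell_type_raises(self, annotation_for, toy):
        ann, design = self._annotation(annotation_for, toy, 0.2, 0.2)
        with pytest.raises(ValueError, match="absent"):
            abundance_shift_test(ann, design, "NK")


class TestCohortComparison:
    def test_identical_cohorts_p_one(self):
        a = pd.DataFrame({"B": [0.1, 0.1, 0.1], "T": [0.9, 0.9, 0.9]})
        out = compare_cohort_fractions(a, a.copy())
        assert (out["t"] == 0).all() and (out["p"] == 1).all()

    def test_planted_monocyte_enrichment_detected(self, rng):
        a = pd.DataFrame(
            {"Mono": rng.normal(0.10, 0.01, 8), "T": rng.normal(0.6, 0.02, 8)}
        )
        b = pd.DataFrame(
            {"Mono": rng.normal(0.25, 0.01, 8), "T": rng.normal(0.6, 0.02, 8)}
        )
        out = compare_cohort_fractions(a, b)
        assert out.loc["Mono", "significant"]
        assert not out.loc["T", "significant"]

    def test_single_sample_cohort_rejected(self):
        a = pd.DataFrame({"B": [0.1]})
        with pytest.raises(ValueError, match="two samples"):
            compare_cohort_fractions(a, a)

    def test_unshared_type_skipped_with_warning(self):
        a = pd.DataFrame({"B": [0.1, 0.2], "T": [0.9, 0.8]})
        b = pd.DataFrame({"B": [0.15, 0.22]})
        with pytest.warns(UserWarning, match="skipped"):
            out = compare_cohort_fractions(a, b)
        assert list(out.index) == ["B"]


def test_expression_abundance_max_over_types(toy, annotation_for):
    counts = np.array([[1, 0], [1, 0], [2, 1], [2, 0]])
    m = toy(counts)
    ann = annotation_for(m, cell_type=["B", "B", "T", "T"])
    ab = expression_abundance(normalize(m), ann)
    assert ab["g0"] == pytest.approx(100.0)  # every cell expresses g0
    assert ab["g1"] == pytest.approx(50.0)  # half of T cells, no B cells
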