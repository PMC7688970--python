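"""The statistical primitives against independently coded oracles."""

import numpy as np
from hypothesis import given, settings, strategies as st
from scipy import stats as ss

from capblood.stats import (
    bh_correct,
    oneway_anova,
    pooled_ttest,
    signed_z_from_p,
    two_proportion_z,
)


def textbook_t(a, b):
    """Pooled-variance two-sample t, coded from the formula."""
    na, nb = len(a), len(b)
    sp2 = (np.sum((a - np.mean(a)) ** 2) + np.sum((b - np.mean(b)) ** 2)) / (
        na + nb - 2
    )
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2 * ss.t.sf(abs(t), na + nb - 2)


def textbook_f(groups):
    """One-way ANOVA F from the sum-of-squares decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, ss.f.sf(F, dfb, dfw)


def textbook_two_prop_z(c1, n1, c2, n2):
    p1, p2 = c1 / n1, c2 / n2
    phat = (c1 + c2) / (n1 + n2)
    return (p1 - p2) / np.sqrt(phat * (1 - phat) * (1 / n1 + 1 / n2))


def bh_oracle(p, alpha):
    """Step-up by exhaustive search over the cutoff rank."""
    p = np.asarray(p)
    order = np.argsort(p, kind="mergesort")
    m = len(p)
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k / m * alpha:
            best_k = k
    reject = np.zeros(m, dtype=bool)
    if best_k:
        reject[order[:best_k]] = True
    return reject


class TestPooledTTest:
    def test_matches_textbook_formula_on_random_instances(self, rng):
        for _ in range(100):
            na, nb = rng.integers(2, 12, size=2)
            a, b = rng.normal(size=na), rng.normal(size=nb)
            t, p, deg = pooled_ttest(a[None, :], b[None, :])
            t_ref, p_ref = textbook_t(a, b)
            assert not deg[0]
            np.testing.assert_allclose(t[0], t_ref, rtol=1e-10)
            np.testing.assert_allclose(p[0], p_ref, rtol=1e-10)

    def test_matches_scipy_vectorized(self, rng):
        a, b = rng.normal(size=(50, 6)), rng.normal(size=(50, 8))
        t, p, _ = pooled_ttest(a, b)
        ref = ss.ttest_ind(a, b, axis=1)
        np.testing.assert_allclose(t, ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(p, ref.pvalue, rtol=1e-12)

    def test_identical_groups_give_t0_p1(self):
        a = np.array([[1.0, 1.0, 1.0]])
        t, p, deg = pooled_ttest(a, a)
        assert t[0] == 0 and p[0] == 1 and not deg[0]

    def test_zero_variance_unequal_means_flagged_degenerate(self):
        a = np.full((1, 3), 2.0)
        b = np.full((1, 3), 5.0)
        t, p, deg = pooled_ttest(a, b)
        assert deg[0] and np.isinf(t[0]) and 0 < p[0] < 1e-300

    def test_one_sided_complement(self, rng):
        a, b = rng.normal(size=(20, 5)), rng.normal(size=(20, 5))
        _, p_gt, _ = pooled_ttest(a, b, alternative="greater")
        _, p_lt, _ = pooled_ttest(a, b, alternative="less")
        np.testing.assert_allclose(p_gt + p_lt, 1.0, rtol=1e-12)


class TestOnewayAnova:
    def test_matches_textbook_formula_on_random_instances(self, rng):
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = [rng.normal(size=rng.integers(2, 8)) for _ in range(k)]
            F, p, deg = oneway_anova([g[None, :] for g in groups])
            F_ref, p_ref = textbook_f(groups)
            assert not deg[0]
            np.testing.assert_allclose(F[0], F_ref, rtol=1e-10)
            np.testing.assert_allclose(p[0], p_ref, rtol=1e-10)

    def test_hand_example_two_groups(self):
        # {0,1,2} vs {3,4,5}: ssb = 13.5, ssw = 4, F = 13.5 / 1 = 13.5
        F, p, _ = oneway_anova(
            [np.array([[0.0, 1.0, 2.0]]), np.array([[3.0, 4.0, 5.0]])]
        )
        f_ref, p_ref = ss.f_oneway([0, 1, 2], [3, 4, 5])
        np.testing.assert_allclose(F[0], 13.5, rtol=1e-12)
        np.testing.assert_allclose(F[0], f_ref, rtol=1e-12)
        np.testing.assert_allclose(p[0], p_ref, rtol=1e-12)

    def test_constant_distinct_groups_give_inf_sentinel(self):
        groups = [np.full((1, 3), v) for v in (1.0, 2.0, 3.0, 4.0)]
        F, p, deg = oneway_anova(groups)
        assert np.isinf(F[0]) and deg[0] and p[0] == np.nextafter(0.0, 1.0)

    def test_all_constant_equal_gives_p1(self):
        groups = [np.full((1, 3), 2.0), np.full((1, 4), 2.0)]
        F, p, deg = oneway_anova(groups)
        assert F[0] == 0 and p[0] == 1 and not deg[0]


class TestBH:
    def test_hand_example_all_rejected(self):
        q, rej = bh_correct([0.01, 0.02, 0.03, 0.04], fdr=0.05)
        assert rej.all()

    def test_single_p(self):
        _, rej = bh_correct([0.04], fdr=0.05)
        assert rej[0]

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=200)
        q, _ = bh_correct(p)
        assert (q >= p - 1e-15).all()

    def test_nan_excluded(self):
        q, rej = bh_correct([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not rej[1]
        assert rej[0]

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12),
        st.floats(min_value=0.01, max_value=0.2),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_exhaustive_oracle(self, p, alpha):
        _, rej = bh_correct(p, fdr=alpha)
        np.testing.assert_array_equal(rej, bh_oracle(p, alpha))


class TestTwoProportionZ:
    def test_matches_closed_form_counts(self):
        z, _ = two_proportion_z(8, 20, 10, 100)
        np.testing.assert_allclose(z, textbook_two_prop_z(8, 20, 10, 100), rtol=1e-10)

    def test_matches_statsmodels_on_random_instances(self, rng):
        from statsmodels.stats.proportion import proportions_ztest

        for _ in range(100):
            n1, n2 = rng.integers(5, 50, size=2)
            c1 = rng.integers(1, n1)
            c2 = rng.integers(1, n2)
            z, p = two_proportion_z(c1, n1, c2, n2)
            z_ref, p_ref = proportions_ztest([c1, c2], [n1, n2])
            np.testing.assert_allclose(z, z_ref, rtol=1e-10)
            np.testing.assert_allclose(p, p_ref, rtol=1e-10)

    def test_equal_proportions_z0(self):
        z, p = two_proportion_z(5, 10, 50, 100)
        assert z == 0 and p == 1

    def test_antisymmetry(self, rng):
        for _ in range(20):
            c1, w1 = rng.uniform(1, 10), rng.uniform(10, 20)
            c2, w2 = rng.uniform(1, 10), rng.uniform(10, 20)
            z1, _ = two_proportion_z(c1, w1, c2, w2)
            z2, _ = two_proportion_z(c2, w2, c1, w1)
            np.testing.assert_allclose(z1, -z2, rtol=1e-12)


class TestSignedZ:
    def test_roundtrip_through_normal_tail(self):
        p = np.array([0.05, 0.01, 0.5])
        z = signed_z_from_p(p, np.array([1.0, -1.0, 1.0]))
        back = 2 * ss.norm.sf(np.abs(z))
        np.testing.assert_allclose(back, p, rtol=1e-10)
        assert z[0] > 0 > z[1]
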