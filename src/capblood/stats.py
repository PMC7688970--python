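"""Vectorized statistical primitives shared by the testing stages.

These are the classical pooled-variance two-sample t-test, one-way ANOVA,
Benjamini-Hochberg step-up correction, and the (optionally weighted)
two-proportion z-test. The t and F routines are implemented directly so
that many genes are tested in one vectorized call and so that degenerate
zero-variance inputs resolve by an explicit convention: equal means with
zero variance give p = 1; unequal means with zero variance give an
infinite statistic, the smallest positive p, and a degeneracy flag.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

TINY_P = np.nextafter(0.0, 1.0)


def pooled_ttest(a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"):
    """Row-wise classical (equal-variance) two-sample t-test.

    ``a`` and ``b`` are (genes x observations). Returns
    ``(t, p, degenerate)`` arrays. ``alternative`` is "two-sided",
    "greater" (mean(a) > mean(b)) or "less".
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need at least two observations per group")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    ssa = ((a - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((b - mb[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb

    degenerate = (denom == 0) & (diff != 0)
    null_flat = (denom == 0) & (diff == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    t = np.where(degenerate, np.where(diff > 0, np.inf, -np.inf), t)

    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = np.where(null_flat, 0.5 if alternative != "two-sided" else 1.0, p)
    p = np.where(degenerate, np.maximum(p, TINY_P), p)
    return t, np.clip(p, 0.0, 1.0), degenerate


def oneway_anova(groups):
    """Row-wise one-way ANOVA over a list of (genes x n_i) group arrays.

    Returns ``(F, p, degenerate)``. Groups with a single observation
    contribute to the between-group sum of squares only (as in the
    classical decomposition).
    """
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.shape[1] for g in groups])
    if (ns < 1).any():
        raise ValueError("empty group")
    N = int(ns.sum())
    k = len(groups)
    if N - k < 1:
        raise ValueError("no within-group degrees of freedom")
    means = np.stack([g.mean(axis=1) for g in groups], axis=1)  # G x k
    grand = (means * ns).sum(axis=1) / N
    ssb = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.stack(
        [((g - m[:, None]) ** 2).sum(axis=1) for g, m in zip(groups, means.T)],
        axis=1,
    ).sum(axis=1)
    dfb, dfw = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ssw > 0, (ssb / dfb) / np.where(ssw > 0, ssw / dfw, 1.0), 0.0)
    degenerate = (ssw == 0) & (ssb > 0)
    null_flat = (ssw == 0) & (ssb == 0)
    F = np.where(degenerate, np.inf, F)
    p = stats.f.sf(F, dfb, dfw)
    p = np.where(null_flat, 1.0, p)
    p = np.where(degenerate, TINY_P, p)
    return F, np.clip(p, 0.0, 1.0), degenerate


def bh_correct(pvalues, fdr: float = 0.05):
    """Benjamini-Hochberg step-up: returns ``(qvalues, reject)``.

    NaN p-values are excluded from the correction and stay NaN / False.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        rej, qv, _, _ = multipletests(p[ok], alpha=fdr, method="fdr_bh")
        q[ok] = qv
        reject[ok] = rej
    return q, reject


def signed_z_from_p(p, sign):
    """Signed normal quantile of a two-tailed p: ``sign x |Phi^-1(p/2)|``."""
    p = np.clip(np.asarray(p, dtype=float), TINY_P, 1.0)
    magnitude = np.abs(special.ndtri(p / 2.0))
    return np.sign(sign) * magnitude


def two_proportion_z(count1, total1, count2, total2):
    """Two-proportion z-test on (optionally weighted) counts.

    ``z = (p1 - p2) / sqrt(phat (1 - phat) (1/w1 + 1/w2))`` with
    ``phat`` the pooled proportion; totals act as effective sample sizes,
    so fractional weighted counts are accepted. Returns ``(z, p)`` with a
    two-sided normal p; degenerate inputs (zero pooled variance or an
    empty side) give z = 0, p = 1.
    """
    c1, w1 = float(count1), float(total1)
    c2, w2 = float(count2), float(total2)
    if w1 <= 0 or w2 <= 0:
        return 0.0, 1.0
    p1, p2 = c1 / w1, c2 / w2
    phat = (c1 + c2) / (w1 + w2)
    var = phat * (1.0 - phat) * (1.0 / w1 + 1.0 / w2)
    if var <= 0:
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
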