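"""Scalar statistics on localization data, implemented from first principles.

Pearson correlation (with the t-distributed p-value), Student's t-tests
(paired and pooled-variance two-sample, Welch by flag) and one-way ANOVA with
Holm-Sidak-adjusted pairwise comparisons are computed directly from their
textbook formulas; only the reference distributions (t, F) come from scipy.
Correlations on localization data are always taken on log10 values, matching
the double-log axes the quantities are reported on.  All p-values are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as st

from .errors import DegenerateInputError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    n: int
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError("non-finite values in input")
    return x


def pearson_correlation(x, y) -> TestResult:
    """Product-moment correlation with two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x, y = _clean(x), _clean(y)
    n = x.size
    if n != y.size or n < 3:
        raise DegenerateInputError("need two equal-length vectors with n >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    sxx, syy = float(xc @ xc), float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateInputError("zero variance in x or y")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    r = min(1.0, max(-1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(st.t.sf(abs(t), df))
    return TestResult(statistic=r, degrees_of_freedom=df, p_value=p, n=n)


def t_test(a, b, paired: bool = False, welch: bool = False) -> TestResult:
    """Student's t-test, two-sided.

    Paired: one-sample t on the differences.  Two-sample: pooled-variance
    Student statistic by default; ``welch=True`` switches to the
    unequal-variance form with Welch-Satterthwaite degrees of freedom.
    """
    a, b = _clean(a), _clean(b)
    if paired:
        if a.size != b.size:
            raise DegenerateInputError("paired test needs equal lengths")
        d = a - b
        n = d.size
        if n < 2:
            raise DegenerateInputError("need n >= 2 pairs")
        sd = d.std(ddof=1)
        if sd == 0.0:
            if np.allclose(d, 0.0):
                return TestResult(statistic=0.0, degrees_of_freedom=n - 1,
                                  p_value=1.0, n=n)
            raise DegenerateInputError("constant nonzero differences (sd = 0)")
        t = d.mean() / (sd / np.sqrt(n))
        df = n - 1
    else:
        na, nb = a.size, b.size
        if na < 2 or nb < 2:
            raise DegenerateInputError("each group needs n >= 2")
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if welch:
            se2 = va / na + vb / nb
            if se2 == 0.0:
                if a.mean() == b.mean():
                    return TestResult(statistic=0.0, degrees_of_freedom=na + nb - 2,
                                      p_value=1.0, n=na + nb)
                raise DegenerateInputError("zero variance in both groups")
            t = (a.mean() - b.mean()) / np.sqrt(se2)
            df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            if pooled == 0.0:
                if a.mean() == b.mean():
                    return TestResult(statistic=0.0, degrees_of_freedom=na + nb - 2,
                                      p_value=1.0, n=na + nb)
                raise DegenerateInputError("zero pooled variance")
            t = (a.mean() - b.mean()) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
            df = na + nb - 2
        n = na + nb
    p = 2.0 * float(st.t.sf(abs(t), df))
    return TestResult(statistic=float(t), degrees_of_freedom=float(df),
                      p_value=min(p, 1.0), n=int(n))


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    Ordered raw p's p(1) <= ... <= p(m) get adjusted(i) = 1 - (1 - p(i))^(m-i+1),
    enforced monotone nondecreasing along the ordering.
    """
    p = _clean(p_values)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def anova_holm_sidak(groups) -> tuple[TestResult, list[tuple[int, int, TestResult]]]:
    """One-way ANOVA plus Holm-Sidak-adjusted pairwise Student's t-tests.

    Returns the omnibus F result and, for every group pair (i, j), a
    TestResult whose ``adjusted_p`` carries the Holm-Sidak value across all
    m = g(g-1)/2 comparisons.
    """
    gs = [_clean(g) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise DegenerateInputError("need >= 2 groups with n >= 2 each")
    if all(g.var(ddof=1) == 0.0 for g in gs) and len({g.mean() for g in gs}) == 1:
        raise DegenerateInputError("all groups identical constants")
    n_tot = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in gs)
    df_b, df_w = len(gs) - 1, n_tot - len(gs)
    if ss_within == 0.0:
        raise DegenerateInputError("zero within-group variance")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(st.f.sf(f, df_b, df_w))
    omnibus = TestResult(statistic=float(f), degrees_of_freedom=float(df_b),
                         p_value=p, n=n_tot)

    pairs = [(i, j) for i in range(len(gs)) for j in range(i + 1, len(gs))]
    raw = [t_test(gs[i], gs[j]) for i, j in pairs]
    adj = holm_sidak([r.p_value for r in raw])
    pairwise = [(i, j, TestResult(statistic=r.statistic,
                                  degrees_of_freedom=r.degrees_of_freedom,
                                  p_value=r.p_value, n=r.n,
                                  adjusted_p=float(a)))
                for (i, j), r, a in zip(pairs, raw, adj)]
    return omnibus, pairwise
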