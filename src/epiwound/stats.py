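"""Classical group statistics used by the figure-style reports.

The tests are written out from their standard definitions — pooled
two-sample t, one-way fixed-effects ANOVA, and Tukey's honestly
significant difference on the studentized range — with p-values taken
from the corresponding scipy.stats distributions. The experimental unit
throughout is the animal-level (or wound-level) datapoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TestResult",
    "PairwiseResult",
    "summarize",
    "unpaired_t_test",
    "one_way_anova",
    "tukey_hsd",
    "holm_adjust",
]


@dataclass(frozen=True)
class GroupSample:
    """A labelled sample of independent per-animal (or per-wound) values."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.isfinite(v).all():
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def var(self) -> float:
        """Sample variance (n - 1 denominator)."""
        return float(self.values.var(ddof=1)) if self.n > 1 else math.nan


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    method: str

    def __post_init__(self) -> None:
        if not (math.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")


__all__.append("tukey_critical_q")


@dataclass(frozen=True)
class PairwiseResult:
    label_a: str
    label_b: str
    diff: float
    q: float
    p_adj: float
    method: str = "tukey-hsd"


def summarize(group: GroupSample) -> tuple[float, float, int]:
    """(mean, SEM, n) with SEM = sd/sqrt(n); SEM is NaN at n = 1."""
    if group.n == 1:
        return group.mean, math.nan, 1
    sem = math.sqrt(group.var / group.n)
    return group.mean, sem, group.n


def unpaired_t_test(
    x: GroupSample, y: GroupSample, equal_variance: bool = True
) -> TestResult:
    """Unpaired two-tailed t test.

    Defaults to the pooled-variance Student form; ``equal_variance=False``
    gives Welch's test with Satterthwaite degrees of freedom. Two groups
    with zero variance and equal means return t = 0, p = 1 rather than
    0/0.
    """
    if x.n < 2 or y.n < 2:
        raise ValueError("each group needs n >= 2")
    dmean = x.mean - y.mean
    if equal_variance:
        df = x.n + y.n - 2
        sp2 = ((x.n - 1) * x.var + (y.n - 1) * y.var) / df
        se = math.sqrt(sp2 * (1.0 / x.n + 1.0 / y.n))
        method = "student-t"
    else:
        vx, vy = x.var / x.n, y.var / y.n
        se = math.sqrt(vx + vy)
        if se > 0:
            df = (vx + vy) ** 2 / (
                vx ** 2 / (x.n - 1) + vy ** 2 / (y.n - 1)
            )
        else:
            df = x.n + y.n - 2
        method = "welch-t"
    if se == 0.0:
        if dmean == 0.0:
            return TestResult(0.0, df, 1.0, method)
        return TestResult(math.copysign(math.inf, dmean), df, 0.0, method)
    t = dmean / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(t, df, min(p, 1.0), method)


def _anova_sums(groups: Sequence[GroupSample]) -> tuple[float, float, int, int]:
    k = len(groups)
    all_vals = np.concatenate([g.values for g in groups])
    grand = all_vals.mean()
    n_total = all_vals.size
    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ss_within = sum(float(((g.values - g.mean) ** 2).sum()) for g in groups)
    return ss_between, ss_within, k, n_total


def one_way_anova(groups: Sequence[GroupSample]) -> TestResult:
    """Ordinary (fixed-effects) one-way ANOVA.

    F = MS_between / MS_within on (k - 1, N - k) degrees of freedom.
    All values identical gives F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.n < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    ss_b, ss_w, k, n_total = _anova_sums(groups)
    df_b, df_w = k - 1, n_total - k
    if ss_w == 0.0:
        if ss_b == 0.0:
            return TestResult(0.0, (df_b, df_w), 1.0, "one-way-anova")
        return TestResult(math.inf, (df_b, df_w), 0.0, "one-way-anova")
    f = (ss_b / df_b) / (ss_w / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(f, (df_b, df_w), p, "one-way-anova")


def tukey_hsd(
    groups: Sequence[GroupSample], compute_p: bool = True
) -> list[PairwiseResult]:
    """Tukey's HSD over all group pairs.

    Uses the Tukey–Kramer statistic
    ``q = |m_i - m_j| / sqrt(MS_w/2 * (1/n_i + 1/n_j))`` and the
    studentized range distribution with k groups and N - k error
    degrees of freedom, which controls the family-wise error rate at
    the nominal level for all pairwise mean comparisons.
    ``compute_p=False`` skips the (numerically expensive) distribution
    evaluation and reports only q — rejection can then be decided
    against :func:`tukey_critical_q`, e.g. inside simulations.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.n < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    _, ss_w, k, n_total = _anova_sums(groups)
    df_w = n_total - k
    ms_w = ss_w / df_w
    out: list[PairwiseResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            diff = a.mean - b.mean
            se = math.sqrt(ms_w / 2.0 * (1.0 / a.n + 1.0 / b.n))
            if se == 0.0:
                q = 0.0 if diff == 0.0 else math.inf
                p = 1.0 if diff == 0.0 else 0.0
            elif compute_p:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_w))
            else:
                q = abs(diff) / se
                p = math.nan
            out.append(PairwiseResult(a.label, b.label, diff, q, min(max(p, 0.0), 1.0)))
    return out


def tukey_critical_q(alpha: float, k: int, df: float) -> float:
    """Critical studentized-range value q_{alpha; k, df}."""
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m, dtype=float)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
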