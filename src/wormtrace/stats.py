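"""Group-comparison decision tree with star labeling.

Pairwise comparisons: samples that pass a normality gate (Anderson-Darling
and Shapiro-Wilk both non-rejecting at alpha = 0.05, or n > 30) are compared
with an unpaired two-tailed Student t test, switching to the Welch variant
when a two-sided F-ratio test rejects variance homogeneity; otherwise a
two-sided Mann-Whitney test is used.  Multi-group comparisons run a one-way
ANOVA with Bonferroni-corrected pairwise t tests when every group passes the
gate, else Kruskal-Wallis followed by Dunn's tie-corrected z comparisons
with Bonferroni adjustment.  Every result records the decision path taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatSample",
    "NormalityResult",
    "TestResult",
    "normality_gate",
    "variance_homogeneity",
    "compare_two",
    "compare_many",
    "dunn_posthoc",
    "star_label",
]

ALPHA = 0.05
N_SHORTCUT = 30  # above this, the gate passes regardless of test outcomes

_STAR_MAP = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class StatSample:
    values: np.ndarray
    group: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 3:
            raise ValueError("a sample needs at least 3 one-dimensional values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class NormalityResult:
    normal: bool
    n: int
    shortcut_used: bool
    shapiro_p: float
    anderson_stat: float
    anderson_crit_5pct: float
    degenerate: bool = False


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    correction: str = "none"
    stars: str = ""
    groups: tuple[str, ...] = ()
    decision_path: dict = field(default_factory=dict)


def star_label(p: float) -> str:
    """Map a p-value to the conventional significance stars.

    ns for p > 0.05; then *, **, ***, **** at 0.05, 0.01, 0.001, 0.0001
    (most extreme applicable threshold)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    for thr, stars in _STAR_MAP:
        if p <= thr:
            return stars
    return "ns"


def _as_sample(x) -> StatSample:
    return x if isinstance(x, StatSample) else StatSample(np.asarray(x))


def _anderson_norm(x) -> tuple[float, float]:
    """Anderson-Darling statistic and its 5% critical value.

    Uses the legacy critical-value interface; the comparison against the
    tabulated 5% value is the decision we document, so silence the scipy
    deprecation chatter about choosing a p-value method.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        ad = sps.anderson(x, dist="norm")
    crit5 = float(ad.critical_values[list(ad.significance_level).index(5.0)])
    return float(ad.statistic), crit5


def normality_gate(sample, alpha: float = ALPHA) -> NormalityResult:
    """Decide whether a sample may be treated as normal.

    Passes when n > 30 (large-sample shortcut) or when neither the
    Anderson-Darling nor the Shapiro-Wilk test rejects at `alpha`; a
    constant sample is flagged degenerate and treated as non-normal.
    """
    s = _as_sample(sample)
    x = s.values
    if np.ptp(x) == 0:
        return NormalityResult(False, s.n, False, float("nan"), float("nan"),
                               float("nan"), degenerate=True)
    if s.n > N_SHORTCUT:
        # still report the sub-statistics for the audit trail
        sh_p = float(sps.shapiro(x).pvalue)
        ad_stat, crit5 = _anderson_norm(x)
        return NormalityResult(True, s.n, True, sh_p, ad_stat, crit5)
    sh_p = float(sps.shapiro(x).pvalue)
    ad_stat, crit5 = _anderson_norm(x)
    normal = (sh_p > alpha) and (ad_stat <= crit5)
    return NormalityResult(normal, s.n, False, sh_p, ad_stat, crit5)


def variance_homogeneity(a, b, alpha: float = ALPHA) -> tuple[bool, float, float]:
    """Two-sided F-ratio test of equal variances.

    Returns (homogeneous, F, p).  F uses the first sample's variance in the
    numerator; the two-sided p doubles the smaller tail.
    """
    xa, xb = _as_sample(a).values, _as_sample(b).values
    va, vb = np.var(xa, ddof=1), np.var(xb, ddof=1)
    if va == 0 and vb == 0:
        return True, 1.0, 1.0
    if vb == 0 or va == 0:
        return False, float("inf"), 0.0
    F = va / vb
    dfn, dfd = len(xa) - 1, len(xb) - 1
    p = 2.0 * min(sps.f.cdf(F, dfn, dfd), sps.f.sf(F, dfn, dfd))
    p = min(p, 1.0)
    return p > alpha, float(F), float(p)


def compare_two(a, b, alpha: float = ALPHA) -> TestResult:
    """Pairwise comparison following the normality-gated decision tree."""
    sa, sb = _as_sample(a), _as_sample(b)
    ga, gb = normality_gate(sa, alpha), normality_gate(sb, alpha)
    path = {
        "normal_a": ga.normal, "normal_b": gb.normal,
        "shortcut_a": ga.shortcut_used, "shortcut_b": gb.shortcut_used,
    }
    if ga.normal and gb.normal:
        hom, F, p_f = variance_homogeneity(sa, sb, alpha)
        path.update(variance_homogeneous=hom, f_ratio=F, f_p=p_f)
        res = sps.ttest_ind(sa.values, sb.values, equal_var=hom)
        name = "student_t" if hom else "welch_t"
    else:
        res = sps.mannwhitneyu(sa.values, sb.values, alternative="two-sided")
        name = "mann_whitney"
    path["test"] = name
    p = float(res.pvalue)
    return TestResult(test=name, statistic=float(res.statistic), p_value=p,
                      stars=star_label(p), groups=(sa.group, sb.group),
                      decision_path=path)


def _rank_with_ties(pooled: np.ndarray):
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    return ranks, tie_sum


def dunn_posthoc(groups: list[np.ndarray], labels: list[str],
                 alpha: float = ALPHA) -> list[TestResult]:
    """Dunn's pairwise z comparisons on pooled ranks with tie correction,
    Bonferroni-adjusted over all pairs."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks, tie_sum = _rank_with_ties(pooled)
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
        out.append(TestResult(
            test="dunn_z", statistic=float(z), p_value=p,
            correction="bonferroni", stars=star_label(p),
            groups=(labels[i], labels[j]),
            decision_path={"mean_rank_i": mean_ranks[i],
                           "mean_rank_j": mean_ranks[j],
                           "tie_correction": tie_sum > 0},
        ))
    return out


def compare_many(groups, labels: list[str] | None = None,
                 alpha: float = ALPHA) -> tuple[TestResult, list[TestResult]]:
    """Omnibus plus pairwise comparisons for three or more groups.

    All groups normal (by the gate) -> one-way ANOVA with Bonferroni-
    corrected pairwise t tests; otherwise Kruskal-Wallis followed by Dunn's
    comparisons.
    """
    samples = [_as_sample(g) for g in groups]
    if len(samples) < 3:
        raise ValueError("compare_many needs at least 3 groups")
    labels = labels or [s.group or f"g{i}" for i, s in enumerate(samples)]
    gates = [normality_gate(s, alpha) for s in samples]
    all_normal = all(g.normal for g in gates)
    arrays = [s.values for s in samples]
    m = len(samples) * (len(samples) - 1) // 2
    if all_normal:
        F, p = sps.f_oneway(*arrays)
        omnibus = TestResult(test="anova_oneway", statistic=float(F),
                             p_value=float(p), stars=star_label(float(p)),
                             groups=tuple(labels),
                             decision_path={"all_normal": True})
        pairwise = []
        for i, j in combinations(range(len(samples)), 2):
            res = sps.ttest_ind(arrays[i], arrays[j], equal_var=True)
            padj = min(1.0, float(res.pvalue) * m)
            pairwise.append(TestResult(
                test="student_t", statistic=float(res.statistic),
                p_value=padj, correction="bonferroni", stars=star_label(padj),
                groups=(labels[i], labels[j]),
                decision_path={"raw_p": float(res.pvalue)},
            ))
    else:
        H, p = sps.kruskal(*arrays)
        omnibus = TestResult(test="kruskal_wallis", statistic=float(H),
                             p_value=float(p), stars=star_label(float(p)),
                             groups=tuple(labels),
                             decision_path={"all_normal": False})
        pairwise = dunn_posthoc(arrays, labels, alpha)
    return omnibus, pairwise
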