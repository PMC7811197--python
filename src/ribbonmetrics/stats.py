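"""Small-sample statistical comparison protocol.

Morphometric samples here are tiny (n of 3 to 45), so the nonparametric
tests are computed exactly: the Mann-Whitney two-sided p-value by complete
enumeration of group assignments, and the one-sample Wilcoxon signed-rank
p-value from the exact null distribution of the signed-rank sum.  With
complete separation of samples of sizes 3 and 23 the exact Mann-Whitney
p is 2 / C(26, 3) = 2/2600, which prints as 0.0008 — a value the normal
approximation cannot reproduce.

``compare_groups`` implements the dispatch protocol used for the
measurement tables: a Shapiro-Wilk normality gate and an equal-SD gate
choose between parametric (t / Welch t / ANOVA + Tukey) and nonparametric
(exact Mann-Whitney / Kruskal-Wallis + Dunn) paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["SampleSet", "TestResult", "exact_mann_whitney",
           "one_sample_wilcoxon", "compare_groups", "dunn_posthoc"]

#: largest min(n1, n2) for which Mann-Whitney assignments are enumerated
EXACT_MW_LIMIT = 10
#: largest n for which Wilcoxon sign patterns are enumerated (via DP)
EXACT_WILCOXON_LIMIT = 25
#: per-group Shapiro-Wilk alpha for the normality gate
NORMALITY_ALPHA = 0.05
#: SD ratio beyond which the equal-variance assumption is dropped
SD_RATIO_LIMIT = 2.0


class StatsError(ValueError):
    pass


@dataclass
class SampleSet:
    """A labelled group of measurements."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise StatsError(f"sample {self.label!r} is empty")
        if np.any(~np.isfinite(self.values)):
            raise StatsError(f"sample {self.label!r} contains missing values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_two_tailed: float
    exact: bool = True
    adjusted: bool = False
    adjustment: Optional[str] = None
    groups: tuple[str, ...] = ()
    note: str = ""
    posthoc: list["TestResult"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise StatsError(f"p-value outside [0, 1]: {self.p_two_tailed}")


def _rank_midrank(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def exact_mann_whitney(x: SampleSet, y: SampleSet) -> TestResult:
    """Two-sided Mann-Whitney test, exact by enumeration for small samples.

    Ranks use mid-ranks for ties; the null distribution is obtained by
    enumerating all C(n1+n2, n1) assignments of the observed values to
    the two groups (feasible for min(n) <= 10), so ties are handled by
    permuting the data as observed.  The two-sided p-value is the null
    probability of a rank-sum at least as far from its mean as observed.
    Larger samples fall back to the tie-corrected normal approximation
    and are flagged ``exact=False``.
    """
    n1, n2 = x.n, y.n
    combined = np.concatenate([x.values, y.values])
    ranks = _rank_midrank(combined)
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0
    u_obs = w_obs - n1 * (n1 + 1) / 2.0

    if min(n1, n2) <= EXACT_MW_LIMIT:
        # enumerate over the smaller group for speed; the rank-sum of the
        # other group is determined by the total, so extremeness matches
        small = min(n1, n2)
        total = ranks.sum()
        d_obs = abs(w_obs - mu) if n1 <= n2 else abs((total - w_obs) - (n2 * (n1 + n2 + 1) / 2.0))
        mu_small = small * (n1 + n2 + 1) / 2.0
        count = 0
        n_comb = 0
        for subset in combinations(range(n1 + n2), small):
            w = ranks[list(subset)].sum()
            n_comb += 1
            if abs(w - mu_small) >= d_obs - 1e-9:
                count += 1
        p = count / n_comb
        return TestResult(method="mann_whitney_exact", statistic=u_obs,
                          p_two_tailed=min(1.0, p), exact=True,
                          groups=(x.label, y.label))
    res = sps.mannwhitneyu(x.values, y.values, alternative="two-sided",
                           method="asymptotic")
    return TestResult(method="mann_whitney_normal_approx",
                      statistic=float(res.statistic),
                      p_two_tailed=float(res.pvalue), exact=False,
                      groups=(x.label, y.label),
                      note=f"min(n) > {EXACT_MW_LIMIT}; normal approximation")


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact null counts of 2*W+ over all sign patterns (DP convolution).

    Ranks are doubled so mid-ranks become integers.
    """
    scaled = np.round(2 * ranks).astype(int)
    total = int(scaled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled:
        nxt = counts.copy()
        nxt[r:] += counts[: len(counts) - r]
        counts = nxt
    return counts, total


def one_sample_wilcoxon(x: SampleSet, mu0: float) -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu0``.

    Zero differences are dropped (the classical convention); mid-ranks
    handle tied absolute differences, and the exact two-sided p-value is
    computed from the full null distribution of the signed-rank sum for
    n <= 25.  If every value equals ``mu0`` the test is degenerate and
    p = 1.0 is returned with a note.
    """
    d = x.values - mu0
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(method="wilcoxon_signed_rank", statistic=0.0,
                          p_two_tailed=1.0, exact=True, groups=(x.label,),
                          note="all values equal mu0; test degenerate")
    ranks = _rank_midrank(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    if n <= EXACT_WILCOXON_LIMIT:
        counts, tot2 = _signed_rank_distribution(ranks)
        w2 = 2 * w_plus
        center = tot2 / 2.0
        dev = abs(w2 - center)
        idx = np.arange(tot2 + 1)
        p = counts[np.abs(idx - center) >= dev - 1e-9].sum() / counts.sum()
        return TestResult(method="wilcoxon_signed_rank_exact",
                          statistic=w_plus, p_two_tailed=min(1.0, float(p)),
                          exact=True, groups=(x.label,))
    mu = total / 2.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w_plus - mu) / sigma
    p = 2 * sps.norm.sf(abs(z))
    return TestResult(method="wilcoxon_signed_rank_normal_approx",
                      statistic=w_plus, p_two_tailed=float(min(1.0, p)),
                      exact=False, groups=(x.label,),
                      note=f"n > {EXACT_WILCOXON_LIMIT}; normal approximation")


def _groups_normal(groups: Sequence[SampleSet]) -> bool:
    """Shapiro-Wilk gate: every group consistent with normality at alpha.

    Groups too small for the test (n < 3) or constant are treated as
    non-normal, steering the dispatcher to the nonparametric path.
    """
    for g in groups:
        if g.n < 3 or np.ptp(g.values) == 0:
            return False
        if sps.shapiro(g.values).pvalue < NORMALITY_ALPHA:
            return False
    return True


def _equal_sds(groups: Sequence[SampleSet]) -> bool:
    sds = [float(np.std(g.values, ddof=1)) for g in groups]
    lo, hi = min(sds), max(sds)
    if hi == 0:
        return True
    if lo == 0:
        return False
    return hi / lo <= SD_RATIO_LIMIT


def dunn_posthoc(groups: Sequence[SampleSet]) -> list[TestResult]:
    """Dunn's rank-based pairwise comparisons with Bonferroni adjustment."""
    all_vals = np.concatenate([g.values for g in groups])
    N = all_vals.size
    ranks = _rank_midrank(all_vals)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start:start + g.n].mean()))
        start += g.n
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for (i, gi), (j, gj) in combinations(enumerate(groups), 2):
        se = math.sqrt(var_base * (1.0 / gi.n + 1.0 / gj.n))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2 * sps.norm.sf(abs(z))
        out.append(TestResult(
            method="dunn", statistic=float(z),
            p_two_tailed=float(min(1.0, p_raw * m)),
            exact=False, adjusted=True, adjustment="bonferroni",
            groups=(gi.label, gj.label),
        ))
    return out


def compare_groups(groups: Sequence[SampleSet], design: str = "auto") -> TestResult:
    """Normality-gated dispatcher over two or more groups.

    Two samples: normal + equal SDs -> unpaired t; normal + unequal SDs
    (ratio > 2) -> Welch t; otherwise exact Mann-Whitney.  Three or more:
    normal + equal SDs -> one-way ANOVA with Tukey HSD post hoc;
    otherwise Kruskal-Wallis with Dunn/Bonferroni post hoc.  The result
    names the chosen path; post-hoc results carry adjusted p-values.
    """
    if len(groups) < 2:
        raise StatsError("compare_groups needs at least two groups")
    if design == "two_sample" and len(groups) != 2:
        raise StatsError("two_sample design requires exactly two groups")
    if design == "k_sample" and len(groups) < 3:
        raise StatsError("k_sample design requires at least three groups")

    labels = tuple(g.label for g in groups)
    normal = _groups_normal(groups)
    if normal:
        for g in groups:
            if g.n < 2:
                raise StatsError(
                    f"group {g.label!r} has n < 2; variance undefined"
                )

    if len(groups) == 2:
        x, y = groups
        if normal:
            equal = _equal_sds(groups)
            res = sps.ttest_ind(x.values, y.values, equal_var=equal)
            return TestResult(
                method="t_test" if equal else "welch_t_test",
                statistic=float(res.statistic),
                p_two_tailed=float(res.pvalue), exact=False, groups=labels,
            )
        return exact_mann_whitney(x, y)

    if normal and _equal_sds(groups):
        res = sps.f_oneway(*[g.values for g in groups])
        tk = sps.tukey_hsd(*[g.values for g in groups])
        posthoc = [
            TestResult(method="tukey_hsd", statistic=float(tk.statistic[i, j]),
                       p_two_tailed=float(tk.pvalue[i, j]), exact=False,
                       adjusted=True, adjustment="tukey",
                       groups=(groups[i].label, groups[j].label))
            for i, j in combinations(range(len(groups)), 2)
        ]
        return TestResult(method="anova", statistic=float(res.statistic),
                          p_two_tailed=float(res.pvalue), exact=False,
                          groups=labels, posthoc=posthoc)
    try:
        res = sps.kruskal(*[g.values for g in groups])
        stat, p = float(res.statistic), float(res.pvalue)
    except ValueError:  # all values identical across groups
        stat, p = 0.0, 1.0
    return TestResult(method="kruskal_wallis", statistic=stat,
                      p_two_tailed=p, exact=False, groups=labels,
                      posthoc=dunn_posthoc(groups))
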