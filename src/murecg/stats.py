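"""Group comparison pipeline for derived cardiac parameters.

Mirrors the conventional small-animal EP statistics workflow: per-group
D'Agostino-Pearson normality gate at alpha = 0.05, two-sided Student's
t-test when both groups pass (Mann-Whitney otherwise), one-way ANOVA with
Tukey's HSD for three groups, and Pearson chi-square (no continuity
correction, the common Prism default) for prevalence/inducibility tables.
Values are summarized as mean +/- s.e.m.

The normality test needs n >= 8; smaller groups fall back to Mann-Whitney
(conservative).  No correction is applied across the many parameters
compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError

ALPHA = 0.05
NORMALITY_MIN_N = 8


@dataclass
class GroupSample:
    group: str
    values: np.ndarray
    parameter: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("group values must be finite")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class ComparisonResult:
    test_used: str
    statistic: float
    p_value: float
    pairwise: list[dict] = field(default_factory=list)
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def summarize(sample: GroupSample) -> dict:
    """mean, s.e.m. (sample SD / sqrt(n)), median and n for one group."""
    v = sample.values
    if len(v) < 1:
        raise InsufficientDataError("empty sample")
    sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
    return {"group": sample.group, "parameter": sample.parameter,
            "mean": float(np.mean(v)), "sem": sem,
            "median": float(np.median(v)), "n": len(v)}


def _passes_normality(values: np.ndarray) -> bool:
    if len(values) < NORMALITY_MIN_N:
        return False
    return sps.normaltest(values).pvalue >= ALPHA


def compare_two(a: GroupSample, b: GroupSample) -> ComparisonResult:
    """Normality-gated two-group comparison.

    Both groups pass D'Agostino-Pearson (p >= 0.05) -> two-sided Student's
    t-test; otherwise (including groups too small for the normality test)
    two-sided Mann-Whitney.
    """
    for g in (a, b):
        if g.n < 3:
            raise InsufficientDataError(
                f"group {g.group!r} has n={g.n} < 3; not evaluable")
    if _passes_normality(a.values) and _passes_normality(b.values):
        res = sps.ttest_ind(a.values, b.values)
        return ComparisonResult(test_used="t", statistic=float(res.statistic),
                                p_value=float(res.pvalue))
    res = sps.mannwhitneyu(a.values, b.values, alternative="two-sided")
    return ComparisonResult(test_used="mann_whitney",
                            statistic=float(res.statistic),
                            p_value=float(res.pvalue))


def compare_three(groups: list[GroupSample],
                  include_pairwise: bool = True) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``include_pairwise=False`` skips the (comparatively expensive)
    studentized-range integrals when only the omnibus F is needed.
    """
    if len(groups) != 3:
        raise ValueError("compare_three expects exactly three groups")
    for g in groups:
        if g.n < 3:
            raise InsufficientDataError(
                f"group {g.group!r} has n={g.n} < 3; not evaluable")
    arrays = [g.values for g in groups]
    if all(np.ptp(v) == 0 for v in arrays) and len({v[0] for v in arrays}) == 1:
        raise InsufficientDataError("all values identical; variance degenerate")
    f, p = sps.f_oneway(*arrays)
    pairwise = []
    if include_pairwise:
        tukey = sps.tukey_hsd(*arrays)
        for i in range(3):
            for j in range(i + 1, 3):
                pairwise.append({"pair": (groups[i].group, groups[j].group),
                                 "adjusted_p": float(tukey.pvalue[i, j])})
    return ComparisonResult(test_used="anova_tukey", statistic=float(f),
                            p_value=float(p), pairwise=pairwise)


def compare_proportions(flagged: list[int], totals: list[int],
                        yates: bool = False) -> ComparisonResult:
    """Pearson chi-square on the k x 2 flagged/unflagged table."""
    if len(flagged) != len(totals) or len(flagged) < 2:
        raise ValueError("need flagged and total counts for >= 2 groups")
    if any(t < 1 for t in totals):
        raise InsufficientDataError("zero-total group in contingency table")
    table = np.array([[f, t - f] for f, t in zip(flagged, totals)])
    if np.any(table.sum(axis=0) == 0):
        raise InsufficientDataError(
            "degenerate contingency table: a column total is zero")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=yates)
    return ComparisonResult(test_used="chi_square", statistic=float(chi2),
                            p_value=float(p))


def significance_stars(p: float) -> str:
    """Figure-caption style star coding at <0.05/<0.01/<0.001/<0.0001."""
    for thresh, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"),
                          (0.05, "*")):
        if p < thresh:
            return stars
    return "ns"
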