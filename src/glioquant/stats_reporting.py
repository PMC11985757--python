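"""Normality-gated statistical dispatch and descriptive summaries.

Every grouped comparison in the pipeline goes through the same rule: each
group is tested for normality with the Shapiro-Wilk test at alpha = 0.05.
If every group passes, data are described as mean +- SEM and compared with
an unpaired t-test (two groups) or one-way ANOVA with Holm-Sidak post-hoc
pairwise comparisons (more than two).  Otherwise data are described as
median +- SEM and compared with the Mann-Whitney U test or Kruskal-Wallis
with Dunn's post-hoc test.  p < 0.05 is considered significant.

The SEM (sample standard deviation / sqrt(n)) accompanies the median as
well as the mean — unusual, but it is the pipeline's fixed reporting
convention; a bootstrap median CI is available as a clearly labelled
extra (:func:`bootstrap_median_ci`).

Dunn's test is implemented here directly (rank-sum z approximation with
tie correction); the pairwise p-values are family-corrected Sidak-style
by default, matching the "corrected for multiple comparisons" convention
of common statistics packages (``p_adjust`` is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA_NORMALITY = 0.05
ALPHA_SIGNIFICANCE = 0.05


@dataclass(frozen=True)
class GroupedMeasurements:
    """Named groups of one measured quantity."""

    groups: list[tuple[str, list[float]]]
    measure: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")

    def arrays(self) -> list[np.ndarray]:
        return [np.asarray(v, dtype=float) for _, v in self.groups]

    def labels(self) -> list[str]:
        return [lab for lab, _ in self.groups]


@dataclass(frozen=True)
class Descriptive:
    label: str
    center: float
    sem: float
    n: int
    center_type: str  # "mean" | "median"

    def __str__(self) -> str:
        return f"{self.label}: {self.center_type} {self.center:g} ± {self.sem:g} (n={self.n})"


@dataclass(frozen=True)
class TestReport:
    """Outcome of one grouped comparison."""

    test_name: str
    p_value: float
    normal: bool
    descriptives: list[Descriptive]
    posthoc: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA_SIGNIFICANCE

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def summary(self) -> str:
        lines = [f"{self.test_name}: p = {self.p_value:.4g} {self.stars or 'ns'}"]
        lines += [f"  {d}" for d in self.descriptives]
        if self.posthoc is not None:
            lines.append("  post-hoc pairwise p-values:")
            lines.append("    " + self.posthoc.to_string().replace("\n", "\n    "))
        return "\n".join(lines)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def describe(values, center: str = "mean") -> Descriptive:
    """Center +- SEM for one group; SEM = sd / sqrt(n) for either center."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot describe an empty group")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    c = float(np.mean(v)) if center == "mean" else float(np.median(v))
    sem = 0.0 if v.size == 1 else float(np.std(v, ddof=1) / np.sqrt(v.size))
    return Descriptive("", c, sem, int(v.size), center)


def _holm_sidak_pairwise(arrays: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    pairs = list(combinations(range(len(arrays)), 2))
    raw = [stats.ttest_ind(arrays[i], arrays[j]).pvalue for i, j in pairs]
    adj = multipletests(raw, method="holm-sidak")[1]
    return _pairwise_frame(labels, pairs, adj)


def dunn_test(arrays: list[np.ndarray], labels: list[str], p_adjust: str = "sidak") -> pd.DataFrame:
    """Dunn's post-hoc test after Kruskal-Wallis.

    z statistic on mean ranks of the pooled sample with tie correction;
    two-sided normal p-values, family-corrected per ``p_adjust``
    ("sidak", "bonferroni", "holm" or "none").
    """
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        sizes.append(a.size)
        start += a.size

    pairs = list(combinations(range(len(arrays)), 2))
    raw = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw.append(2.0 * stats.norm.sf(abs(z)))
    m = len(pairs)
    raw = np.asarray(raw)
    if p_adjust == "sidak":
        adj = 1.0 - (1.0 - raw) ** m
    elif p_adjust == "bonferroni":
        adj = np.minimum(raw * m, 1.0)
    elif p_adjust == "holm":
        adj = multipletests(raw, method="holm")[1]
    elif p_adjust == "none":
        adj = raw
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    return _pairwise_frame(labels, pairs, np.minimum(adj, 1.0))


def _pairwise_frame(labels, pairs, pvals) -> pd.DataFrame:
    df = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for (i, j), p in zip(pairs, pvals):
        df.iloc[i, j] = df.iloc[j, i] = p
    return df


def dispatch_test(
    g: GroupedMeasurements,
    alpha_normality: float = ALPHA_NORMALITY,
    dunn_adjust: str = "sidak",
) -> TestReport:
    """Run the normality-gated comparison on >= 2 groups of >= 3 values.

    Parametric branch (all groups Shapiro-Wilk p > alpha): unpaired
    t-test / one-way ANOVA + Holm-Sidak, mean +- SEM.  Non-parametric
    branch: Mann-Whitney U / Kruskal-Wallis + Dunn, median +- SEM.
    """
    arrays = g.arrays()
    labels = g.labels()
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for lab, a in zip(labels, arrays):
        if a.size < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 values")

    normal = all(stats.shapiro(a).pvalue > alpha_normality for a in arrays)
    center = "mean" if normal else "median"
    descriptives = [
        Descriptive(lab, d.center, d.sem, d.n, d.center_type)
        for lab, d in ((lab, describe(a, center)) for lab, a in zip(labels, arrays))
    ]

    posthoc = None
    if normal:
        if len(arrays) == 2:
            name = "unpaired t-test"
            p = float(stats.ttest_ind(*arrays).pvalue)
        else:
            name = "one-way ANOVA + Holm-Sidak"
            p = float(stats.f_oneway(*arrays).pvalue)
            posthoc = _holm_sidak_pairwise(arrays, labels)
    else:
        if len(arrays) == 2:
            name = "Mann-Whitney U"
            p = float(stats.mannwhitneyu(*arrays, alternative="two-sided").pvalue)
        else:
            name = "Kruskal-Wallis + Dunn"
            p = float(stats.kruskal(*arrays).pvalue)
            posthoc = dunn_test(arrays, labels, p_adjust=dunn_adjust)
    return TestReport(name, p, normal, descriptives, posthoc)


def bootstrap_median_ci(
    values, n_boot: int = 2000, ci: float = 0.95, seed: int | None = None
) -> tuple[float, float]:
    """Percentile bootstrap CI for the median — an optional extra to the
    median +- SEM reporting convention."""
    rng = np.random.default_rng(seed)
    v = np.asarray(values, dtype=float)
    meds = np.median(rng.choice(v, size=(n_boot, v.size), replace=True), axis=1)
    lo = (1.0 - ci) / 2.0
    return tuple(np.quantile(meds, [lo, 1.0 - lo]))
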