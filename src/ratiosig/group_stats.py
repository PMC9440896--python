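"""Normality-gated group comparisons and the lipid-profile normalization.

The decision procedure: every group is screened with the Shapiro–Wilk
test; if all groups look normal (p > alpha) the parametric branch runs
(two-tailed Student's t for two groups, one-way ANOVA with protected
Fisher-LSD post hoc for three or more), otherwise the non-parametric
branch (two-sided Mann–Whitney U, Kruskal–Wallis).  No post hoc follows
Kruskal–Wallis: the omnibus stands alone.

Also here: min-max percent normalization of species-by-group mean
matrices for heatmaps — per species, the smallest group mean maps to 0%
and the largest to 100%.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import GroupedData

__all__ = [
    "TestReport",
    "normality_gate",
    "compare_two",
    "compare_many",
    "fisher_lsd",
    "minmax_percent",
]

logger = logging.getLogger(__name__)

#: switch Mann–Whitney from exact enumeration to the tie/continuity
#: corrected normal approximation above this per-group size
MANNWHITNEY_EXACT_MAX_N = 8


@dataclass
class TestReport:
    """Outcome of a gated comparison: gate p-values, branch, omnibus, post hoc."""

    gate_p: dict[str, float]
    branch: str  # "parametric" | "nonparametric"
    omnibus_name: str
    omnibus_statistic: float
    omnibus_p: float
    posthoc: list[tuple[tuple[str, str], float]] = field(default_factory=list)


def _check_groups(groups: GroupedData, min_n: int = 3) -> None:
    for label, values in groups.items():
        if len(values) < min_n:
            raise ValueError(
                f"group {label!r} has {len(values)} values; need >= {min_n}")


def normality_gate(groups: GroupedData, alpha: float = 0.05) -> tuple[str, dict[str, float]]:
    """Shapiro–Wilk screen of every group; parametric iff all pass.

    Returns ``(branch, per_group_p)``.  A constant group is an error (the
    test statistic is undefined at zero variance).
    """
    _check_groups(groups)
    gate_p: dict[str, float] = {}
    for label, values in groups.items():
        if np.ptp(values) == 0:
            raise ValueError(
                f"group {label!r} is constant; normality test undefined")
        gate_p[label] = float(stats.shapiro(values).pvalue)
    branch = "parametric" if all(p > alpha for p in gate_p.values()) else "nonparametric"
    for label, p in gate_p.items():
        logger.info("normality gate: group %s Shapiro-Wilk p=%.4g", label, p)
    logger.info("normality gate: %s branch at alpha=%g", branch, alpha)
    return branch, gate_p


def compare_two(groups: GroupedData, alpha: float = 0.05,
                welch: bool = False) -> TestReport:
    """Two-group comparison: Student's t or Mann–Whitney U, as gated.

    The parametric branch uses the classical equal-variance pooled t test
    (``welch=True`` switches to Welch).  The non-parametric branch uses the
    two-sided Mann–Whitney U: exact enumeration when both groups have at
    most 8 values and no ties, the tie/continuity corrected normal
    approximation otherwise.
    """
    if len(groups) != 2:
        raise ValueError(f"compare_two needs exactly 2 groups, got {len(groups)}")
    branch, gate_p = normality_gate(groups, alpha=alpha)
    (la, a), (lb, b) = groups.items()
    if branch == "parametric":
        res = stats.ttest_ind(a, b, equal_var=not welch)
        name = "Welch t" if welch else "Student t"
        return TestReport(gate_p, branch, name,
                          float(res.statistic), float(res.pvalue))
    pooled = np.concatenate([a, b])
    exact = (min(len(a), len(b)) <= MANNWHITNEY_EXACT_MAX_N
             and len(np.unique(pooled)) == len(pooled))
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return TestReport(gate_p, branch, "Mann-Whitney U",
                      float(res.statistic), float(res.pvalue))


def compare_many(groups: GroupedData, alpha: float = 0.05,
                 protected: bool = True) -> TestReport:
    """Multi-group comparison: one-way ANOVA + Fisher LSD, or Kruskal–Wallis.

    The parametric branch runs a one-way ANOVA; pairwise Fisher-LSD
    p-values follow for every pair, by default only when the omnibus is
    significant at ``alpha`` (protected LSD).  The non-parametric branch
    reports the tie-corrected Kruskal–Wallis omnibus only.
    """
    if len(groups) < 3:
        raise ValueError(
            f"compare_many needs >= 3 groups, got {len(groups)}; "
            "use compare_two for a two-group design")
    branch, gate_p = normality_gate(groups, alpha=alpha)
    arrays = list(groups.groups.values())
    labels = groups.labels
    if branch == "nonparametric":
        res = stats.kruskal(*arrays)
        return TestReport(gate_p, branch, "Kruskal-Wallis",
                          float(res.statistic), float(res.pvalue))
    res = stats.f_oneway(*arrays)
    report = TestReport(gate_p, branch, "one-way ANOVA",
                        float(res.statistic), float(res.pvalue))
    if protected and not (report.omnibus_p < alpha):
        return report
    means = {lab: float(np.mean(v)) for lab, v in groups.items()}
    sizes = {lab: len(v) for lab, v in groups.items()}
    ss_within = sum(float(np.sum((v - np.mean(v)) ** 2)) for v in arrays)
    df_error = sum(sizes.values()) - len(labels)
    mse = ss_within / df_error
    for pair in itertools.combinations(labels, 2):
        report.posthoc.append((pair, fisher_lsd(means, sizes, mse, df_error, pair)))
    return report


def fisher_lsd(group_means, group_sizes, mse: float, df_error: int,
               pair: tuple[str, str]) -> float:
    """Fisher's least-significant-difference pairwise p-value.

    ``t = (mean_i - mean_j) / sqrt(mse * (1/n_i + 1/n_j))`` referred to a t
    distribution on the ANOVA error degrees of freedom; two-tailed, with no
    multiplicity adjustment (that is the LSD definition).
    """
    if not (mse > 0):
        raise ValueError(f"mse must be > 0, got {mse}")
    if df_error < 1:
        raise ValueError(f"df_error must be >= 1, got {df_error}")
    i, j = pair
    t = (group_means[i] - group_means[j]) / np.sqrt(
        mse * (1.0 / group_sizes[i] + 1.0 / group_sizes[j]))
    return float(2.0 * stats.t.sf(abs(t), df_error))


def minmax_percent(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-row min-max normalization to percent for heatmap display.

    For each species (row) the smallest group mean maps to 0% and the
    largest to 100%: ``100 * (x - min) / (max - min)``.  A constant row
    becomes all zeros with a logged warning.
    """
    values = profile.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("profile means must be finite")
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    if flat.any():
        logger.warning("minmax_percent: %d constant row(s) set to 0%%: %s",
                       flat.sum(), list(profile.index[flat])[:5])
    safe = np.where(span == 0, 1.0, span)
    out = 100.0 * (values - lo) / safe
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=profile.index, columns=profile.columns)
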