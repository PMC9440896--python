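"""Significance-A outlier statistics for replicate-free log protein ratios.

When a label-free proteomics design has a single pooled measurement per
condition, per-protein replicate tests are impossible.  The alternative
implemented here treats the whole distribution of per-protein log ratios
as the null and asks, protein by protein, how far out in the tail the
protein's ratio sits.

The spread of the null is estimated robustly and *asymmetrically* from
three percentiles of the log-ratio distribution,

    r_{-1} = 15.87th percentile,  r_0 = median,  r_1 = 84.13th percentile,

so that ``r_1 - r_0`` (right) and ``r_0 - r_{-1}`` (left) are one-sided
robust standard deviations: 15.87 and 84.13 are ``100*Phi(-1)`` and
``100*Phi(+1)``, so for a normal sample each difference converges to the
conventional s.d.  A protein with log ratio ``r`` is standardized against
the side of the distribution it falls on,

    z = (r - r_0) / (r_1 - r_0)      if r >= r_0      (right tail)
    z = (r_0 - r) / (r_0 - r_{-1})   if r <  r_0      (left tail)

and its outlier p-value ("significance A") is the standard normal mass
beyond ``z``:

    p = 0.5 * erfc(z / sqrt(2)) = integral_z^inf phi(t) dt,

the probability of a log ratio at least this extreme under the null
hypothesis that the distribution has normal upper and lower tails.  ``p``
lives in (0, 0.5]; the median protein scores exactly 0.5.

Differential proteins are then called with two joint gates: fold change
above a threshold (default 1.5, i.e. ``|r| > log2 1.5``) and significance-A
p below a threshold (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erfc
from statsmodels.stats.multitest import multipletests

from .io_tables import QuantTable

__all__ = [
    "LOWER_PERCENTILE",
    "UPPER_PERCENTILE",
    "DegenerateSpreadError",
    "LogRatioSet",
    "RobustSpread",
    "compute_log_ratios",
    "percentile",
    "robust_spread",
    "significance_a",
    "score_table",
    "call_differential",
]

logger = logging.getLogger(__name__)

#: percentiles bracketing one standard normal s.d. around the median:
#: 100*Phi(-1) = 15.87 and 100*Phi(+1) = 84.13 (to two decimals)
LOWER_PERCENTILE = 15.87
UPPER_PERCENTILE = 84.13

#: refuse to estimate the percentile triple below this many retained
#: proteins; the tail percentiles are meaningless on tiny sets
DEFAULT_MIN_RETAINED = 20


class DegenerateSpreadError(ValueError):
    """The log-ratio distribution has a zero one-sided robust s.d."""


@dataclass
class LogRatioSet:
    """Per-protein log2 ratios plus the excluded proteins with reasons.

    Retained and excluded ids are disjoint and together cover the input
    table: parsers upstream never drop rows, so every exclusion (missing
    or zero abundance in either condition) is recorded here.
    """

    ratios: pd.Series  # index protein_id, value log2(treated/control)
    excluded: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.ratios.to_numpy(dtype=float))):
            raise ValueError("retained log ratios must be finite")
        overlap = set(self.ratios.index) & {pid for pid, _ in self.excluded}
        if overlap:
            raise ValueError(f"protein(s) both retained and excluded: {sorted(overlap)[:3]}")

    @property
    def n_retained(self) -> int:
        return len(self.ratios)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


@dataclass(frozen=True)
class RobustSpread:
    """The percentile triple and the two one-sided robust s.d. values."""

    r_minus1: float  #: 15.87th percentile
    r0: float        #: median
    r1: float        #: 84.13th percentile

    def __post_init__(self) -> None:
        if not (self.r_minus1 <= self.r0 <= self.r1):
            raise ValueError("percentile triple must be ordered")
        if self.sd_right <= 0 or self.sd_left <= 0:
            raise DegenerateSpreadError(
                "one-sided robust s.d. is zero; the log-ratio distribution "
                "is degenerate on at least one side of the median")

    @property
    def sd_right(self) -> float:
        return self.r1 - self.r0

    @property
    def sd_left(self) -> float:
        return self.r0 - self.r_minus1


def compute_log_ratios(table: QuantTable, treated: str, control: str) -> LogRatioSet:
    """Form per-protein ``log2(treated / control)`` ratios.

    Only proteins quantified in both conditions enter the analysis: a
    protein missing or zero in either condition is excluded with a reason
    (zero is stored distinctly from missing upstream but neither admits a
    log ratio).  Exclusions are logged once each.
    """
    for name in (treated, control):
        if name not in table.conditions:
            raise KeyError(
                f"unknown condition {name!r}; table has {table.conditions}")
    t = table.data[treated].to_numpy(dtype=float)
    c = table.data[control].to_numpy(dtype=float)
    ids = np.asarray(table.protein_ids)

    excluded: list[tuple[str, str]] = []
    keep = np.ones(len(ids), dtype=bool)
    for side, values in ((treated, t), (control, c)):
        for flag, reason in ((np.isnan(values), f"unquantified in {side}"),
                             (values == 0, f"zero abundance in {side}")):
            for i in np.nonzero(flag & keep)[0]:
                excluded.append((ids[i], reason))
                logger.info("excluding %s: %s", ids[i], reason)
            keep &= ~flag
    ratios = pd.Series(np.log2(t[keep] / c[keep]),
                       index=pd.Index(ids[keep], name="protein_id"),
                       name="log2_ratio")
    return LogRatioSet(ratios=ratios, excluded=excluded)


def percentile(values, q: float) -> float:
    """The ``q``-th quantile (``q`` a fraction in [0, 1]) of a finite vector.

    Uses linear interpolation between order statistics: with the sorted
    sample ``v[0..n-1]`` and ``h = (n-1) q``, the result is
    ``v[floor(h)] + (h - floor(h)) * (v[floor(h)+1] - v[floor(h)])``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of an empty vector is undefined")
    if not np.all(np.isfinite(arr)):
        raise ValueError("percentile requires finite values")
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must be a fraction in [0, 1], got {q}")
    return float(np.quantile(arr, q))  # numpy's default is the linear rule


def robust_spread(ratios, min_retained: int = DEFAULT_MIN_RETAINED) -> RobustSpread:
    """Estimate the asymmetric robust spread of a log-ratio distribution."""
    if isinstance(ratios, LogRatioSet):
        arr = ratios.ratios.to_numpy(dtype=float)
    elif isinstance(ratios, pd.Series):
        arr = ratios.to_numpy(dtype=float)
    else:
        arr = np.asarray(ratios, dtype=float)
    if arr.size < min_retained:
        raise ValueError(
            f"only {arr.size} retained log ratios; at least {min_retained} "
            "are required for a meaningful percentile estimate")
    return RobustSpread(
        r_minus1=percentile(arr, LOWER_PERCENTILE / 100.0),
        r0=percentile(arr, 0.5),
        r1=percentile(arr, UPPER_PERCENTILE / 100.0),
    )


def significance_a(r, spread: RobustSpread):
    """Standardized outlier distance and significance-A p for log ratio(s).

    Returns ``(z, tail, p)``.  For scalar ``r`` these are a float, the
    string ``"right"`` or ``"left"`` and a float; for array input, arrays.
    Ratios at or above the median are standardized by the right-sided
    robust s.d., ratios below by the left-sided one, and
    ``p = 0.5 * erfc(z / sqrt 2)`` is the standard normal upper-tail mass
    beyond ``z`` — strictly decreasing in ``z``, 0.5 at the median.
    """
    arr = np.asarray(r, dtype=float)
    right = arr >= spread.r0
    z = np.where(right,
                 (arr - spread.r0) / spread.sd_right,
                 (spread.r0 - arr) / spread.sd_left)
    p = 0.5 * erfc(z / np.sqrt(2.0))
    tail = np.where(right, "right", "left")
    if np.isscalar(r) or arr.ndim == 0:
        return float(z), str(tail), float(p)
    return z, tail, p


def score_table(ratios: LogRatioSet | pd.Series,
                spread: RobustSpread | None = None,
                min_retained: int = DEFAULT_MIN_RETAINED) -> pd.DataFrame:
    """Score every retained protein: z, tail, p and direction-agnostic fold change.

    ``fold_change = 2**|r| = max(a, b)/min(a, b) >= 1`` is derived from the
    same log ratio used for the p-value, so the fold-change gate and the
    significance gate share a single source of truth.
    """
    series = ratios.ratios if isinstance(ratios, LogRatioSet) else ratios
    if spread is None:
        spread = robust_spread(series, min_retained=min_retained)
    r = series.to_numpy(dtype=float)
    z, tail, p = significance_a(r, spread)
    return pd.DataFrame({
        "protein_id": series.index,
        "log2_ratio": r,
        "z": z,
        "tail": tail,
        "p": p,
        "fold_change": np.exp2(np.abs(r)),
    })


def call_differential(scores: pd.DataFrame,
                      fc_threshold: float = 1.5,
                      p_threshold: float = 0.05) -> tuple[set, set, pd.DataFrame]:
    """Apply the two differential-expression gates.

    A protein is differential iff ``fold_change > fc_threshold`` (strict)
    and ``p < p_threshold`` (strict); its direction is the sign of the log
    ratio.  Also annotates a Benjamini–Hochberg q-value column for the
    reader's benefit — it never participates in the call.  Returns
    ``(up_ids, down_ids, annotated_scores)``.
    """
    if fc_threshold < 1:
        raise ValueError(f"fc_threshold must be >= 1, got {fc_threshold}")
    if p_threshold <= 0:
        raise ValueError(f"p_threshold must be > 0, got {p_threshold}")
    annotated = scores.copy()
    de = (annotated["fold_change"].to_numpy() > fc_threshold) \
        & (annotated["p"].to_numpy() < p_threshold)
    r = annotated["log2_ratio"].to_numpy()
    direction = np.where(de, np.where(r > 0, "up", "down"), "none")
    annotated["de"] = de
    annotated["direction"] = direction
    if len(annotated):
        annotated["q_bh"] = multipletests(annotated["p"].to_numpy(),
                                          method="fdr_bh")[1]
    else:
        annotated["q_bh"] = np.array([], dtype=float)
    up = set(annotated.loc[de & (r > 0), "protein_id"])
    down = set(annotated.loc[de & (r < 0), "protein_id"])
    return up, down, annotated
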