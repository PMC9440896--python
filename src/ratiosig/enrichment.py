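"""Over-representation analysis against a detected-protein background.

The hit list (differential proteins) is tested category by category with
the one-sided hypergeometric upper tail, using the set of all detected
proteins as the background — not a whole-genome reference — so that
detectability bias cancels.  Raw p-values are Bonferroni-corrected over
the categories actually tested.  Pairwise set overlaps ("co-regulation")
are reported as a percentage of each set, yielding a range when the two
sets differ in size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_tables import GeneSetCollection

__all__ = [
    "OverlapReport",
    "hypergeom_upper_tail",
    "overrepresentation",
    "set_overlap",
]

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` background size, ``K`` category size within the background,
    ``n`` hit-list size, ``k`` observed overlap.  The survival function is
    evaluated by scipy in a numerically stable way (log-space gammas).
    """
    for name, value in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(value) != value or value < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {value}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def overrepresentation(de_set, background, sets: GeneSetCollection,
                       min_category_size: int = 5) -> pd.DataFrame:
    """Test every category for enrichment of the hit list.

    Categories are first intersected with the background; those with fewer
    than ``min_category_size`` background members are skipped.  Bonferroni
    multiplies each raw p by the number ``m`` of categories actually
    tested, capped at 1.  Hits outside the background are dropped with a
    logged warning.  Rows are sorted by ascending raw p, then category id.

    Columns: category_id, N, K, n, k, enrichment_ratio, p_raw, p_adj.
    """
    background = set(background)
    if not background:
        raise ValueError("background set is empty")
    de_set = set(de_set)
    stray = de_set - background
    if stray:
        logger.warning("dropping %d hit id(s) absent from the background "
                       "(e.g. %s)", len(stray), sorted(stray)[:3])
        de_set &= background

    N = len(background)
    n = len(de_set)
    rows = []
    for cat in sets:
        members = set(cat.members) & background
        K = len(members)
        if K < min_category_size:
            continue
        k = len(de_set & members)
        p_raw = hypergeom_upper_tail(k, K, n, N)
        ratio = (k / n) / (K / N) if n > 0 else 0.0
        rows.append((cat.category_id, N, K, n, k, ratio, p_raw))
    m = len(rows)
    df = pd.DataFrame(rows, columns=["category_id", "N", "K", "n", "k",
                                     "enrichment_ratio", "p_raw"])
    df["p_adj"] = np.minimum(1.0, m * df["p_raw"]) if m else pd.Series(dtype=float)
    return df.sort_values(["p_raw", "category_id"],
                          kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class OverlapReport:
    """Exact overlap of two identifier sets with both directional percentages."""

    size_a: int
    size_b: int
    intersection: int
    pct_of_a: float
    pct_of_b: float

    @property
    def pct_range(self) -> tuple[float, float]:
        """The co-regulation range, smaller percentage first."""
        return tuple(sorted((self.pct_of_a, self.pct_of_b)))  # type: ignore[return-value]


def set_overlap(a, b) -> OverlapReport:
    """Venn-style overlap of two sets, as a percentage of each.

    An empty set's percentage is defined as 0 with a logged warning.
    """
    a, b = set(a), set(b)
    inter = len(a & b)
    if not a or not b:
        logger.warning("set_overlap: empty set; its percentage is defined as 0")
    return OverlapReport(
        size_a=len(a),
        size_b=len(b),
        intersection=inter,
        pct_of_a=100.0 * inter / len(a) if a else 0.0,
        pct_of_b=100.0 * inter / len(b) if b else 0.0,
    )
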