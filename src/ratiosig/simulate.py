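"""Synthetic data with known ground truth for every pipeline stage.

The quantification simulator emulates a replicate-free two-condition
label-free experiment: one pooled abundance per protein per condition,
a unimodal null distribution of log2 ratios (optionally asymmetric), a
planted fraction of truly differential proteins at a fixed effect size,
and missing-completely-at-random dropouts.

The null family is an equal-mass split normal about the median: a ratio
falls on the right side with probability 1/2 and its magnitude is
half-normal with the right scale, symmetrically on the left with the left
scale.  Each side of the distribution is therefore exactly a normal tail
about the median — the null the outlier statistic assumes — while the two
scales may differ, which is what exercises the asymmetric spread
estimator.  ``null_skew`` is the log2 ratio of left to right scale
(0 = symmetric; 1 = left tail twice as wide as the right).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_tables import ConfigError, GeneSet, GeneSetCollection, GroupedData, QuantTable

__all__ = [
    "SimulationConfig",
    "simulate_quant_experiment",
    "simulate_grouped_measurements",
    "simulate_gene_sets",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated two-condition quantification.

    Defaults describe a 10,000-protein experiment with 5% truly
    differential proteins at a 4-fold (|log2| = 2) effect over a symmetric
    normal null with s.d. 0.3 log2 units, baselines log-uniform across four
    decades of intensity, and no missing values (missingness is opt-in so
    that ground-truth recovery is well defined by default).
    """

    n_proteins: int = 10_000
    frac_de: float = 0.05
    effect_log2: float = 2.0
    null_sd: float = 0.3
    null_skew: float = 0.0
    baseline_range: tuple[float, float] = (1e5, 1e9)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins", f"must be >= 1, got {self.n_proteins}")
        if not (0.0 <= self.frac_de <= 1.0):
            raise ConfigError("frac_de", f"must be in [0, 1], got {self.frac_de}")
        if self.effect_log2 < 0:
            raise ConfigError("effect_log2", f"must be >= 0, got {self.effect_log2}")
        if not (self.null_sd > 0):
            raise ConfigError("null_sd", f"must be > 0, got {self.null_sd}")
        lo, hi = self.baseline_range
        if not (0 < lo <= hi):
            raise ConfigError("baseline_range",
                              f"must be a positive interval, got {self.baseline_range}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate",
                              f"must be in [0, 1), got {self.missing_rate}")

    @property
    def scale_left(self) -> float:
        return self.null_sd * 2.0 ** (self.null_skew / 2.0)

    @property
    def scale_right(self) -> float:
        return self.null_sd * 2.0 ** (-self.null_skew / 2.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_range"] = list(self.baseline_range)
        return d


def _split_normal(rng: np.random.Generator, n: int,
                  scale_left: float, scale_right: float) -> np.ndarray:
    """Equal-mass split normal centred at 0: each side a normal tail."""
    right = rng.random(n) < 0.5
    magnitude = np.abs(rng.standard_normal(n))
    return np.where(right, magnitude * scale_right, -magnitude * scale_left)


def simulate_quant_experiment(config: SimulationConfig) -> tuple[QuantTable, pd.DataFrame]:
    """Simulate a two-condition quantification table with ground truth.

    Exactly ``round(frac_de * n_proteins)`` proteins are truly
    differential, half up and half down (the odd one up).  Control
    abundances are drawn log-uniformly from ``baseline_range``; treated
    abundance is ``control * 2**(null draw + planted log2 ratio)``.
    Missing cells are independent per cell at ``missing_rate``.

    Returns the :class:`~ratiosig.io_tables.QuantTable` (conditions
    ``control`` and ``treated``) and a truth table with one row per protein
    (``protein_id``, ``is_de``, ``planted_log2_ratio``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    width = max(4, len(str(n)))
    ids = np.array([f"P{i + 1:0{width}d}" for i in range(n)])

    n_de = int(np.floor(config.frac_de * n + 0.5))  # round half up
    n_up = (n_de + 1) // 2  # tie broken toward up
    de_idx = rng.choice(n, size=n_de, replace=False)
    planted = np.zeros(n)
    planted[de_idx[:n_up]] = config.effect_log2
    planted[de_idx[n_up:]] = -config.effect_log2

    lo, hi = config.baseline_range
    control = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), n)
    eps = _split_normal(rng, n, config.scale_left, config.scale_right)
    treated = control * 2.0 ** (eps + planted)

    data = pd.DataFrame({"control": control, "treated": treated},
                        index=pd.Index(ids, name="protein_id"))
    if config.missing_rate > 0:
        mask = rng.random(size=data.shape) < config.missing_rate
        data = data.mask(mask)

    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True  # count is exactly round(frac_de * n) by construction
    truth = pd.DataFrame({
        "protein_id": ids,
        "is_de": is_de,
        "planted_log2_ratio": planted,
    })
    return QuantTable(data), truth


def simulate_grouped_measurements(n_groups: int, n_per_group: int,
                                  means, sd: float, family: str = "normal",
                                  seed: int = 0) -> GroupedData:
    """Seeded grouped measurements for the normality-gated tests.

    ``family="normal"`` draws ``N(mean_i, sd)`` per group; ``"lognormal"``
    draws ``exp(N(log mean_i, sd))`` so that ``sd`` is the log-scale spread
    and large values produce strongly right-skewed groups.  Labels are
    ``g1..gk``.
    """
    if n_groups < 2:
        raise ConfigError("n_groups", f"must be >= 2, got {n_groups}")
    if n_per_group < 3:
        raise ConfigError("n_per_group",
                          f"must be >= 3 (normality test undefined below 3), "
                          f"got {n_per_group}")
    means = np.asarray(means, dtype=float)
    if means.shape != (n_groups,):
        raise ConfigError("means", f"need {n_groups} entries, got {means.shape}")
    if not (sd > 0):
        raise ConfigError("sd", f"must be > 0, got {sd}")
    if family not in ("normal", "lognormal"):
        raise ConfigError("family", f"must be 'normal' or 'lognormal', got {family!r}")
    if family == "lognormal" and np.any(means <= 0):
        raise ConfigError("means", "lognormal family requires positive means")

    rng = np.random.default_rng(seed)
    groups: dict[str, np.ndarray] = {}
    for i in range(n_groups):
        z = rng.standard_normal(n_per_group)
        if family == "normal":
            values = means[i] + sd * z
        else:
            values = np.exp(np.log(means[i]) + sd * z)
        groups[f"g{i + 1}"] = values
    return GroupedData(groups)


def simulate_gene_sets(n_categories: int, category_size: int,
                       universe, planted_category_members,
                       seed: int = 0) -> GeneSetCollection:
    """A gene-set collection with exactly one planted enriched category.

    The first category (id ``planted``) contains exactly the planted
    members; the remaining ``n_categories - 1`` are uniform draws of
    ``category_size`` identifiers from the universe, without replacement
    within a category.
    """
    if n_categories < 1:
        raise ConfigError("n_categories", f"must be >= 1, got {n_categories}")
    if category_size < 1:
        raise ConfigError("category_size", f"must be >= 1, got {category_size}")
    universe = list(dict.fromkeys(universe))
    planted = list(dict.fromkeys(planted_category_members))
    if not planted:
        raise ConfigError("planted_category_members", "must be non-empty")
    outside = [m for m in planted if m not in set(universe)]
    if outside:
        raise ConfigError("planted_category_members",
                          f"member(s) outside universe: {outside[:5]}")
    if category_size > len(universe):
        raise ConfigError("category_size",
                          f"{category_size} exceeds universe size {len(universe)}")

    rng = np.random.default_rng(seed)
    categories = [GeneSet("planted", "planted enriched category", tuple(planted))]
    universe_arr = np.asarray(universe, dtype=object)
    for i in range(1, n_categories):
        members = rng.choice(universe_arr, size=category_size, replace=False)
        categories.append(GeneSet(f"random{i:04d}", "uniform draw from universe",
                                  tuple(members)))
    return GeneSetCollection(categories)
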