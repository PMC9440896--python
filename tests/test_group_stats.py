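import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ratiosig.group_stats import (compare_many, compare_two, fisher_lsd,
                                  minmax_percent, normality_gate)
from ratiosig.io_tables import GroupedData
from ratiosig.simulate import simulate_grouped_measurements


def exact_mannwhitney_p(a, b) -> float:
    """Enumeration oracle: two-sided exact Mann-Whitney p over all label
    assignments of the pooled sample (no ties)."""
    pooled = list(a) + list(b)
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    dist = Counter()
    for combo in itertools.combinations(range(len(pooled)), na):
        group_a = [pooled[i] for i in combo]
        group_b = [pooled[i] for i in range(len(pooled)) if i not in set(combo)]
        dist[sum(1 for x in group_a for y in group_b if x > y)] += 1
    total = sum(dist.values())
    le = sum(c for u, c in dist.items() if u <= u_obs) / total
    ge = sum(c for u, c in dist.items() if u >= u_obs) / total
    return min(1.0, 2 * min(le, ge))


class TestNormalityGate:
    def test_normal_samples_take_parametric_branch(self):
        data = simulate_grouped_measurements(2, 8, [0.0, 0.0], 1.0, seed=0)
        branch, gate_p = normality_gate(data)
        assert branch == "parametric"
        assert all(p > 0.05 for p in gate_p.values())

    def test_heavy_skew_takes_nonparametric_branch(self):
        data = simulate_grouped_measurements(2, 50, [1.0, 1.0], 2.0,
                                             family="lognormal", seed=4)
        branch, gate_p = normality_gate(data)
        assert branch == "nonparametric"
        assert min(gate_p.values()) < 0.05

    def test_gate_is_pure_function_of_pvalues(self):
        data = simulate_grouped_measurements(2, 8, [0.0, 0.0], 1.0, seed=3)
        _, gate_p = normality_gate(data)
        expected = "parametric" if all(p > 0.05 for p in gate_p.values()) \
            else "nonparametric"
        branch, _ = normality_gate(data)
        assert branch == expected

    def test_constant_group_error_names_group(self):
        data = GroupedData({"ok": np.array([1.0, 2.0, 3.0]),
                            "flat": np.array([5.0, 5.0, 5.0])})
        with pytest.raises(ValueError, match="flat"):
            normality_gate(data)

    def test_small_group_rejected(self):
        data = GroupedData({"a": np.array([1.0, 2.0]),
                            "b": np.array([1.0, 2.0, 3.0])})
        with pytest.raises(ValueError, match="'a'"):
            normality_gate(data)


class TestCompareTwo:
    def test_identical_groups_t_zero_p_one(self):
        data = GroupedData({"a": np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
                            "b": np.array([1.0, 2.0, 3.0, 4.0, 5.0])})
        report = compare_two(data)
        assert report.branch == "parametric"
        assert report.omnibus_statistic == pytest.approx(0.0)
        assert report.omnibus_p == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(12)
        base = rng.standard_normal(8)
        data = GroupedData({"a": 2.0 + base, "b": 12.0 + rng.standard_normal(8)})
        report = compare_two(data)
        assert report.branch == "parametric"
        assert report.omnibus_p < 0.01

    def test_parametric_p_matches_reference(self):
        data = simulate_grouped_measurements(2, 8, [0.0, 1.0], 1.0, seed=5)
        report = compare_two(data)
        assert report.branch == "parametric"
        ref = stats.ttest_ind(data["g1"], data["g2"], equal_var=True)
        assert report.omnibus_p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_skewed_routes_to_exact_mannwhitney(self):
        # strongly non-normal small groups, no ties: exact branch
        a = np.array([1.0, 2.0, 3.0, 4.0, 100.0, 200.0, 400.0])
        b = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 1000.0, 2000.0])
        data = GroupedData({"a": a, "b": b})
        report = compare_two(data)
        if report.branch == "nonparametric":
            assert report.omnibus_p == pytest.approx(
                exact_mannwhitney_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_mannwhitney_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = np.exp(rng.standard_normal(6) * 2)
        b = np.exp(rng.standard_normal(7) * 2)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(exact_mannwhitney_p(a, b), abs=1e-12)

    def test_wrong_group_count(self):
        data = GroupedData({"a": np.array([1.0, 2.0, 3.0])})
        with pytest.raises(ValueError, match="exactly 2"):
            compare_two(data)


class TestCompareMany:
    def test_abc_fixture_lsd_pattern(self, abc_groups):
        report = compare_many(abc_groups)
        assert report.branch == "parametric"
        assert report.omnibus_name == "one-way ANOVA"
        assert report.omnibus_p < 0.001
        posthoc = dict(report.posthoc)
        assert posthoc[("A", "C")] < 0.05
        assert posthoc[("B", "C")] < 0.05
        assert posthoc[("A", "B")] > 0.05

    def test_abc_lsd_matches_pooled_t_oracle(self, abc_groups):
        # MSE = 1 (each group has unit sample variance), df_error = 6
        report = compare_many(abc_groups)
        posthoc = dict(report.posthoc)
        t_ab = (2.0 - 3.0) / math.sqrt(1.0 * (1 / 3 + 1 / 3))
        expected = 2 * stats.t.sf(abs(t_ab), 6)
        assert posthoc[("A", "B")] == pytest.approx(expected, abs=1e-12)

    def test_protected_lsd_suppressed_when_omnibus_flat(self):
        data = simulate_grouped_measurements(3, 6, [0.0, 0.0, 0.0], 1.0, seed=8)
        report = compare_many(data)
        if report.branch == "parametric" and report.omnibus_p >= 0.05:
            assert report.posthoc == []

    def test_unprotected_flag_forces_posthoc(self):
        data = simulate_grouped_measurements(3, 6, [0.0, 0.0, 0.0], 1.0, seed=8)
        report = compare_many(data, protected=False)
        if report.branch == "parametric":
            assert len(report.posthoc) == 3

    def test_nonparametric_branch_kruskal_no_posthoc(self):
        data = simulate_grouped_measurements(3, 30, [1.0, 1.0, 5.0], 2.0,
                                             family="lognormal", seed=9)
        report = compare_many(data)
        assert report.branch == "nonparametric"
        assert report.omnibus_name == "Kruskal-Wallis"
        assert report.posthoc == []

    def test_two_groups_redirected(self):
        data = GroupedData({"a": np.array([1.0, 2.0, 3.0]),
                            "b": np.array([1.0, 2.0, 3.5])})
        with pytest.raises(ValueError, match="compare_two"):
            compare_many(data)


class TestFisherLsd:
    MEANS = {"A": 2.0, "B": 3.0, "C": 11.0}
    SIZES = {"A": 3, "B": 3, "C": 3}

    def test_equal_means_p_one(self):
        p = fisher_lsd({"x": 1.0, "y": 1.0}, {"x": 4, "y": 4}, 2.0, 6, ("x", "y"))
        assert p == pytest.approx(1.0)

    def test_formula_oracle(self):
        t = (self.MEANS["A"] - self.MEANS["C"]) / math.sqrt(1.0 * (1 / 3 + 1 / 3))
        expected = 2 * stats.t.sf(abs(t), 6)
        assert fisher_lsd(self.MEANS, self.SIZES, 1.0, 6, ("A", "C")) == \
            pytest.approx(expected, abs=1e-12)

    def test_single_observation_group_allowed(self):
        sizes = {"A": 1, "B": 5}
        p = fisher_lsd({"A": 0.0, "B": 1.0}, sizes, 0.5, 4, ("A", "B"))
        t = -1.0 / math.sqrt(0.5 * (1 + 1 / 5))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 4), abs=1e-12)

    def test_reduces_to_pooled_two_sample_t(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 9)
        mse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        df = len(a) + len(b) - 2
        mse /= df
        p = fisher_lsd({"a": a.mean(), "b": b.mean()},
                       {"a": len(a), "b": len(b)}, mse, df, ("a", "b"))
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_mse_rejected(self):
        with pytest.raises(ValueError, match="mse"):
            fisher_lsd(self.MEANS, self.SIZES, 0.0, 6, ("A", "B"))


class TestMinmaxPercent:
    def test_row_endpoints_fixed(self):
        profile = pd.DataFrame([[2.0, 5.0, 8.0]], index=["lipid1"],
                               columns=["g1", "g2", "g3"])
        out = minmax_percent(profile)
        np.testing.assert_allclose(out.loc["lipid1"], [0.0, 50.0, 100.0])

    def test_two_group_row(self):
        out = minmax_percent(pd.DataFrame([[3.0, 9.0]]))
        np.testing.assert_allclose(out.iloc[0], [0.0, 100.0])

    def test_constant_row_zero_with_warning(self, caplog):
        profile = pd.DataFrame([[7.0, 7.0, 7.0]], index=["flat"])
        with caplog.at_level("WARNING", logger="ratiosig.group_stats"):
            out = minmax_percent(profile)
        np.testing.assert_allclose(out.iloc[0], [0.0, 0.0, 0.0])
        assert "constant" in caplog.text

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.01, 100.0), st.floats(-50.0, 50.0))
    def test_invariant_to_positive_affine_transform(self, a, b):
        profile = pd.DataFrame([[1.0, 4.0, 2.5, 9.0]])
        transformed = profile * a + b
        np.testing.assert_allclose(minmax_percent(transformed).to_numpy(),
                                   minmax_percent(profile).to_numpy(),
                                   rtol=1e-7, atol=1e-7)
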