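"""Conditional-independence tests: hand-computed oracles, null calibration,
and invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amenbn.citests import cg_lrt_test, ci_test, fisher_z_test, g2_test
from amenbn.exceptions import InsufficientDataError, NotDiscreteError
from amenbn.variables import DataTable, VariableSpec

from conftest import continuous_table, mixed_table


def two_by_two(counts):
    """Discrete 2x2 DataTable with the given cell counts [[aa,ab],[ba,bb]]."""
    rows = []
    for i, xl in enumerate("ab"):
        for j, yl in enumerate("cd"):
            rows += [{"x": xl, "y": yl}] * counts[i][j]
    return DataTable(
        [VariableSpec("x", "discrete", ("a", "b")),
         VariableSpec("y", "discrete", ("c", "d"))],
        pd.DataFrame(rows),
    )


class TestG2:
    def test_hand_computed_2x2(self):
        """Statistic equals 2·Σ o·ln(o/e) computed cell by cell by hand."""
        counts = [[10, 20], [20, 10]]
        tab = two_by_two(counts)
        n = 60
        expected_stat = 0.0
        row = [30, 30]
        col = [30, 30]
        for i in range(2):
            for j in range(2):
                o = counts[i][j]
                e = row[i] * col[j] / n
                expected_stat += 2 * o * math.log(o / e)
        res = g2_test(tab, "x", "y")
        assert res.statistic == pytest.approx(expected_stat, abs=1e-12)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(expected_stat, 1))

    def test_constant_variable_gives_p_one(self):
        tab = two_by_two([[15, 0], [25, 0]])  # y constant at level c
        res = g2_test(tab, "x", "y")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_conditioning_df(self):
        rng = np.random.default_rng(0)
        n = 400
        tab = mixed_table(
            {
                "x": np.array(["a", "b"])[rng.integers(0, 2, n)],
                "y": np.array(["c", "d"])[rng.integers(0, 2, n)],
                "z": np.array(["u", "v", "w"])[rng.integers(0, 3, n)],
            },
            {"x": ("a", "b"), "y": ("c", "d"), "z": ("u", "v", "w")},
        )
        assert g2_test(tab, "x", "y", ("z",)).df == 1 * 1 * 3

    def test_rejects_continuous_input(self):
        tab = continuous_table({"x": np.arange(5.0), "y": np.arange(5.0)})
        with pytest.raises(NotDiscreteError):
            g2_test(tab, "x", "y")

    def test_level_relabeling_invariance(self):
        """G² depends only on the counts, not on which label is which."""
        tab = two_by_two([[10, 20], [20, 10]])
        swapped = two_by_two([[20, 10], [10, 20]])  # x levels exchanged
        assert g2_test(tab, "x", "y").statistic == pytest.approx(
            g2_test(swapped, "x", "y").statistic, abs=1e-12
        )


class TestFisherZ:
    def test_duplicated_variable_flags_perfect_correlation(self):
        x = np.random.default_rng(1).normal(size=50)
        tab = continuous_table({"x": x, "y": x.copy()})
        assert fisher_z_test(tab, "x", "y").p_value == 0.0

    def test_partial_correlation_matches_recursion_formula(self):
        """Residual-method partial correlation equals the textbook recursion
        r_xy.z = (r_xy − r_xz·r_yz)/sqrt((1−r_xz²)(1−r_yz²))."""
        rng = np.random.default_rng(2)
        z = rng.normal(size=500)
        x = 0.6 * z + rng.normal(size=500)
        y = -0.4 * z + rng.normal(size=500)
        tab = continuous_table({"x": x, "y": y, "z": z})
        r = np.corrcoef(np.vstack([x, y, z]))
        r_part = (r[0, 1] - r[0, 2] * r[1, 2]) / math.sqrt(
            (1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2)
        )
        expected_z = abs(math.atanh(r_part)) * math.sqrt(500 - 1 - 3)
        res = fisher_z_test(tab, "x", "y", ("z",))
        assert res.statistic == pytest.approx(expected_z, abs=1e-8)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        t1 = continuous_table({"x": x, "y": y})
        t2 = continuous_table({"x": 3.0 * x - 7.0, "y": 0.01 * y + 2.0})
        assert fisher_z_test(t1, "x", "y").statistic == pytest.approx(
            fisher_z_test(t2, "x", "y").statistic, abs=1e-8
        )

    def test_insufficient_data(self):
        tab = continuous_table({"x": np.arange(3.0), "y": np.arange(3.0) ** 2})
        with pytest.raises(InsufficientDataError):
            fisher_z_test(tab, "x", "y", ())


class TestCgLrt:
    def test_single_level_discrete_is_independent(self):
        rng = np.random.default_rng(4)
        tab = mixed_table(
            {"y": rng.normal(size=30), "d": ["only"] * 30}, {"d": ("only",)}
        )
        res = cg_lrt_test(tab, "y", "d")
        assert (res.statistic, res.df, res.p_value) == (0.0, 1, 1.0)

    def test_df_matches_hand_enumeration(self):
        """2-level stratifier + 1 continuous regressor: the full model has
        (slope + intercept + variance) × 2 strata = 6 free parameters, the
        reduced one (intercept + variance) × 2 = 4, so df = 2."""
        rng = np.random.default_rng(5)
        n = 200
        d = np.array(["a", "b"])[rng.integers(0, 2, n)]
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        tab = mixed_table({"y": y, "x": x, "d": d}, {"d": ("a", "b")})
        assert cg_lrt_test(tab, "y", "x", ("d",)).df == 2

    def test_discrete_extra_variable_df(self):
        """Adding a 2-level stratifier to an intercept-only model doubles the
        (intercept, variance) pairs: df = 4 − 2 = 2."""
        rng = np.random.default_rng(6)
        n = 200
        d = np.array(["a", "b"])[rng.integers(0, 2, n)]
        tab = mixed_table({"y": rng.normal(size=n), "d": d}, {"d": ("a", "b")})
        assert cg_lrt_test(tab, "y", "d").df == 2

    def test_agrees_with_fisher_on_bivariate_gaussian(self):
        """Accept/reject decisions at α = 0.05 agree with Fisher's z in at
        least 95% of 200 simulated bivariate Gaussian datasets."""
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(200):
            x = rng.normal(size=200)
            y = 0.1 * rng.normal() * x + rng.normal(size=200)
            tab = continuous_table({"x": x, "y": y})
            a = cg_lrt_test(tab, "x", "y").p_value < 0.05
            b = fisher_z_test(tab, "x", "y").p_value < 0.05
            agree += a == b
        assert agree / 200 >= 0.95

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        n = 300
        d = np.array(["a", "b"])[rng.integers(0, 2, n)]
        y = np.where(d == "a", 1.0, -1.0) + rng.normal(size=n)
        t1 = mixed_table({"y": y, "d": d}, {"d": ("a", "b")})
        t2 = mixed_table({"y": 10.0 * y + 3.0, "d": d}, {"d": ("a", "b")})
        assert cg_lrt_test(t1, "y", "d").statistic == pytest.approx(
            cg_lrt_test(t2, "y", "d").statistic, abs=1e-8
        )

    def test_discrete_pair_with_continuous_conditioning_uses_discrete_part(self):
        """Both-discrete pairs test through G² on the discrete conditioning
        subset (continuous nodes between discrete nodes are colliders)."""
        rng = np.random.default_rng(9)
        n = 300
        a = np.array(["a", "b"])[rng.integers(0, 2, n)]
        b = np.array(["c", "d"])[rng.integers(0, 2, n)]
        tab = mixed_table(
            {"a": a, "b": b, "z": rng.normal(size=n)},
            {"a": ("a", "b"), "b": ("c", "d")},
        )
        mixed_res = ci_test(tab, "a", "b", ("z",))
        plain = g2_test(tab, "a", "b")
        assert mixed_res.statistic == pytest.approx(plain.statistic, abs=1e-12)


class TestNullCalibration:
    """p-values under a true null are approximately uniform for all tests."""

    def test_g2_null_uniform(self):
        rng = np.random.default_rng(123)
        ps = []
        for _ in range(1000):
            x = np.array(["a", "b"])[rng.integers(0, 2, 200)]
            y = np.array(["c", "d"])[rng.integers(0, 2, 200)]
            tab = mixed_table({"x": x, "y": y}, {"x": ("a", "b"), "y": ("c", "d")})
            ps.append(g2_test(tab, "x", "y").p_value)
        assert stats.kstest(ps, "uniform").statistic < 0.1

    def test_fisher_null_uniform(self):
        rng = np.random.default_rng(124)
        ps = []
        for _ in range(1000):
            tab = continuous_table({k: rng.normal(size=100) for k in "xyz"})
            ps.append(fisher_z_test(tab, "x", "y", ("z",)).p_value)
        assert stats.kstest(ps, "uniform").statistic < 0.1

    def test_cg_lrt_null_uniform(self):
        rng = np.random.default_rng(125)
        ps = []
        for _ in range(1000):
            d = np.array(["a", "b"])[rng.integers(0, 2, 200)]
            tab = mixed_table(
                {"y": rng.normal(size=200), "x": d, "z": rng.normal(size=200)},
                {"x": ("a", "b")},
            )
            ps.append(cg_lrt_test(tab, "y", "x", ("z",)).p_value)
        assert stats.kstest(ps, "uniform").statistic < 0.1


def test_symmetry_in_arguments():
    """Swapping (x, y) leaves G² and Fisher-z statistics unchanged, and the
    CG-LRT decision agrees in ≥95% of null simulations."""
    rng = np.random.default_rng(10)
    x = rng.normal(size=300)
    y = 0.3 * x + rng.normal(size=300)
    tab = continuous_table({"x": x, "y": y})
    assert fisher_z_test(tab, "x", "y").statistic == pytest.approx(
        fisher_z_test(tab, "y", "x").statistic, abs=1e-12
    )
    agree = 0
    for seed in range(100):
        rng = np.random.default_rng(2000 + seed)
        n = 150
        d = np.array(["a", "b"])[rng.integers(0, 2, n)]
        tab = mixed_table(
            {"u": rng.normal(size=n), "v": rng.normal(size=n), "d": d},
            {"d": ("a", "b")},
        )
        p1 = cg_lrt_test(tab, "u", "v", ("d",)).p_value < 0.05
        p2 = cg_lrt_test(tab, "v", "u", ("d",)).p_value < 0.05
        agree += p1 == p2
    assert agree / 100 >= 0.95
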