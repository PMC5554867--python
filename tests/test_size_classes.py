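"""Diameter-class binning, flow accounting, expected frequencies, G-test."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import power_divergence

from forestdyn.errors import InvalidMeasurementError, UndefinedStatisticError
from forestdyn.size_classes import (
    DiameterClassScheme,
    assign_class,
    class_flows,
    class_growth_test,
    class_mortality_rate,
    expected_class_frequencies,
    g_test,
)
from forestdyn.simulate import SimulationParams, simulate_stand
from tests.conftest import build_registry


class TestAssignClass:
    @pytest.mark.parametrize(
        "dbh, expected",
        [
            (4.99, 0),   # inclusion threshold belongs to the first class
            (7.0, 0),
            (10.0, 0),   # upper-closed boundary
            (10.01, 1),
            (20.0, 1),
            (20.5, 2),
            (40.0, 2),
            (79.9, 3),
            (80.0, 3),
        ],
    )
    def test_boundary_convention(self, dbh, expected):
        assert assign_class(dbh) == expected

    def test_overflow_class(self):
        scheme = DiameterClassScheme()
        assert assign_class(81.0, scheme) == scheme.n_classes

    def test_below_inclusion_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            assign_class(3.0)

    def test_breaks_must_increase(self):
        with pytest.raises(InvalidMeasurementError):
            DiameterClassScheme(breaks_cm=(5, 5, 10))


class TestClassFlows:
    def test_toy_hand_enumeration(self):
        """6 trees: one death, one upward move, one downward move, one recruit."""
        specs = [
            ("T1", "A", [7.0, 8.0]),       # stays in class 1
            ("T2", "A", [9.5, 11.0]),      # grows out of class 1 into 2
            ("T3", "B", [6.0, "dead"]),    # dies in class 1
            ("T4", "B", [12.0, 9.0]),      # shrinks from class 2 into 1
            ("T5", "C", [25.0, 26.0]),     # stays in class 3
            ("T6", "C", [None, 5.5]),      # recruit into class 1
        ]
        reg = build_registry(specs, {"c0": 2000, "c1": 2005})
        table = class_flows(reg, "c0", "c1")
        assert table.n0[:3] == (3, 1, 1)
        assert table.nt[:3] == (3, 1, 1)
        assert table.dead[:3] == (1, 0, 0)
        assert table.outgrowth[:3] == (1, 1, 0)   # T2 out of 1, T4 out of 2
        assert table.ingrowth[:3] == (1, 1, 0)    # T4 into 1, T2 into 2
        assert table.recruits[:3] == (1, 0, 0)
        assert table.total_outgrowth[0] == 2 and table.total_ingrowth[0] == 2
        table.check_conservation()

    def test_no_class_changes_means_zero_flows(self):
        specs = [("T1", "A", [6.0, 6.5]), ("T2", "B", [15.0, 15.5])]
        reg = build_registry(specs, {"c0": 2000, "c1": 2005})
        table = class_flows(reg, "c0", "c1")
        assert sum(table.outgrowth) == sum(table.ingrowth) == 0

    @pytest.mark.parametrize("seed", [1, 22, 333])
    def test_conservation_on_simulations(self, seed):
        reg = simulate_stand(
            SimulationParams(n_initial_trees=300, n_plots=6, seed=seed,
                             growth_median_cm=0.8, census_years=(0, 5))
        )
        table = class_flows(reg, "c0", "c5")
        table.check_conservation()
        for k in range(table.n_classes):
            assert (
                table.nt[k]
                == table.n0[k] - table.dead[k] - table.outgrowth[k]
                + table.recruits[k] + table.ingrowth[k]
            )
        assert sum(table.n0) == reg.snapshot("c0").n_trees

    def test_class_mortality_printed_values(self):
        assert class_mortality_rate(867, 133, 5) == pytest.approx(3.2757, abs=1e-4)
        assert class_mortality_rate(415, 30, 5) == pytest.approx(1.4895, abs=1e-4)
        assert class_mortality_rate(200, 0, 5) == 0.0


class TestExpectedFrequencies:
    def test_scaled_counts_stand_b(self):
        exp = expected_class_frequencies([867, 415, 77, 5], 1364, 1313)
        assert exp == pytest.approx([834.583, 399.483, 74.121, 4.813], abs=5e-4)

    def test_scaled_dead_stand_b(self):
        exp = expected_class_frequencies([133, 30, 11, 2], 1364, 1313)
        assert exp[1] == pytest.approx(28.878, abs=5e-4)

    def test_ratio_one_is_identity(self):
        vals = [12.0, 7.0, 3.0]
        assert expected_class_frequencies(vals, 640, 640) == pytest.approx(vals)

    @given(
        st.lists(st.integers(0, 1000), min_size=2, max_size=6).filter(
            lambda v: sum(1 for x in v if x > 0) >= 2
        ),
        st.integers(1, 5000),
        st.integers(1, 5000),
    )
    @settings(deadline=None)
    def test_preserves_proportions(self, vals, n0, nt):
        exp = expected_class_frequencies(vals, n0, nt)
        pos = [(v, e) for v, e in zip(vals, exp) if v > 0]
        (v1, e1), (v2, e2) = pos[0], pos[-1]
        assert e1 * v2 == pytest.approx(e2 * v1, rel=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            expected_class_frequencies([1, 2], 0, 10)


class TestGTest:
    def test_perfect_fit(self):
        res = g_test([10, 20, 30], [10, 20, 30])
        assert res.g == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.df == 2

    def test_hand_value(self):
        res = g_test([10, 5], [7.5, 7.5])
        assert res.g == pytest.approx(1.699, abs=5e-4)

    def test_constant_ratio_identity(self):
        """E_i = O_i * c gives G = 2 * sum(O) * ln(1/c) in closed form."""
        obs = [133, 30, 11, 2]
        exp = expected_class_frequencies(obs, 1364, 1313)
        res = g_test(obs, exp)
        assert res.g == pytest.approx(2 * 176 * math.log(1364 / 1313), rel=1e-9)
        assert res.g == pytest.approx(13.41, abs=5e-3)

    def test_zero_observed_contributes_zero(self):
        res = g_test([0, 10], [5.0, 5.0])
        assert res.g == pytest.approx(2 * 10 * math.log(2), rel=1e-9)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            g_test([1, 2], [0.0, 3.0])
        with pytest.raises(UndefinedStatisticError):
            g_test([1], [1.0])

    def test_agrees_with_scipy_power_divergence(self):
        """Independent route: scipy's log-likelihood-ratio statistic."""
        obs = [40, 30, 20, 10]
        exp = [30.0, 30.0, 25.0, 15.0]
        stat, p = power_divergence(obs, exp, lambda_="log-likelihood")
        res = g_test(obs, exp)
        assert res.g == pytest.approx(stat, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=25)
    def test_first_order_agreement_with_pearson(self, seed):
        """G ~ Pearson X^2 for expectations close to observations."""
        rng = np.random.default_rng(seed)
        exp = rng.uniform(50, 150, size=5)
        obs = exp * (1 + rng.uniform(-0.02, 0.02, size=5))
        obs *= exp.sum() / obs.sum()  # the approximation assumes equal totals
        g = g_test(obs, exp).g
        pearson = float(((obs - exp) ** 2 / exp).sum())
        assert g == pytest.approx(pearson, rel=0.05, abs=1e-4)


class TestGrowthTest:
    def test_symmetry_with_dead_recruit_contract(self):
        res = class_growth_test(128, 206)
        assert res.z == pytest.approx((128 - 206) / math.sqrt(334), rel=1e-9)
        assert round(abs(res.z), 2) == 4.27

    def test_equal_flows(self):
        res = class_growth_test(17, 17)
        assert res.z == 0.0 and res.p_exact == pytest.approx(1.0)

    def test_small_flow_exact_p(self):
        from scipy.stats import binom

        pmf = [binom.pmf(k, 39, 0.5) for k in range(40)]
        expected = sum(p for p in pmf if p <= pmf[28] * (1 + 1e-9))
        assert class_growth_test(28, 11).p_exact == pytest.approx(expected, rel=1e-7)
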