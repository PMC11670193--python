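import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from veinflow.flow import BoundaryConditions, solve_steady_flow
from veinflow.geometry import divide_segments
from veinflow.stats import (
    compare_groups,
    high_velocity_contingency,
    mann_whitney,
    pearson_trend,
    pooled_segment_values,
    spearman_trend,
)
from veinflow.summary import build_vein_record
from veinflow.synthetic import VesselParams, generate_vessel


def exact_mw_two_sided_p(a, b):
    """Oracle: exhaustive enumeration of all rank assignments."""
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(sorted(range(1, n1 + n2 + 1))[i] for i in combo) - n1 * (n1 + 1) / 2.0
        # distance from the null mean determines extremeness (two-sided)
        if abs(u - n1 * n2 / 2.0) >= abs(u_obs - n1 * n2 / 2.0) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_identical_groups_no_separation(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value >= 0.99

    def test_fully_separated_6v5_exact(self):
        a = [10.0, 11.0, 12.0, 13.0, 14.0, 15.0]
        b = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = mann_whitney(a, b, method="exact")
        assert res.p_value == pytest.approx(2.0 / 462.0, rel=1e-12)
        assert res.p_value == pytest.approx(exact_mw_two_sided_p(a, b), rel=1e-12)
        assert res.effect_direction == 1

    def test_symmetry_under_swap(self):
        a = [3.0, 5.0, 9.0, 12.0]
        b = [1.0, 2.0, 4.0, 6.0, 7.0]
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.effect_direction == -r2.effect_direction

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_ties_fall_back_to_asymptotic(self):
        res = mann_whitney([1.0, 1.0, 2.0], [1.0, 3.0, 3.0], method="exact")
        assert res.test_name == "mann-whitney-asymptotic"
        assert 0.0 <= res.p_value <= 1.0

    def test_exact_matches_enumeration_random_cases(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(size=4)
            res = mann_whitney(a, b, method="exact")
            assert res.p_value == pytest.approx(exact_mw_two_sided_p(a, b), rel=1e-9)


class TestSpearmanTrend:
    def test_perfectly_increasing(self):
        res = spearman_trend([1, 2, 3, 4, 5], [2.0, 3.0, 5.0, 8.0, 13.0])
        assert res.statistic == pytest.approx(1.0)
        assert res.effect_direction == 1

    def test_perfectly_decreasing(self):
        res = spearman_trend([1, 2, 3, 4, 5], [9.0, 7.0, 5.0, 3.0, 1.0])
        assert res.statistic == pytest.approx(-1.0)

    def test_constant_values_degenerate(self):
        res = spearman_trend([1, 2, 3], [5.0, 5.0, 5.0])
        assert res.degenerate
        assert np.isfinite(res.statistic)
        assert np.isfinite(res.p_value)

    def test_ties_brute_force_oracle(self):
        # pooled sample with ties: rank-then-Pearson must agree to 1e-12
        x = np.repeat(np.arange(1, 16), 3).astype(float)
        rng = np.random.default_rng(8)
        y = np.round(x * 0.3 + rng.normal(size=x.size), 0)  # many ties

        def avg_ranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty_like(v)
            ranks[order] = np.arange(1, v.size + 1, dtype=float)
            for val in np.unique(v):
                mask = v == val
                ranks[mask] = ranks[mask].mean()
            return ranks

        rho_oracle = np.corrcoef(avg_ranks(x), avg_ranks(y))[0, 1]
        res = spearman_trend(x, y)
        assert res.statistic == pytest.approx(rho_oracle, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            spearman_trend([1, 2], [3.0, 4.0])

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.integers(min_value=-100, max_value=100),
            min_size=4,
            max_size=20,
            unique=True,
        )
    )
    def test_invariant_under_monotone_transform(self, ys):
        # exp(y/100) is strictly monotone and keeps distinct values distinct
        x = list(range(len(ys)))
        r1 = spearman_trend(x, [float(y) for y in ys])
        r2 = spearman_trend(x, list(np.exp(np.array(ys) / 100.0)))
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-9)

    def test_strength_label(self):
        res = spearman_trend([1, 2, 3, 4, 5, 6], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert res.strong


class TestPearsonTrend:
    def test_linear_relationship(self):
        res = pearson_trend([1, 2, 3, 4], [2.0, 4.0, 6.0, 8.0])
        assert res.statistic == pytest.approx(1.0)


class TestContingency:
    def test_printed_table_percentages(self):
        res = high_velocity_contingency(36, 90, 11, 75)
        assert res.extra["percent_a"] == 40.0
        assert res.extra["percent_b"] == 14.7

    def test_printed_table_significance(self):
        res = high_velocity_contingency(36, 90, 11, 75)
        assert res.p_value < 0.001

    def test_chi2_hand_formula(self):
        res = high_velocity_contingency(36, 90, 11, 75)
        obs = np.array([[36.0, 54.0], [11.0, 64.0]])
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        chi2_hand = ((obs - exp) ** 2 / exp).sum()
        assert res.statistic == pytest.approx(chi2_hand, abs=1e-9)

    def test_identical_proportions(self):
        res = high_velocity_contingency(10, 50, 20, 100)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_flagged_exceeds_total_rejected(self):
        with pytest.raises(ValueError):
            high_velocity_contingency(91, 90, 11, 75)
        with pytest.raises(ValueError):
            high_velocity_contingency(5, 0, 1, 10)

    def test_fisher_option_consistent(self):
        chi2 = high_velocity_contingency(36, 90, 11, 75)
        fisher = high_velocity_contingency(36, 90, 11, 75, method="fisher")
        assert 0.0 <= fisher.p_value <= 1.0
        assert 0.0 <= chi2.p_value <= 1.0
        # both must call the association significant at this separation
        assert fisher.p_value < 0.01 and chi2.p_value < 0.01


def _make_records():
    records = []
    for i, (ratio, vel, ruptured) in enumerate(
        [(0.29, 0.08, True), (0.35, 0.06, True), (0.9, 0.02, False), (1.1, 0.015, False)]
    ):
        params = VesselParams(
            inlet_radius=3.0, outlet_inlet_area_ratio=ratio, inlet_velocity=vel, seed=i
        )
        g = generate_vessel(params)
        scheme = divide_segments(g, 15)
        sol = solve_steady_flow(g, BoundaryConditions(vel))
        records.append(build_vein_record(f"s{i}", ruptured, g, sol, scheme))
    return records


class TestCompareGroups:
    def test_quantile_convention_on_1_to_8(self):
        x = np.arange(1.0, 9.0)
        assert np.quantile(x, 0.25) == pytest.approx(2.75)
        assert np.quantile(x, 0.75) == pytest.approx(6.25)

    def test_single_value_groups_collapse(self):
        recs = _make_records()[:2]
        recs = [recs[0], dataclasses_replace_rupture(recs[1], False)]
        comp = compare_groups(recs, "pressure_avg")
        assert comp.median_a == comp.q1_a == comp.q3_a

    def test_direction_ruptured_pressure_higher(self):
        comp = compare_groups(_make_records(), "pressure_avg")
        assert comp.median_a > comp.median_b

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(_make_records(), "nonexistent_thing")

    def test_group_level_variables(self):
        comp = compare_groups(_make_records(), "group_wss_C")
        assert comp.median_a > comp.median_b


def dataclasses_replace_rupture(rec, value):
    import dataclasses

    return dataclasses.replace(rec, ruptured=value)


class TestPooledSegmentValues:
    def test_shapes_and_pooling(self):
        recs = _make_records()
        x, y = pooled_segment_values(recs, "wss", ruptured=True)
        assert x.size == y.size == 2 * 15
        assert set(np.unique(x)) == set(range(1, 16))

    def test_missing_group_rejected(self):
        recs = [r for r in _make_records() if r.ruptured]
        with pytest.raises(ValueError):
            pooled_segment_values(recs, "wss", ruptured=False)
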