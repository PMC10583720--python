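import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossfx.distributions import ObservedDistribution, estimate_observed_distribution
from crossfx.estimands import (
    Controlled,
    Dag,
    NaturalM1,
    PotentialOutcomeSpec,
    canonical_levels,
    make_effect,
)
from crossfx.lp_bounds import (
    ProfileDistribution,
    build_lp,
    counterfactual_value,
    enumerate_profiles,
    marginalize_q,
    realized_observation,
    sample_compatible_distribution,
    solve_bounds,
    true_effects_from_q,
)


class TestEnumeration:
    def test_profile_counts(self):
        assert enumerate_profiles(Dag.A).n_profiles == 4 * 4 * 256 == 4096
        assert enumerate_profiles(Dag.B).n_profiles == 4 * 16 * 256 == 16384

    def test_function_counts_follow_parent_rule(self):
        # 2^(2^k) functions for k binary parents
        assert enumerate_profiles(Dag.A).m2_tables.shape[0] == 4
        assert enumerate_profiles(Dag.B).m2_tables.shape[0] == 16
        assert enumerate_profiles(Dag.B).y_tables.shape[0] == 256

    def test_enumeration_order_truth_table_msb_first(self):
        space = enumerate_profiles(Dag.A)
        # function index 2 = binary 10: output 1 at x=0, 0 at x=1
        assert space.m1_tables[2].tolist() == [1, 0]
        assert space.m1_tables[1].tolist() == [0, 1]

    def test_profile_index_ordering(self):
        space = enumerate_profiles(Dag.B)
        # y index varies fastest, m1 slowest
        assert space.i_y[0] == 0 and space.i_y[1] == 1
        assert space.i_m1[0] == 0 and space.i_m1[16 * 256] == 1


class TestRealizedObservation:
    def test_all_zero_profile(self):
        space = enumerate_profiles(Dag.B)
        assert realized_observation(space, 0, profile=0) == (0, 0, 0)
        assert realized_observation(space, 1, profile=0) == (0, 0, 0)

    def test_composition(self):
        space = enumerate_profiles(Dag.A)
        # r_M1 = identity in x (index 0b01 = 1), r_M2 = const 1 (0b11 = 3),
        # r_Y(x, m1, m2) = m1 (truth table 00 11 00 11 -> 0b00110011 = 51)
        profile = np.flatnonzero(
            (space.i_m1 == 1) & (space.i_m2 == 3) & (space.i_y == 0b00110011)
        )[0]
        assert realized_observation(space, 1, profile=profile) == (1, 1, 1)
        assert realized_observation(space, 0, profile=profile) == (0, 1, 0)

    def test_deterministic_in_x(self):
        space = enumerate_profiles(Dag.B)
        m1a, m2a, ya = realized_observation(space, 0)
        m1b, m2b, yb = realized_observation(space, 0)
        assert np.array_equal(ya, yb) and np.array_equal(m2a, m2b)


class TestCounterfactualValue:
    def test_consistency_with_realized_observation(self):
        # Y(x) evaluated via the both-natural nesting equals the realized y
        space = enumerate_profiles(Dag.B)
        from crossfx.estimands import NaturalM2NaturalM1

        for x in (0, 1):
            po = PotentialOutcomeSpec(x, NaturalM1(x), NaturalM2NaturalM1(x, x))
            cf = counterfactual_value(space, po)
            _, _, y = realized_observation(space, x)
            assert np.array_equal(cf, y)

    def test_fully_controlled_reads_y_table(self):
        space = enumerate_profiles(Dag.A)
        po = PotentialOutcomeSpec(1, Controlled(0), Controlled(1))
        cf = counterfactual_value(space, po)
        assert np.array_equal(cf, space.y_tables[space.i_y, 1, 0, 1])

    def test_hand_composed_example(self):
        # r_M1 = identity, r_Y(x, m1, m2) = m1: Y(1, M1(0), 0) = r_Y(1, 0, 0) = 0
        space = enumerate_profiles(Dag.A)
        profile = int(
            np.flatnonzero((space.i_m1 == 1) & (space.i_y == 0b00110011))[0]
        )
        po = PotentialOutcomeSpec(1, NaturalM1(0), Controlled(0))
        assert counterfactual_value(space, po, profile=profile) == 0


class TestLPProblem:
    def test_constraint_matrix_shape_and_incidence(self, uniform_dist):
        for dag, ncol in ((Dag.A, 4096), (Dag.B, 16384)):
            spec = make_effect("crossA_M1nat", canonical_levels("crossA_M1nat"), dag)
            lp = build_lp(uniform_dist, spec, dag)
            assert lp.constraints.shape == (16, ncol)
            # each profile produces exactly one cell per arm
            assert np.array_equal(lp.constraints.sum(axis=0), np.full(ncol, 2.0))
            # the 8 rows of one arm partition the profiles
            assert np.array_equal(lp.constraints[:8].sum(axis=0), np.ones(ncol))

    def test_null_contrast_objective_is_zero(self, uniform_dist):
        spec = make_effect("crossA_M1nat", {"x": 1, "xp": 1, "x1": 0, "m2": 0}, Dag.B)
        lp = build_lp(uniform_dist, spec, Dag.B)
        assert not lp.objective.any()

    def test_dump_schema_round_trips(self, uniform_dist):
        spec = make_effect("crossA_M1nat", canonical_levels("crossA_M1nat"), Dag.A)
        lp = build_lp(uniform_dist, spec, Dag.A)
        d = lp.to_dict()
        dense = np.zeros(d["A"]["shape"])
        dense[d["A"]["rows"], d["A"]["cols"]] = d["A"]["values"]
        assert np.array_equal(dense, lp.constraints)


class TestSolveBounds:
    def test_uniform_table_reference_interval(self, uniform_dist):
        for dag in (Dag.A, Dag.B):
            spec = make_effect("crossA_M1nat", canonical_levels("crossA_M1nat"), dag)
            bi = solve_bounds(uniform_dist, spec, dag)
            assert bi.lower == pytest.approx(-0.75, abs=1e-8)
            assert bi.upper == pytest.approx(0.75, abs=1e-8)

    def test_constant_outcome_collapses_to_null(self, point_mass_dist):
        spec = make_effect(
            "crossB_M2ctrl_inner", canonical_levels("crossB_M2ctrl_inner"), Dag.B
        )
        bi = solve_bounds(point_mass_dist, spec, Dag.B)
        assert bi.lower == pytest.approx(0.0, abs=1e-8)
        assert bi.upper == pytest.approx(0.0, abs=1e-8)

    def test_total_effect_collapses_to_identified_point(self):
        dist, _ = sample_compatible_distribution(Dag.B, seed=17)
        spec = make_effect("total_effect", {"x": 1, "xp": 0}, Dag.B)
        bi = solve_bounds(dist, spec, Dag.B)
        te = dist.p[1].sum(axis=(0, 1))[1] - dist.p[1].sum(axis=(0, 1))[0]
        assert bi.lower == pytest.approx(te, abs=1e-7)
        assert bi.upper == pytest.approx(te, abs=1e-7)

    def test_intervals_within_unit_range(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            dist, _ = sample_compatible_distribution(Dag.B, seed=rng)
            for name in ("crossA_M1nat", "crossB_M2nat_inner_nat"):
                spec = make_effect(name, canonical_levels(name), Dag.B)
                bi = solve_bounds(dist, spec, Dag.B)
                assert -1.0 - 1e-9 <= bi.lower <= bi.upper <= 1.0 + 1e-9


class TestSampling:
    def test_tables_normalized_per_arm(self):
        dist, q = sample_compatible_distribution(Dag.A, seed=0)
        assert np.allclose(dist.p.sum(axis=(0, 1, 2)), 1.0, atol=1e-12)
        assert q.q.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_q_gives_deterministic_table(self):
        space = enumerate_profiles(Dag.A)
        q = np.zeros(space.n_profiles)
        q[123] = 1.0
        dist = marginalize_q(ProfileDistribution(q, Dag.A))
        assert set(np.unique(dist.p)) <= {0.0, 1.0}

    def test_large_concentration_approaches_uniform_q_marginal(self):
        dist, _ = sample_compatible_distribution(Dag.A, concentration=5e4, seed=1)
        space = enumerate_profiles(Dag.A)
        ref = marginalize_q(
            ProfileDistribution(np.full(space.n_profiles, 1 / space.n_profiles), Dag.A)
        )
        assert np.abs(dist.p - ref.p).max() < 0.01


class TestTruth:
    def test_null_contrast_truth_is_zero(self):
        _, q = sample_compatible_distribution(Dag.B, seed=9)
        spec = make_effect("crossA_M1nat", {"x": 1, "xp": 1, "x1": 0, "m2": 0}, Dag.B)
        assert true_effects_from_q(q, spec) == 0.0

    def test_point_mass_q_truth_is_difference_of_bits(self):
        space = enumerate_profiles(Dag.B)
        q = np.zeros(space.n_profiles)
        q[777] = 1.0
        pq = ProfileDistribution(q, Dag.B)
        spec = make_effect("crossA_M1nat", canonical_levels("crossA_M1nat"), Dag.B)
        assert true_effects_from_q(pq, spec) in (-1.0, 0.0, 1.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_truth_lies_within_lp_bounds(self, seed):
        dist, q = sample_compatible_distribution(Dag.A, seed=seed)
        for name in ("crossA_M1nat", "crossA_M2nat"):
            spec = make_effect(name, canonical_levels(name), Dag.A)
            bi = solve_bounds(dist, spec, Dag.A)
            assert bi.contains(true_effects_from_q(q, spec), tol=1e-8)
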