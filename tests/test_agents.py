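import math

import numpy as np
import pytest

from tommarket import (
    Belief,
    DegenerateEvidenceError,
    Item,
    PolicyTable,
    PriceSchedule,
    Scenario,
    TaskConfig,
    binary_softmax,
    build_grid,
    build_hierarchy,
    expected_revenue,
    irl_posterior,
    naive_policy_table,
    naive_stage1_policy,
    optimal_prices,
    planning_q,
    stage3_policy,
    total_buyer_utility,
    uniform_prior,
)
from tommarket.io import (
    read_policy_csv,
    read_price_csv,
    write_policy_csv,
    write_price_csv,
)


class TestBinarySoftmax:
    def test_equal_values_give_half(self):
        assert binary_softmax(3.0, 3.0, 0.5) == 0.5

    def test_zero_beta_gives_half(self):
        assert binary_softmax(100.0, -100.0, 0.0) == 0.5

    def test_logistic_of_scaled_difference(self):
        # beta * (q_self - q_other) = 0.5 * 12 = 6
        assert binary_softmax(12.0, 0.0, 0.5) == pytest.approx(1 / (1 + math.exp(-6)))

    def test_saturates_without_overflow(self):
        assert binary_softmax(1e6, -1e6, 1.0) == 1.0
        assert binary_softmax(-1e6, 1e6, 1.0) == 0.0


class TestNaiveBuyer:
    def test_symmetric_scenario_indifferent(self, default_config):
        assert naive_stage1_policy(Scenario(5.0, 5.0), default_config) == 0.5

    def test_hand_computed_example(self, default_config):
        # U1(apple) = 6, U1(orange) = -6; sigma(0.5 * 12)
        p = naive_stage1_policy(Scenario(d_apple=2.0, r_apple=8.0), default_config)
        assert p == pytest.approx(1 / (1 + math.exp(-6)), abs=1e-12)

    def test_policy_monotone_in_preference_and_distance(self, default_config):
        table = naive_policy_table(default_config).p_apple
        assert np.all(np.diff(table, axis=0) > 0)  # increasing in r
        assert np.all(np.diff(table, axis=1) < 0)  # decreasing in d

    def test_table_matches_scalar_policy(self, default_config, default_grid):
        table = naive_policy_table(default_config)
        for r in (0.0, 3.5, 10.0):
            for d in (0.0, 7.0):
                assert table.prob(default_config, r, d) == pytest.approx(
                    naive_stage1_policy(Scenario(d, r), default_config), abs=1e-15
                )


class TestStage3Policy:
    def test_symmetry_cases(self, default_config):
        assert stage3_policy(5.0, PriceSchedule(5.0), default_config) == 0.5
        # Q difference = 2(8 - 7) = 2 -> sigma(1)
        assert stage3_policy(8.0, PriceSchedule(7.0), default_config) == pytest.approx(
            1 / (1 + math.exp(-1))
        )

    def test_relabeling_symmetry(self, default_config):
        for r, m in [(8.0, 7.0), (2.5, 6.0), (0.0, 10.0)]:
            assert stage3_policy(r, PriceSchedule(m), default_config) == pytest.approx(
                1 - stage3_policy(10 - r, PriceSchedule(10 - m), default_config)
            )


class TestIRLPosterior:
    def test_constant_likelihood_returns_prior_exactly(self, default_config):
        n = default_config.n_points
        const = PolicyTable(level=-1, p_apple=np.full((n, n), 0.7))
        prior = uniform_prior(default_config)
        post = irl_posterior(const, Item.APPLE, 3.0, prior, default_config)
        assert np.allclose(post.masses, prior.masses, rtol=0, atol=1e-15)

    def test_three_point_hand_computation(self, coarse_config):
        # Likelihoods sigma(-5), 0.5, sigma(5) over {0, 5, 10} at d = 5.
        table = naive_policy_table(coarse_config)
        prior = uniform_prior(coarse_config)
        post = irl_posterior(table, Item.APPLE, 5.0, prior, coarse_config)
        lik = np.array([1 / (1 + math.exp(5)), 0.5, 1 / (1 + math.exp(-5))])
        assert post.masses == pytest.approx(lik / lik.sum(), abs=1e-9)
        assert post.masses == pytest.approx([0.00446, 0.33333, 0.66220], abs=1e-5)

    def test_posterior_monotone_when_likelihood_monotone(self, default_config):
        table = naive_policy_table(default_config)
        prior = uniform_prior(default_config)
        for d in build_grid(default_config):
            post = irl_posterior(table, Item.APPLE, d, prior, default_config)
            ratio = post.masses / prior.masses
            assert np.all(np.diff(ratio) >= -1e-15)

    def test_degenerate_evidence_raises(self, default_config):
        n = default_config.n_points
        zero = PolicyTable(level=-1, p_apple=np.zeros((n, n)))
        with pytest.raises(DegenerateEvidenceError):
            irl_posterior(zero, Item.APPLE, 3.0, uniform_prior(default_config), default_config)


class TestPricing:
    def test_midpoint_price_pays_midpoint_exactly(self, default_config):
        # At m = 5 both purchase branches pay 5, whatever the posterior.
        assert expected_revenue(5.0, uniform_prior(default_config), default_config) == pytest.approx(5.0)

    def test_eleven_point_oracle(self):
        # Independent plain-python sum over the unit lattice at m = 8.
        config = TaskConfig(grid_step=1.0)
        prior = uniform_prior(config)
        oracle = 0.0
        for r in range(11):
            p_buy = 1 / (1 + math.exp(-0.5 * 2 * (r - 8)))
            oracle += (1 / 11) * (8 * p_buy + 2 * (1 - p_buy))
        value = expected_revenue(8.0, prior, config)
        assert value == pytest.approx(oracle, abs=1e-12)
        assert value == pytest.approx(3.40, abs=5e-3)

    def test_revenue_mirror_invariance(self, default_config):
        # With a mirror-symmetric posterior, m and S - m earn the same.
        prior = uniform_prior(default_config)
        for m in (0.0, 2.5, 4.0):
            assert expected_revenue(m, prior, default_config) == pytest.approx(
                expected_revenue(10 - m, prior, default_config)
            )

    def test_uninformative_posterior_prices_at_midpoint(self, default_config):
        assert optimal_prices(uniform_prior(default_config), default_config).m_apple == 5.0

    def test_certain_high_preference_prices_high(self, default_config):
        masses = np.zeros(default_config.n_points)
        masses[-1] = 1.0  # buyer certainly values the apple at 10
        best = optimal_prices(Belief(masses), default_config)
        # Exhaustive independent scan of the price lattice.
        grid = build_grid(default_config)
        revs = [
            m * stage3_policy(10.0, PriceSchedule(m), default_config)
            + (10 - m) * (1 - stage3_policy(10.0, PriceSchedule(m), default_config))
            for m in grid
        ]
        assert best.m_apple == grid[int(np.argmax(revs))]
        assert best.m_apple >= 7.5

    def test_seller_table_relabeling_symmetry(self, default_hierarchy, default_config):
        grid = build_grid(default_config)
        for level in (0, 2):
            table = default_hierarchy.prices(level)
            for j, d in enumerate(grid):
                mirror = table.m_apple[len(grid) - 1 - j, 1]
                assert abs(table.m_apple[j, 0] - (10 - mirror)) <= default_config.grid_step + 1e-9


class TestPlanning:
    def test_flat_price_response_collapses_to_naive(self, default_config, default_hierarchy):
        # If the seller's response ignores the observation, the stage-3 term
        # cancels and the planner behaves exactly like the naive buyer.
        from tommarket import PriceTable

        n = default_config.n_points
        flat = PriceTable(level=0, m_apple=np.full((n, 2), 6.0))
        for r, d in [(8.0, 2.0), (3.0, 7.5), (5.0, 5.0)]:
            q_a, q_o = planning_q(Scenario(d, r), flat, default_config)
            naive_diff = 2 * (r - d)
            assert q_a - q_o == pytest.approx(naive_diff, abs=1e-12)

    def test_matches_game_tree_enumeration_on_coarse_grid(self, coarse_config, coarse_hierarchy):
        # Brute-force oracle: enumerate every (first move, purchase) path and
        # weight by the purchase softmax.
        table = coarse_hierarchy.prices(0)
        grid = build_grid(coarse_config)
        for r in grid:
            for d in grid:
                scenario = Scenario(d, r)
                expected = []
                for first in (Item.APPLE, Item.ORANGE):
                    prices = table.schedule(coarse_config, d, first)
                    p_apple = stage3_policy(r, prices, coarse_config)
                    q = 0.0
                    for third, weight in ((Item.APPLE, p_apple), (Item.ORANGE, 1 - p_apple)):
                        q += weight * total_buyer_utility(scenario, prices, first, third)
                    expected.append(q)
                q_a, q_o = planning_q(scenario, table, coarse_config)
                assert q_a == pytest.approx(expected[0], abs=1e-12)
                assert q_o == pytest.approx(expected[1], abs=1e-12)

    def test_relabeling_symmetry_of_q(self, default_config, default_hierarchy):
        table = default_hierarchy.prices(0)
        for r, d in [(8.0, 2.0), (1.5, 9.0), (6.0, 4.5)]:
            q_a, _ = planning_q(Scenario(d, r), table, default_config)
            _, q_o = planning_q(Scenario(10 - d, 10 - r), table, default_config)
            assert q_a == pytest.approx(q_o, abs=1e-9)


class TestHierarchy:
    def test_minimal_hierarchy(self):
        h = build_hierarchy(TaskConfig(max_level=-1))
        assert h.levels == [-1]

    def test_default_structure(self, default_hierarchy):
        assert default_hierarchy.levels == [-1, 0, 1, 2, 3]
        for level in (-1, 1, 3):
            assert default_hierarchy.policy(level).p_apple.shape == (21, 21)
        for level in (0, 2):
            assert default_hierarchy.prices(level).m_apple.shape == (21, 2)

    def test_rebuild_is_bit_identical(self, default_config, default_hierarchy):
        rebuilt = build_hierarchy(default_config)
        for level in default_hierarchy.levels:
            a, b = default_hierarchy.tables[level], rebuilt.tables[level]
            field = "p_apple" if hasattr(a, "p_apple") else "m_apple"
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_policy_mirror_symmetry_every_level(self, default_hierarchy):
        for level in (-1, 1, 3):
            p = default_hierarchy.policy(level).p_apple
            assert np.max(np.abs(p + p[::-1, ::-1] - 1)) < 1e-9

    def test_policies_strictly_interior(self, default_hierarchy):
        for level in (-1, 1, 3):
            p = default_hierarchy.policy(level).p_apple
            assert np.all(p > 0) and np.all(p < 1)

    def test_prices_lie_on_grid(self, default_hierarchy, default_grid):
        for level in (0, 2):
            m = default_hierarchy.prices(level).m_apple
            assert np.all(np.isin(m, default_grid))

    def test_zero_beta_collapses_everything(self):
        h = build_hierarchy(TaskConfig(beta=0.0))
        for level in (-1, 1, 3):
            assert np.all(h.policy(level).p_apple == 0.5)
        config = h.config
        prior = uniform_prior(config)
        post = irl_posterior(h.policy(-1), Item.APPLE, 3.0, prior, config)
        assert np.allclose(post.masses, prior.masses, rtol=0, atol=1e-15)

    def test_large_beta_naive_policy_is_step_at_r_equals_d(self):
        config = TaskConfig(beta=100.0)
        table = naive_policy_table(config).p_apple
        grid = build_grid(config)
        r, d = np.meshgrid(grid, grid, indexing="ij")
        off_boundary = np.abs(r - d) > 1e-9
        indicator = (r > d).astype(float)
        assert np.max(np.abs(table - indicator)[off_boundary]) < 1e-6

    def test_posterior_after_apple_dominates_prior(self, default_config, default_hierarchy):
        # First-order stochastic dominance of the level-0 posterior over the
        # flat prior whenever the naive likelihood increases with preference.
        prior = uniform_prior(default_config)
        table = default_hierarchy.policy(-1)
        for d in (0.0, 2.5, 5.0, 9.0):
            post = irl_posterior(table, Item.APPLE, d, prior, default_config)
            assert np.all(np.cumsum(post.masses) <= np.cumsum(prior.masses) + 1e-12)


class TestCSVRoundTrip:
    def test_policy_and_price_tables(self, tmp_path, default_hierarchy, default_config):
        policy = default_hierarchy.policy(1)
        path = tmp_path / "policy.csv"
        write_policy_csv(policy, default_config, path)
        back = read_policy_csv(path)
        assert back.level == 1
        assert np.allclose(back.p_apple, policy.p_apple, atol=1e-12)

        prices = default_hierarchy.prices(2)
        path = tmp_path / "prices.csv"
        write_price_csv(prices, default_config, path)
        back = read_price_csv(path)
        assert back.level == 2
        assert np.array_equal(back.m_apple, prices.m_apple)
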