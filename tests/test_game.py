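"""Unit and property tests of the harvesting-game mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harvestgame.game import (
    GameConfig,
    bonus_payment,
    draw_replenish_fraction,
    play_game,
    step,
    threshold_policy,
    time_penalty,
)


class TestReplenishmentDraws:
    def test_degenerate_sd_returns_mean(self, rng):
        config = GameConfig(replenish_sd=0.0)
        assert all(
            draw_replenish_fraction(config, rng) == 0.15 for _ in range(10)
        )

    def test_sample_mean_matches_stated_moments(self):
        config = GameConfig()
        rng = np.random.default_rng(7)
        draws = np.array(
            [draw_replenish_fraction(config, rng) for _ in range(100_000)]
        )
        assert abs(draws.mean() - 0.15) < 3 * 0.03 / np.sqrt(100_000)

    def test_clamp_keeps_draws_non_negative(self):
        # a mean near zero makes the clamp actually bind
        config = GameConfig(replenish_mean=0.01, replenish_sd=0.03)
        rng = np.random.default_rng(11)
        draws = [draw_replenish_fraction(config, rng) for _ in range(100_000)]
        assert min(draws) >= 0.0


class TestStep:
    def test_full_harvest_empties_absorbing_pool(self, default_game, rng):
        next_resource, event = step(60, 60, default_game, rng)
        assert next_resource == 0
        assert event.post_replenish_resource == 0

    def test_zero_harvest_truncates_at_cap(self, default_game, rng):
        next_resource, _ = step(60, 0, default_game, rng)
        assert next_resource == 60

    def test_update_rule_at_exact_mean_fraction(self, rng):
        # remainder 51, fraction 0.15 -> replenishment round(7.65) = 8
        config = GameConfig(replenish_sd=0.0)
        next_resource, event = step(60, 9, config, rng)
        assert next_resource == 59
        assert event.replenish_fraction_drawn == 0.15

    @pytest.mark.parametrize("harvest", [-1, 61])
    def test_infeasible_harvest_raises(self, default_game, rng, harvest):
        with pytest.raises(ValueError, match="infeasible"):
            step(60, harvest, default_game, rng)


class TestPayments:
    @pytest.mark.parametrize(
        "round_, expected", [(10, 240.0), (50, 0.0), (49, 6.0), (70, 0.0)]
    )
    def test_time_penalty(self, round_, expected):
        assert time_penalty(round_) == expected

    def test_non_positive_round_rejected(self):
        with pytest.raises(ValueError):
            time_penalty(0)

    @pytest.mark.parametrize(
        "points, usd", [(100, 0.50), (600, 3.00), (10_000, 3.00), (0, 0.0)]
    )
    def test_bonus_payment(self, points, usd):
        assert bonus_payment(points) == pytest.approx(usd)


class TestPlayGame:
    def test_harvest_everything_lasts_one_round(self, default_game, rng):
        traj = play_game(lambda s, r: s, default_game, rng)
        assert traj.rounds_lasted == 1
        assert traj.total_rewards == 60
        assert traj.exhausted
        assert traj.penalty_seconds == 6 * 49
        assert traj.bonus_usd == pytest.approx(0.30)

    def test_never_harvesting_lasts_the_full_game(self, default_game, rng):
        traj = play_game(lambda s, r: 0, default_game, rng)
        assert traj.rounds_lasted == 70
        assert traj.total_rewards == 0
        assert not traj.exhausted
        assert traj.penalty_seconds == 0

    def test_infeasible_policy_error_names_the_round(self, default_game, rng):
        with pytest.raises(ValueError, match="round 1"):
            play_game(lambda s, r: s + 1, default_game, rng)

    def test_target_51_beats_coarser_targets(self, default_game):
        """Monte-Carlo policy comparison: harvesting to 51 out-earns
        noticeably different targets."""
        means = {}
        for target in (40, 45, 51, 60):
            rng = np.random.default_rng(2024)
            totals = [
                play_game(threshold_policy(target), default_game, rng).total_rewards
                for _ in range(2000)
            ]
            means[target] = np.mean(totals)
        assert all(means[51] > means[t] for t in (40, 45, 60))

    def test_summaries_consistent_with_events(self, default_game):
        rng = np.random.default_rng(5)
        traj = play_game(threshold_policy(30), default_game, rng)
        assert traj.rounds_lasted == len(traj.events)
        assert traj.total_rewards == sum(e.harvest for e in traj.events)


@st.composite
def _policy_and_seed(draw):
    target = draw(st.integers(min_value=0, max_value=60))
    frac = draw(st.floats(min_value=0.0, max_value=1.0))
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    return target, frac, seed


class TestGameInvariants:
    @settings(max_examples=40, deadline=None)
    @given(_policy_and_seed())
    def test_resource_stays_in_bounds_and_zero_absorbs(self, params):
        target, frac, seed = params
        config = GameConfig()

        def policy(s, r):  # erratic mix of threshold and proportional play
            return max(0, min(s, int(round((s - target) * frac + s * (1 - frac)))))

        traj = play_game(policy, config, np.random.default_rng(seed))
        resources = [e.post_replenish_resource for e in traj.events]
        assert all(0 <= x <= config.max_resource for x in resources)
        if traj.exhausted:
            assert resources[-1] == 0
            assert traj.events[-1].harvest == traj.events[-1].pre_harvest_resource

    @settings(max_examples=25, deadline=None)
    @given(_policy_and_seed())
    def test_conservation_of_points(self, params):
        target, _, seed = params
        config = GameConfig()
        traj = play_game(threshold_policy(target), config, np.random.default_rng(seed))
        replenished = sum(
            e.post_replenish_resource - (e.pre_harvest_resource - e.harvest)
            for e in traj.events
        )
        assert traj.total_rewards <= config.initial_resource + replenished + 1e-9

    def test_fixed_seed_reproducibility(self, default_game):
        runs = [
            play_game(threshold_policy(45), default_game, np.random.default_rng(99))
            for _ in range(2)
        ]
        assert runs[0].events == runs[1].events
        assert runs[0].summary() == runs[1].summary()
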