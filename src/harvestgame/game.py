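"""Single-player stochastic resource-harvesting game.

A player faces a pool of resource points (60 at the start). Each round they
harvest any number of points; the remainder then replenishes by a random
fraction drawn from a Gaussian (mean 15%, sd 3% of the remainder), truncated
so the pool never exceeds its cap. The game ends when the pool is emptied or
after 70 rounds. Harvested points convert to a capped monetary bonus, and
emptying the pool before round 50 incurs a waiting-time penalty of 6 seconds
per round remaining to round 50.

All randomness flows through an explicit :class:`numpy.random.Generator`, so
trajectories are exactly reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GameConfig",
    "HarvestEvent",
    "Trajectory",
    "draw_replenish_fraction",
    "step",
    "play_game",
    "time_penalty",
    "bonus_payment",
    "threshold_policy",
    "noisy_threshold_policy",
    "trajectories_to_frame",
    "summaries_to_frame",
]

#: Policy callables receive ``(resource, round_index)`` and return a harvest.
Policy = Callable[[int, int], float]


@dataclass(frozen=True)
class GameConfig:
    """All parameters of the harvesting game.

    Defaults reproduce the study conditions: a 60-point pool, proportional
    Gaussian replenishment with mean 0.15 and sd 0.03, a 70-round horizon,
    $0.005 per harvested point capped at $3.00, and a 6 s/round waiting
    penalty for exhausting the pool before round 50.
    """

    initial_resource: int = 60
    max_resource: int = 60
    max_rounds: int = 70
    replenish_mean: float = 0.15
    replenish_sd: float = 0.03
    reward_value: float = 0.005
    bonus_cap: float = 3.00
    penalty_cutoff_round: int = 50
    penalty_per_round: float = 6.0
    show_rounds_remaining: bool = False
    integer_mode: bool = True
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.initial_resource <= self.max_resource:
            raise ValueError("require 0 < initial_resource <= max_resource")
        if self.replenish_mean <= 0:
            raise ValueError("replenish_mean must be positive")
        if self.replenish_sd < 0:
            raise ValueError("replenish_sd must be non-negative")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be at least 1")
        for name in ("reward_value", "bonus_cap", "penalty_per_round"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.penalty_cutoff_round < 0:
            raise ValueError("penalty_cutoff_round must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass(frozen=True)
class HarvestEvent:
    """One round of play: harvest, then proportional replenishment."""

    round_index: int  # 1-based
    pre_harvest_resource: float
    harvest: float
    replenish_fraction_drawn: float
    post_replenish_resource: float


@dataclass
class Trajectory:
    """A complete game: its events plus the outcome summaries."""

    events: list[HarvestEvent] = field(default_factory=list)
    rounds_lasted: int = 0
    total_rewards: float = 0.0
    exhausted: bool = False
    penalty_seconds: float = 0.0
    bonus_usd: float = 0.0

    @property
    def replenish_fractions(self) -> np.ndarray:
        return np.array([e.replenish_fraction_drawn for e in self.events])

    def to_frame(self, participant_id: str | int | None = None) -> pd.DataFrame:
        rows = [
            {
                "participant_id": participant_id,
                "round": e.round_index,
                "pre_harvest": e.pre_harvest_resource,
                "harvest": e.harvest,
                "fraction_drawn": e.replenish_fraction_drawn,
                "post_replenish": e.post_replenish_resource,
            }
            for e in self.events
        ]
        return pd.DataFrame(rows)

    def summary(self, participant_id: str | int | None = None) -> dict:
        d = {
            "participant_id": participant_id,
            "rounds_lasted": self.rounds_lasted,
            "total_rewards": self.total_rewards,
            "exhausted": self.exhausted,
            "penalty_seconds": self.penalty_seconds,
            "bonus_usd": self.bonus_usd,
        }
        if participant_id is None:
            d.pop("participant_id")
        return d


def draw_replenish_fraction(config: GameConfig, rng: np.random.Generator) -> float:
    """Draw one replenishment fraction: Gaussian, clamped below at zero.

    At the default mean (0.15) and sd (0.03) a negative draw is a five-sigma
    event, so the clamp is effectively never active; it exists to keep the
    update rule well defined for any configuration.
    """
    return max(0.0, float(rng.normal(config.replenish_mean, config.replenish_sd)))


def _round_points(x: float) -> int:
    # round-half-even, fixed for reproducibility of integer-mode games
    return int(np.rint(x))


def step(
    resource: float,
    harvest: float,
    config: GameConfig,
    rng: np.random.Generator,
    round_index: int = 1,
) -> tuple[float, HarvestEvent]:
    """Apply one round's update: remove the harvest, replenish the remainder.

    The remainder grows by ``round(remainder * f)`` points (``remainder * f``
    in continuous mode) where ``f`` is the drawn fraction, truncated at the
    resource cap. An empty remainder stays empty: zero is absorbing.
    """
    if harvest < 0 or harvest > resource:
        raise ValueError(
            f"infeasible harvest {harvest!r} from resource {resource!r} "
            f"at round {round_index}"
        )
    remainder = resource - harvest
    fraction = draw_replenish_fraction(config, rng)
    if config.integer_mode:
        replenishment: float = _round_points(remainder * fraction)
    else:
        replenishment = remainder * fraction
    next_resource = min(config.max_resource, remainder + replenishment)
    if remainder == 0:
        next_resource = 0
    event = HarvestEvent(
        round_index=round_index,
        pre_harvest_resource=resource,
        harvest=harvest,
        replenish_fraction_drawn=fraction,
        post_replenish_resource=next_resource,
    )
    return next_resource, event


def play_game(
    policy: Policy,
    config: GameConfig,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Play one full game under ``policy``.

    ``policy(resource, round_index)`` must return a feasible harvest. The
    game stops at exhaustion (pool emptied by a harvest) or after
    ``max_rounds`` rounds. The same seed and policy reproduce the same
    trajectory exactly.
    """
    if rng is None:
        rng = config.rng()
    traj = Trajectory()
    resource: float = config.initial_resource
    for round_index in range(1, config.max_rounds + 1):
        harvest = policy(resource, round_index)
        if config.integer_mode:
            harvest = int(harvest)
        if harvest < 0 or harvest > resource:
            raise ValueError(
                f"policy returned infeasible harvest {harvest!r} for "
                f"resource {resource!r} at round {round_index}"
            )
        resource, event = step(resource, harvest, config, rng, round_index)
        traj.events.append(event)
        traj.total_rewards += event.harvest
        if resource == 0:
            traj.exhausted = True
            break
    traj.rounds_lasted = len(traj.events)
    if traj.exhausted:
        traj.penalty_seconds = time_penalty(traj.rounds_lasted, config)
    traj.bonus_usd = bonus_payment(traj.total_rewards, config)
    return traj


def time_penalty(depletion_round: int, config: GameConfig = GameConfig()) -> float:
    """Waiting penalty for exhausting the pool at ``depletion_round``.

    Six seconds (by default) for every round remaining between the depletion
    round and round 50; depleting at round 10 costs 40 x 6 = 240 seconds.
    """
    if depletion_round < 1:
        raise ValueError("depletion_round must be a positive round number")
    remaining = max(0, config.penalty_cutoff_round - depletion_round)
    return config.penalty_per_round * remaining


def bonus_payment(total_rewards: float, config: GameConfig = GameConfig()) -> float:
    """Monetary bonus: $0.005 per harvested point, capped at $3.00."""
    if total_rewards < 0:
        raise ValueError("total_rewards must be non-negative")
    return min(config.bonus_cap, total_rewards * config.reward_value)


def threshold_policy(target: float) -> Policy:
    """Harvest down to ``target``: take ``max(0, resource - target)``."""

    def policy(resource: float, round_index: int) -> float:
        return max(0.0, resource - target)

    return policy


def noisy_threshold_policy(
    target: float, noise_sd: float, rng: np.random.Generator
) -> Policy:
    """A threshold harvester with per-round Gaussian execution noise.

    The intended harvest ``resource - target`` is perturbed by
    ``N(0, noise_sd)``, rounded, and clipped to the feasible range. Unlike
    the exact threshold policy, a noisy agent with a low target can overshoot
    and empty the pool, which is what produces early exhaustion.
    """

    def policy(resource: float, round_index: int) -> float:
        intended = resource - target + rng.normal(0.0, noise_sd)
        return float(np.clip(np.rint(intended), 0, resource))

    return policy


def trajectories_to_frame(
    trajectories: Iterable[Trajectory],
    participant_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Long event table: one row per harvest event across trajectories."""
    frames = []
    for i, traj in enumerate(trajectories):
        pid = participant_ids[i] if participant_ids is not None else i
        frames.append(traj.to_frame(pid))
    return pd.concat(frames, ignore_index=True)


def summaries_to_frame(
    trajectories: Iterable[Trajectory],
    participant_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Per-participant outcome summary table."""
    rows = []
    for i, traj in enumerate(trajectories):
        pid = participant_ids[i] if participant_ids is not None else i
        rows.append(traj.summary(pid))
    return pd.DataFrame(rows)


def config_to_dict(config: GameConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> GameConfig:
    known = {f for f in GameConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown GameConfig fields: {sorted(unknown)}")
    return GameConfig(**d)


def save_trajectories(
    trajectories: Sequence[Trajectory],
    events_path: str | Path,
    summary_path: str | Path,
    participant_ids: Sequence | None = None,
) -> None:
    trajectories_to_frame(trajectories, participant_ids).to_csv(
        events_path, index=False
    )
    summaries_to_frame(trajectories, participant_ids).to_csv(
        summary_path, index=False
    )
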