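"""The three-stage buyer-seller game and its parameterization.

A buyer walks down one arm of a T-maze to consume one of two items (an apple
or an orange), paying a travel cost equal to the distance.  A seller watches
that first choice, infers the buyer's preferences, and sets prices.  The
buyer then has to purchase one of the items at the posted price.

Preferences, distances and prices each sum to a common constant ``S``
(10 by default), so every pair is stored as its apple component only and
the orange component is derived.  All agents reason on a uniform lattice
``{0, step, 2*step, ..., S}``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Item",
    "PricingObjective",
    "ConfigError",
    "TaskConfig",
    "Scenario",
    "PriceSchedule",
    "build_grid",
    "grid_index",
    "stage1_utility",
    "stage3_utility",
    "seller_reward",
    "total_buyer_utility",
    "load_config",
]


class Item(enum.Enum):
    """One of the two goods in the maze."""

    APPLE = "apple"
    ORANGE = "orange"

    @property
    def other(self) -> "Item":
        return Item.ORANGE if self is Item.APPLE else Item.APPLE


class PricingObjective(enum.Enum):
    """What the seller maximizes when setting the apple price.

    JOINT: expected revenue summed over both purchase branches, the faithful
    expectation of the seller's payoff (it is paid whichever item is bought).
    CHOSEN_ONLY: only the queried item's revenue term, i.e. the literal
    single-item maximization.
    """

    JOINT = "joint"
    CHOSEN_ONLY = "chosen-only"


class ConfigError(ValueError):
    """A task configuration violates an invariant; names the offending field."""


@dataclass(frozen=True)
class TaskConfig:
    """Global constants of the game.

    Parameters
    ----------
    sum_total:
        The shared sum constraint ``S`` for preferences, distances and
        prices (reward/money units).
    grid_step:
        Spacing of the discretization lattice.  Must divide ``sum_total``.
    beta:
        Inverse temperature of the softmax choice rule (unitless).
    log_base:
        Base for all entropy/KL quantities; 2 reports bits.
    pricing_objective:
        See :class:`PricingObjective`.
    max_level:
        Highest theory-of-mind level tabulated by
        :func:`tommarket.agents.build_hierarchy`.
    beta_overrides:
        Optional per-level inverse temperatures; levels not listed use the
        shared ``beta``.
    """

    sum_total: float = 10.0
    grid_step: float = 0.5
    beta: float = 0.5
    log_base: float = 2.0
    pricing_objective: PricingObjective = PricingObjective.JOINT
    max_level: int = 3
    beta_overrides: Mapping[int, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.sum_total > 0:
            raise ConfigError(f"sum_total must be > 0, got {self.sum_total}")
        if not self.grid_step > 0:
            raise ConfigError(f"grid_step must be > 0, got {self.grid_step}")
        n = self.sum_total / self.grid_step
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(
                f"grid_step: {self.grid_step} does not divide sum_total {self.sum_total}"
            )
        if self.beta < 0:
            raise ConfigError(f"beta must be >= 0, got {self.beta}")
        if self.log_base <= 0 or self.log_base == 1:
            raise ConfigError(f"log_base must be positive and != 1, got {self.log_base}")
        if self.max_level < -1:
            raise ConfigError(f"max_level must be >= -1, got {self.max_level}")

    @property
    def n_points(self) -> int:
        """Number of lattice points, ``S / step + 1``."""
        return int(round(self.sum_total / self.grid_step)) + 1

    def beta_for(self, level: int) -> float:
        if self.beta_overrides and level in self.beta_overrides:
            return float(self.beta_overrides[level])
        return self.beta

    def canonical_dict(self) -> dict:
        """JSON-serializable snapshot used for provenance hashing."""
        d = {
            "sum_total": self.sum_total,
            "grid_step": self.grid_step,
            "beta": self.beta,
            "log_base": self.log_base,
            "pricing_objective": self.pricing_objective.value,
            "max_level": self.max_level,
        }
        if self.beta_overrides:
            d["beta_overrides"] = {str(k): v for k, v in sorted(self.beta_overrides.items())}
        return d


@dataclass(frozen=True)
class Scenario:
    """One maze instantiation, stored as its apple components only.

    ``d_apple`` is the walking distance to the apple and ``r_apple`` the
    reward from consuming it; the orange values are implied by the sum
    constraint and exposed as derived accessors so the constraint cannot
    be violated.
    """

    d_apple: float
    r_apple: float
    sum_total: float = 10.0

    def __post_init__(self) -> None:
        for name in ("d_apple", "r_apple"):
            v = getattr(self, name)
            if not 0 <= v <= self.sum_total:
                raise ConfigError(f"{name} must lie in [0, {self.sum_total}], got {v}")

    @property
    def d_orange(self) -> float:
        return self.sum_total - self.d_apple

    @property
    def r_orange(self) -> float:
        return self.sum_total - self.r_apple

    def distance(self, item: Item) -> float:
        return self.d_apple if item is Item.APPLE else self.d_orange

    def reward(self, item: Item) -> float:
        return self.r_apple if item is Item.APPLE else self.r_orange

    def mirrored(self) -> "Scenario":
        """The same maze with the item labels swapped."""
        return Scenario(self.d_orange, self.r_orange, self.sum_total)


@dataclass(frozen=True)
class PriceSchedule:
    """Posted prices, stored as the apple price only."""

    m_apple: float
    sum_total: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.m_apple <= self.sum_total:
            raise ConfigError(
                f"m_apple must lie in [0, {self.sum_total}], got {self.m_apple}"
            )

    @property
    def m_orange(self) -> float:
        return self.sum_total - self.m_apple

    def price(self, item: Item) -> float:
        return self.m_apple if item is Item.APPLE else self.m_orange


def build_grid(config: TaskConfig) -> np.ndarray:
    """The lattice ``{0, step, ..., sum_total}`` on which agents reason."""
    return np.linspace(0.0, config.sum_total, config.n_points)


def grid_index(config: TaskConfig, value: float) -> int:
    """Index of ``value`` on the lattice; raises if it is off-lattice."""
    idx = value / config.grid_step
    if abs(idx - round(idx)) > 1e-9 or not 0 <= round(idx) < config.n_points:
        raise ConfigError(f"value {value} does not lie on the grid")
    return int(round(idx))


def stage1_utility(scenario: Scenario, choice: Item) -> float:
    """First-stage utility: reward minus the distance walked to the item."""
    return scenario.reward(choice) - scenario.distance(choice)


def stage3_utility(scenario: Scenario, prices: PriceSchedule, choice: Item) -> float:
    """Purchase-stage utility: reward minus the posted price."""
    return scenario.reward(choice) - prices.price(choice)


def seller_reward(prices: PriceSchedule, bought: Item) -> float:
    """The seller is paid the price of whichever item the buyer buys."""
    return prices.price(bought)


def total_buyer_utility(
    scenario: Scenario, prices: PriceSchedule, first: Item, third: Item
) -> float:
    """Undiscounted sum of the two stage utilities."""
    return stage1_utility(scenario, first) + stage3_utility(scenario, prices, third)


_CONFIG_KEYS = {
    "sum_total": float,
    "grid_step": float,
    "beta": float,
    "log_base": float,
    "max_level": int,
}


def load_config(path: str | Path, **overrides) -> TaskConfig:
    """Read a flat YAML or JSON file into a :class:`TaskConfig`.

    Keyword arguments override file values; ``None`` overrides are ignored,
    so CLI flags can be passed through unconditionally.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a flat mapping")
    kwargs = {}
    for key, value in raw.items():
        if key in _CONFIG_KEYS:
            kwargs[key] = _CONFIG_KEYS[key](value)
        elif key == "pricing_objective":
            kwargs[key] = PricingObjective(value)
        else:
            raise ConfigError(f"unknown config key {key!r} in {path}")
    for key, value in overrides.items():
        if value is not None:
            kwargs[key] = value
    return TaskConfig(**kwargs)


def with_overrides(config: TaskConfig, **overrides) -> TaskConfig:
    """A copy of ``config`` with non-None overrides applied."""
    clean = {k: v for k, v in overrides.items() if v is not None}
    return replace(config, **clean) if clean else config
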