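"""The alternating theory-of-mind hierarchy of buyers and sellers.

Buyers occupy the odd levels and sellers the even ones, bottoming out at the
naive level -1 buyer:

* ToM(-1) buyer: maximizes each stage separately with a softmax policy.
* ToM(0) seller: Bayesian inverse reinforcement learning (IRL) on the
  ToM(-1) first move, then revenue-maximizing deterministic prices.
* ToM(1) buyer: plans *through* the ToM(0) seller's inference and pricing,
  choosing its first move to shape the price it will later face.
* ToM(2) seller: same IRL machinery, but with the ToM(1) policy as its
  likelihood, which makes it skeptical of bluffable signals.
* ToM(3) buyer: plans through the ToM(2) seller, and so on.

Each level reads only the tabulated artifact of the level directly below it
(strict nesting), so the whole hierarchy is built bottom-up with one table
per level and no nested recursion.  The pipeline contains no randomness:
identical configurations produce bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Union

import numpy as np
from scipy.special import expit

from .environment import (
    ConfigError,
    Item,
    PriceSchedule,
    PricingObjective,
    Scenario,
    TaskConfig,
    build_grid,
    grid_index,
    stage1_utility,
)

__all__ = [
    "Belief",
    "PolicyTable",
    "PriceTable",
    "Hierarchy",
    "DegenerateEvidenceError",
    "binary_softmax",
    "naive_stage1_policy",
    "naive_policy_table",
    "stage3_policy",
    "uniform_prior",
    "irl_posterior",
    "expected_revenue",
    "optimal_prices",
    "seller_price_table",
    "planning_q",
    "planning_policy_table",
    "build_hierarchy",
]


class DegenerateEvidenceError(ValueError):
    """The assumed policy gives the observation zero probability everywhere."""


@dataclass(frozen=True)
class Belief:
    """Probability masses over the ``r_apple`` lattice."""

    masses: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", m)
        if np.any(m < 0):
            raise ValueError("belief masses must be non-negative")
        if abs(m.sum() - 1.0) > 1e-12:
            raise ValueError(f"belief masses must sum to 1, got {m.sum()!r}")


@dataclass(frozen=True)
class PolicyTable:
    """A buyer level's first-move policy on the (r_apple, d_apple) lattice.

    ``p_apple[i, j]`` is the probability of walking to the apple when the
    apple reward is ``grid[i]`` and the apple distance is ``grid[j]``.
    """

    level: int
    p_apple: np.ndarray  # shape (n_r, n_d)

    def prob(self, config: TaskConfig, r_apple: float, d_apple: float) -> float:
        return float(
            self.p_apple[grid_index(config, r_apple), grid_index(config, d_apple)]
        )

    def likelihood(self, config: TaskConfig, observed: Item, d_apple: float) -> np.ndarray:
        """P(observed | r, d) as a vector over the preference lattice."""
        col = self.p_apple[:, grid_index(config, d_apple)]
        return col if observed is Item.APPLE else 1.0 - col


@dataclass(frozen=True)
class PriceTable:
    """A seller level's deterministic price schedule.

    ``m_apple[j, k]`` is the apple price after observing first choice
    ``k`` (0 = apple, 1 = orange) at apple distance ``grid[j]``.
    """

    level: int
    m_apple: np.ndarray  # shape (n_d, 2)

    def schedule(self, config: TaskConfig, d_apple: float, observed: Item) -> PriceSchedule:
        j = grid_index(config, d_apple)
        k = 0 if observed is Item.APPLE else 1
        return PriceSchedule(float(self.m_apple[j, k]), config.sum_total)


@dataclass(frozen=True)
class Hierarchy:
    """Per-level tables, buyers (PolicyTable) at odd levels and sellers
    (PriceTable) at even ones, from -1 up to ``config.max_level``."""

    config: TaskConfig
    tables: Dict[int, Union[PolicyTable, PriceTable]]

    def policy(self, level: int) -> PolicyTable:
        table = self.tables[level]
        if not isinstance(table, PolicyTable):
            raise KeyError(f"level {level} is a seller level, not a buyer level")
        return table

    def prices(self, level: int) -> PriceTable:
        table = self.tables[level]
        if not isinstance(table, PriceTable):
            raise KeyError(f"level {level} is a buyer level, not a seller level")
        return table

    @property
    def levels(self) -> list[int]:
        return sorted(self.tables)


def binary_softmax(q_self, q_other, beta: float):
    """Two-action softmax: the logistic of the scaled value difference."""
    return expit(beta * (np.asarray(q_self, dtype=float) - q_other))


def uniform_prior(config: TaskConfig) -> Belief:
    """The flat prior over the preference lattice used by every seller."""
    n = config.n_points
    return Belief(np.full(n, 1.0 / n))


def naive_stage1_policy(scenario: Scenario, config: TaskConfig) -> float:
    """ToM(-1) first move: softmax over the two stage-one utilities."""
    q_apple = stage1_utility(scenario, Item.APPLE)
    q_orange = stage1_utility(scenario, Item.ORANGE)
    return float(binary_softmax(q_apple, q_orange, config.beta_for(-1)))


def naive_policy_table(config: TaskConfig) -> PolicyTable:
    # U1(apple) - U1(orange) = 2 (r - d) under the sum constraint.
    grid = build_grid(config)
    diff = 2.0 * (grid[:, None] - grid[None, :])
    return PolicyTable(level=-1, p_apple=expit(config.beta_for(-1) * diff))


def stage3_policy(r_apple: float, prices: PriceSchedule, config: TaskConfig) -> float:
    """Purchase-stage softmax, shared by every buyer level and by every
    seller's forecast of the buyer's purchase."""
    diff = 2.0 * (r_apple - prices.m_apple)
    return float(expit(config.beta * diff))


def irl_posterior(
    assumed_policy: PolicyTable,
    observed: Item,
    d_apple: float,
    prior: Belief,
    config: TaskConfig,
) -> Belief:
    """Bayesian inverse reinforcement learning over the preference lattice.

    The posterior mass at each preference is the assumed policy's
    probability of the observed first move there, times the prior mass,
    renormalized.  Passing the ToM(-1) table yields the ToM(0) posterior;
    passing the ToM(1) table yields the skeptical ToM(2) posterior.
    """
    likelihood = assumed_policy.likelihood(config, observed, d_apple)
    peak = likelihood.max()
    if peak > 0.0:
        likelihood = likelihood / peak  # pure rescale; improves conditioning
    unnorm = likelihood * prior.masses
    total = unnorm.sum()
    if total <= 0.0:
        raise DegenerateEvidenceError(
            f"observation {observed.value} at d_apple={d_apple} has zero "
            "probability under the assumed policy"
        )
    return Belief(unnorm / total)


def _revenue_curve(posterior: Belief, config: TaskConfig) -> np.ndarray:
    """Expected revenue at every candidate apple price on the lattice."""
    grid = build_grid(config)
    S = config.sum_total
    # p_buy[i, j]: probability the buyer purchases the apple when its
    # preference is grid[i] and the apple price is grid[j].
    p_buy = expit(config.beta * 2.0 * (grid[:, None] - grid[None, :]))
    if config.pricing_objective is PricingObjective.JOINT:
        payoff = grid[None, :] * p_buy + (S - grid[None, :]) * (1.0 - p_buy)
    else:
        payoff = grid[None, :] * p_buy
    return posterior.masses @ payoff


def expected_revenue(m_apple: float, posterior: Belief, config: TaskConfig) -> float:
    """Seller's expected revenue for one candidate apple price.

    Under the JOINT objective both purchase branches pay; under CHOSEN_ONLY
    only the apple branch is counted (the literal single-item integrand).
    """
    return float(_revenue_curve(posterior, config)[grid_index(config, m_apple)])


def optimal_prices(posterior: Belief, config: TaskConfig) -> PriceSchedule:
    """Revenue-maximizing deterministic price on the lattice.

    Ties (to within 1e-12) are broken toward the price closest to S/2 and
    then toward the lower price, which keeps the argmax deterministic and
    prices mirror-symmetric posteriors at the midpoint.
    """
    grid = build_grid(config)
    curve = _revenue_curve(posterior, config)
    candidates = np.flatnonzero(curve >= curve.max() - 1e-12)
    half = config.sum_total / 2.0
    best = min(candidates, key=lambda i: (abs(grid[i] - half), grid[i]))
    return PriceSchedule(float(grid[best]), config.sum_total)


def seller_price_table(level: int, hierarchy: Dict[int, object], config: TaskConfig) -> PriceTable:
    """Tabulate a seller level: IRL posterior then argmax pricing for every
    (apple distance, observed first move) pair, against a uniform prior."""
    if level % 2 != 0 or level < 0:
        raise ConfigError(f"seller levels are even integers >= 0, got {level}")
    assumed = hierarchy[level - 1]
    grid = build_grid(config)
    prior = uniform_prior(config)
    m = np.empty((config.n_points, 2))
    for j, d in enumerate(grid):
        for k, observed in enumerate((Item.APPLE, Item.ORANGE)):
            try:
                posterior = irl_posterior(assumed, observed, d, prior, config)
            except DegenerateEvidenceError as err:
                raise DegenerateEvidenceError(
                    f"building ToM({level}) price table: {err}"
                ) from err
            m[j, k] = optimal_prices(posterior, config).m_apple
    return PriceTable(level=level, m_apple=m)


def planning_q(
    scenario: Scenario, seller_table: PriceTable, config: TaskConfig
) -> tuple[float, float]:
    """Planning buyer's action values for the two candidate first moves.

    Each first move triggers a known deterministic price response from the
    seller table; the buyer adds its immediate utility to the expected
    purchase-stage utility under its own softmax purchase behavior.
    """
    S = config.sum_total
    q = []
    for first in (Item.APPLE, Item.ORANGE):
        prices = seller_table.schedule(config, scenario.d_apple, first)
        p_apple = stage3_policy(scenario.r_apple, prices, config)
        u3 = (scenario.r_apple - prices.m_apple) * p_apple + (
            (S - scenario.r_apple) - (S - prices.m_apple)
        ) * (1.0 - p_apple)
        q.append(stage1_utility(scenario, first) + u3)
    return q[0], q[1]


def planning_policy_table(
    level: int, hierarchy: Dict[int, object], config: TaskConfig
) -> PolicyTable:
    """Tabulate a planning buyer level (ToM(1), ToM(3), ...): softmax of
    :func:`planning_q` against the seller table one level below."""
    if level % 2 != 1 or level < 1:
        raise ConfigError(f"planning buyer levels are odd integers >= 1, got {level}")
    seller_table: PriceTable = hierarchy[level - 1]
    grid = build_grid(config)
    beta = config.beta_for(level)
    S = config.sum_total
    # Vectorized over the (r, d) lattice: the price response depends only on
    # (d, first move), the purchase softmax only on (r, price).
    m_after = seller_table.m_apple  # (n_d, 2)
    r = grid[:, None]
    q = []
    for k in range(2):  # first move: 0 = apple, 1 = orange
        m = m_after[:, k][None, :]
        p_buy = expit(config.beta * 2.0 * (r - m))
        u3 = (r - m) * p_buy + (m - r) * (1.0 - p_buy)
        u1 = (r - grid[None, :]) if k == 0 else (grid[None, :] - r)
        q.append(u1 + u3)
    return PolicyTable(level=level, p_apple=expit(beta * (q[0] - q[1])))


def build_hierarchy(config: TaskConfig) -> Hierarchy:
    """Tabulate all levels bottom-up, from the naive buyer at -1 through
    ``config.max_level``, memoizing each table so cost is linear in depth."""
    tables: Dict[int, object] = {-1: naive_policy_table(config)}
    for level in range(0, config.max_level + 1):
        try:
            if level % 2 == 0:
                tables[level] = seller_price_table(level, tables, config)
            else:
                tables[level] = planning_policy_table(level, tables, config)
        except (ConfigError, DegenerateEvidenceError) as err:
            raise type(err)(f"failed to build level {level}: {err}") from err
    return Hierarchy(config=config, tables=tables)
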