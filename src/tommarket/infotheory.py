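"""Information-theoretic diagnostics of deception and skepticism.

Three instruments, all reported per apple distance with preferences
marginalized under the uniform prior:

* mutual information between the buyer's preference and its first move
  (how much the move *reveals*; deceptive buyers drive it down);
* KL divergence from a seller's prior to its posterior after a first move
  (how much credence the seller lends the signal; skeptical sellers drive
  it toward zero);
* KL divergence between a buyer's actual policy and the policy its seller
  assumes (how badly the seller's model is wrong, i.e. how effective the
  deception is).

Values are in bits by default (``log_base=2``); the 0*log(0) = 0 convention
applies throughout, though with a finite inverse temperature no
hierarchy-produced table ever exercises it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .agents import Belief, Hierarchy, PolicyTable, irl_posterior, uniform_prior
from .environment import ConfigError, Item, TaskConfig, build_grid, grid_index

__all__ = [
    "MetricCurve",
    "mutual_information",
    "belief_update_kld",
    "likely_item_update_curve",
    "mutual_information_curve",
    "policy_discrepancy",
    "policy_discrepancy_curve",
]


@dataclass(frozen=True)
class MetricCurve:
    """One diagnostic evaluated along the apple-distance axis."""

    metric: str
    level_a: int
    d_apple: np.ndarray
    values: np.ndarray
    level_b: int | None = None
    observed: Sequence[Item] | None = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v < -1e-12):
            raise ValueError(f"{self.metric} curve values must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": self.metric,
                "level_a": self.level_a,
                "level_b": "" if self.level_b is None else self.level_b,
                "d_apple": self.d_apple,
                "observed_item": (
                    [item.value for item in self.observed]
                    if self.observed is not None
                    else ""
                ),
                "value_bits": self.values,
            }
        )


def _xlogy_ratio(p: np.ndarray, q: np.ndarray, log_base: float) -> np.ndarray:
    """Elementwise p*log(p/q) with the 0*log(0)=0 convention."""
    return rel_entr(p, q) / np.log(log_base)


def mutual_information(
    policy: PolicyTable, d_apple: float, prior: Belief, config: TaskConfig
) -> float:
    """I(preference; first move) at one apple distance.

    Computed from the definition: the prior-weighted KL divergence between
    the conditional action distribution and the prior-marginal action
    distribution.
    """
    p_a = policy.p_apple[:, grid_index(config, d_apple)]
    w = prior.masses
    marginal = float(w @ p_a)
    terms = _xlogy_ratio(p_a, marginal, config.log_base) + _xlogy_ratio(
        1.0 - p_a, 1.0 - marginal, config.log_base
    )
    return float(w @ terms)


def belief_update_kld(posterior: Belief, prior: Belief, config: TaskConfig) -> float:
    """D_KL(posterior || prior); the lower, the more skeptical the agent."""
    support_violated = (posterior.masses > 0) & (prior.masses == 0)
    if np.any(support_violated):
        raise ValueError("posterior has mass where the prior has none")
    value = float(np.sum(_xlogy_ratio(posterior.masses, prior.masses, config.log_base)))
    # Gibbs: the divergence is non-negative; snap rounding residue to zero.
    return 0.0 if -1e-9 < value < 0.0 else value


def likely_item_update_curve(
    seller_level: int, hierarchy: Hierarchy, config: TaskConfig
) -> MetricCurve:
    """Belief-update strength after the seller observes the *likelier*
    (closer) first move, at each apple distance.

    The closer item is the apple on the left half of the axis and the orange
    on the right half; the equidistant tie resolves to the apple (the curve
    is mirror-symmetric, so the tie choice is immaterial).
    """
    if seller_level % 2 != 0:
        raise ConfigError(f"seller levels are even, got {seller_level}")
    assumed = hierarchy.policy(seller_level - 1)
    grid = build_grid(config)
    prior = uniform_prior(config)
    half = config.sum_total / 2.0
    observed = [Item.APPLE if d <= half else Item.ORANGE for d in grid]
    values = np.array(
        [
            belief_update_kld(irl_posterior(assumed, obs, d, prior, config), prior, config)
            for d, obs in zip(grid, observed)
        ]
    )
    return MetricCurve(
        metric="belief_update_kld",
        level_a=seller_level,
        d_apple=grid,
        values=values,
        observed=observed,
    )


def mutual_information_curve(
    buyer_level: int, hierarchy: Hierarchy, config: TaskConfig
) -> MetricCurve:
    """Action-preference mutual information at each apple distance."""
    policy = hierarchy.policy(buyer_level)
    grid = build_grid(config)
    prior = uniform_prior(config)
    values = np.array([mutual_information(policy, d, prior, config) for d in grid])
    return MetricCurve(
        metric="mutual_information", level_a=buyer_level, d_apple=grid, values=values
    )


def policy_discrepancy(
    actual: PolicyTable,
    assumed: PolicyTable,
    d_apple: float,
    prior: Belief,
    config: TaskConfig,
) -> float:
    """Prior-expected KL divergence between a buyer's actual first-move
    distribution and the one its seller assumes, at one apple distance."""
    j = grid_index(config, d_apple)
    p = actual.p_apple[:, j]
    q = assumed.p_apple[:, j]
    if np.any((p > 0) & (q == 0)) or np.any(((1 - p) > 0) & (q == 1)):
        raise ValueError("assumed policy gives zero probability to a possible action")
    per_r = _xlogy_ratio(p, q, config.log_base) + _xlogy_ratio(
        1.0 - p, 1.0 - q, config.log_base
    )
    return float(prior.masses @ per_r)


def policy_discrepancy_curve(
    actual_level: int, assumed_level: int, hierarchy: Hierarchy, config: TaskConfig
) -> MetricCurve:
    """Deception effectiveness along the distance axis: the ToM(k+1) buyer's
    actual policy against the ToM(k-1) policy its ToM(k) seller assumes."""
    actual = hierarchy.policy(actual_level)
    assumed = hierarchy.policy(assumed_level)
    grid = build_grid(config)
    prior = uniform_prior(config)
    values = np.array(
        [policy_discrepancy(actual, assumed, d, prior, config) for d in grid]
    )
    return MetricCurve(
        metric="policy_discrepancy",
        level_a=actual_level,
        level_b=assumed_level,
        d_apple=grid,
        values=values,
    )
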