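"""Deterministic sweeps over the scenario grid, with CSV/figure output.

A sweep builds the full hierarchy, evaluates every diagnostic curve along
the apple-distance axis, and (optionally) renders the result surface:
policy heatmaps for the buyer levels, price curves for the seller levels,
and the three information-theoretic curves.  Everything is a closed-form
function of the configuration; a config hash is recorded so re-runs can be
checked for byte-identical output.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .agents import Hierarchy, build_hierarchy
from .environment import TaskConfig, build_grid
from .infotheory import (
    MetricCurve,
    likely_item_update_curve,
    mutual_information_curve,
    policy_discrepancy_curve,
)
from . import io as _io

__all__ = ["SweepResult", "run_sweep", "save_sweep", "render_figures", "config_hash"]

logger = logging.getLogger("tommarket")


def config_hash(config: TaskConfig) -> str:
    payload = json.dumps(config.canonical_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SweepResult:
    """A complete, deterministic result surface for one configuration."""

    config: TaskConfig
    hierarchy: Hierarchy
    curves: list[MetricCurve]
    config_hash: str
    timestamp: str = field(default="")

    def metrics_frame(self) -> pd.DataFrame:
        return pd.concat([c.to_frame() for c in self.curves], ignore_index=True)


def _buyer_levels(config: TaskConfig) -> list[int]:
    return [k for k in range(-1, config.max_level + 1, 2)]


def _seller_levels(config: TaskConfig) -> list[int]:
    return [k for k in range(0, config.max_level + 1, 2)]


def run_sweep(config: TaskConfig) -> SweepResult:
    """Build the hierarchy and evaluate all metric curves across distances."""
    logger.info("building hierarchy up to ToM(%d)", config.max_level)
    hierarchy = build_hierarchy(config)
    for level in hierarchy.levels:
        logger.info("built level ToM(%d)", level)
    curves: list[MetricCurve] = []
    for k in _buyer_levels(config):
        curves.append(mutual_information_curve(k, hierarchy, config))
        logger.info("computed mutual-information curve for ToM(%d)", k)
    for k in _seller_levels(config):
        curves.append(likely_item_update_curve(k, hierarchy, config))
        logger.info("computed belief-update curve for ToM(%d)", k)
    for k in _seller_levels(config):
        if k + 1 <= config.max_level:
            curves.append(policy_discrepancy_curve(k + 1, k - 1, hierarchy, config))
            logger.info("computed policy-discrepancy curve ToM(%d) vs ToM(%d)", k + 1, k - 1)
    return SweepResult(
        config=config,
        hierarchy=hierarchy,
        curves=curves,
        config_hash=config_hash(config),
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
    )


def save_sweep(result: SweepResult, outdir: str | Path) -> None:
    """Write tables, metric curves and provenance; all numeric content is a
    pure function of the config (the timestamp lives only in provenance)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.export_hierarchy(result.hierarchy, outdir)
    result.metrics_frame().to_csv(outdir / "metrics.csv", index=False)
    provenance = {
        "config": result.config.canonical_dict(),
        "config_hash": result.config_hash,
        "timestamp": result.timestamp,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")


def load_metrics(outdir: str | Path) -> pd.DataFrame:
    path = Path(outdir) / "metrics.csv"
    if not path.exists():
        raise FileNotFoundError(
            f"no sweep output found at {path}; run the sweep first"
        )
    return pd.read_csv(path)


def render_figures(result: SweepResult, outdir: str | Path) -> list[Path]:
    """Render the result surface, one raster file per panel group."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = result.config
    grid = build_grid(config)
    written: list[Path] = []

    # Buyer policy heatmaps.
    buyers = _buyer_levels(config)
    fig, axes = plt.subplots(1, len(buyers), figsize=(4 * len(buyers), 3.4), squeeze=False)
    for ax, k in zip(axes[0], buyers):
        table = result.hierarchy.policy(k)
        im = ax.imshow(
            table.p_apple,
            origin="lower",
            extent=(grid[0], grid[-1], grid[0], grid[-1]),
            vmin=0.0,
            vmax=1.0,
            aspect="auto",
            cmap="viridis",
        )
        ax.set_title(f"ToM({k}) buyer")
        ax.set_xlabel("d(apple)")
        ax.set_ylabel("r(apple)")
    fig.colorbar(im, ax=axes[0], label="P(choose apple)", shrink=0.9)
    path = outdir / "policies.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)

    # Seller price curves after an observed apple choice.
    fig, ax = plt.subplots(figsize=(5, 3.4))
    for k in _seller_levels(config):
        table = result.hierarchy.prices(k)
        ax.plot(grid, table.m_apple[:, 0], marker="o", ms=3, label=f"ToM({k}) seller")
    ax.set_xlabel("d(apple)")
    ax.set_ylabel("m(apple) after apple choice")
    ax.legend()
    fig.tight_layout()
    path = outdir / "prices.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)

    # Information-theoretic curves, one panel per metric.
    groups = {
        "mutual_information": ("I(r; a1)", "mutual_information.png"),
        "belief_update_kld": ("D_KL(posterior || prior)", "belief_update.png"),
        "policy_discrepancy": ("E_r D_KL(actual || assumed)", "policy_discrepancy.png"),
    }
    for metric, (ylabel, fname) in groups.items():
        selected = [c for c in result.curves if c.metric == metric]
        if not selected:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.4))
        for curve in selected:
            label = f"ToM({curve.level_a})" + (
                f" vs ToM({curve.level_b})" if curve.level_b is not None else ""
            )
            ax.plot(curve.d_apple, curve.values, marker="o", ms=3, label=label)
        ax.set_xlabel("d(apple)")
        unit = "bits" if config.log_base == 2 else "nats"
        ax.set_ylabel(f"{ylabel} [{unit}]")
        ax.legend()
        fig.tight_layout()
        path = outdir / fname
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
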