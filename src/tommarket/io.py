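"""CSV round-trip for hierarchy tables and metric curves.

One file per table, comma-separated with a header row, '.' decimal
separator and no index column.  Long format: a policy row is
(level, r_apple, d_apple, p_apple); a price row is
(level, d_apple, observed_item, m_apple).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .agents import Hierarchy, PolicyTable, PriceTable
from .environment import Item, TaskConfig, build_grid

__all__ = [
    "policy_frame",
    "price_frame",
    "write_policy_csv",
    "write_price_csv",
    "read_policy_csv",
    "read_price_csv",
    "export_hierarchy",
]


def policy_frame(table: PolicyTable, config: TaskConfig) -> pd.DataFrame:
    grid = build_grid(config)
    r_idx, d_idx = np.meshgrid(np.arange(len(grid)), np.arange(len(grid)), indexing="ij")
    return pd.DataFrame(
        {
            "level": table.level,
            "r_apple": grid[r_idx.ravel()],
            "d_apple": grid[d_idx.ravel()],
            "p_apple": table.p_apple.ravel(),
        }
    )


def price_frame(table: PriceTable, config: TaskConfig) -> pd.DataFrame:
    grid = build_grid(config)
    rows = []
    for k, item in enumerate((Item.APPLE, Item.ORANGE)):
        rows.append(
            pd.DataFrame(
                {
                    "level": table.level,
                    "d_apple": grid,
                    "observed_item": item.value,
                    "m_apple": table.m_apple[:, k],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_policy_csv(table: PolicyTable, config: TaskConfig, path: str | Path) -> None:
    policy_frame(table, config).to_csv(path, index=False)


def write_price_csv(table: PriceTable, config: TaskConfig, path: str | Path) -> None:
    price_frame(table, config).to_csv(path, index=False)


def read_policy_csv(path: str | Path) -> PolicyTable:
    df = pd.read_csv(path)
    level = int(df["level"].iloc[0])
    r_values = np.sort(df["r_apple"].unique())
    d_values = np.sort(df["d_apple"].unique())
    p = (
        df.pivot(index="r_apple", columns="d_apple", values="p_apple")
        .loc[r_values, d_values]
        .to_numpy()
    )
    return PolicyTable(level=level, p_apple=p)


def read_price_csv(path: str | Path) -> PriceTable:
    df = pd.read_csv(path)
    level = int(df["level"].iloc[0])
    d_values = np.sort(df["d_apple"].unique())
    wide = df.pivot(index="d_apple", columns="observed_item", values="m_apple").loc[d_values]
    m = np.column_stack([wide[Item.APPLE.value], wide[Item.ORANGE.value]])
    return PriceTable(level=level, m_apple=m)


def export_hierarchy(hierarchy: Hierarchy, outdir: str | Path) -> list[Path]:
    """Write one CSV per level into ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for level in hierarchy.levels:
        table = hierarchy.tables[level]
        if isinstance(table, PolicyTable):
            path = outdir / f"policy_tom{level}.csv"
            write_policy_csv(table, hierarchy.config, path)
        else:
            path = outdir / f"prices_tom{level}.csv"
            write_price_csv(table, hierarchy.config, path)
        paths.append(path)
    return paths
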