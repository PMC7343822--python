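"""Inventory containers and the two delimited-text dialects.

Two kinds of plot records flow through the pipeline:

* **reference (scientific) dialect** — one row per tree with continuous
  DBH ≥ 10 cm and taxon-level wood density;
* **management dialect** — one row per diameter class × taxon with an
  observed count and the spatial sampling fraction of that class; the top
  class is open (right-censored) and the smallest classes may be missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReferencePlot",
    "DiameterClassRecord",
    "ManagementInventory",
    "write_reference_plots",
    "read_reference_plots",
    "write_management_inventories",
    "read_management_inventories",
]

TREE_COLUMNS = ("dbh", "taxon_id", "wd_mean", "wd_sd", "x", "y")
OPEN_LABEL = "OPEN"


@dataclass
class ReferencePlot:
    """A scientific-dialect plot: a tree list with continuous DBH.

    ``trees`` is a DataFrame with columns dbh (cm), taxon_id, wd_mean,
    wd_sd (g/cm³) and within-plot tree positions x, y (m).
    """

    plot_id: str
    area_ha: float
    trees: pd.DataFrame
    x: float = 0.0
    y: float = 0.0
    date: float = 2005.0

    def __post_init__(self) -> None:
        if not self.area_ha > 0:
            raise ValueError("plot area must be positive")
        missing = [c for c in TREE_COLUMNS if c not in self.trees.columns]
        if missing:
            raise ValueError(f"tree table missing columns {missing}")
        if len(self.trees) and float(self.trees["dbh"].min()) < 10.0 - 1e-9:
            raise ValueError("reference plots only carry trees with DBH >= 10 cm")

    @property
    def n_trees(self) -> int:
        return len(self.trees)


@dataclass
class DiameterClassRecord:
    """One diameter class of a management inventory.

    ``class_hi`` is ``None`` for the open (right-censored) class.
    ``taxon_counts`` maps taxon_id to the number of trees observed in the
    sampled fraction ``p`` of the plot.
    """

    class_lo: float
    class_hi: float | None
    taxon_counts: dict[str, int] = field(default_factory=dict)
    p: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("sampling fraction p must be in (0, 1]")
        if any(v < 0 for v in self.taxon_counts.values()):
            raise ValueError("taxon counts must be non-negative")
        if self.class_hi is not None and self.class_hi <= self.class_lo:
            raise ValueError("class_hi must exceed class_lo")

    @property
    def r(self) -> int:
        """Observed count in the sampled fraction."""
        return int(sum(self.taxon_counts.values()))


@dataclass
class ManagementInventory:
    """A management-dialect plot: binned, censored, partially sampled counts.

    ``taxon_wd`` maps taxon_id to (wd_mean, wd_sd); it is carried along so
    the estimation engine does not need an external wood-density table
    when the inventory was produced by degrading a reference plot.
    """

    plot_id: str
    area_ha: float
    classes: list[DiameterClassRecord]
    census_threshold: float = 10.0
    open_threshold: float = 200.0
    taxon_wd: dict[str, tuple[float, float]] = field(default_factory=dict)
    x: float = 0.0
    y: float = 0.0
    date: float = 2005.0

    def __post_init__(self) -> None:
        if not self.area_ha > 0:
            raise ValueError("plot area must be positive")
        if self.census_threshold not in (10.0, 20.0):
            raise ValueError("census threshold must be 10 or 20 cm")

    @property
    def drop_10_20(self) -> bool:
        """True when the 10–20 cm class is absent and needs the correction model."""
        return self.census_threshold >= 20.0

    @property
    def n_observed(self) -> int:
        return int(sum(c.r for c in self.classes))

    def whole_plot_composition(self) -> dict[str, int]:
        comp: dict[str, int] = {}
        for c in self.classes:
            for t, n in c.taxon_counts.items():
                comp[t] = comp.get(t, 0) + n
        return comp


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def _meta_frame(plots) -> pd.DataFrame:
    rows = []
    for p in plots:
        rows.append(
            {
                "plot_id": p.plot_id,
                "area_ha": p.area_ha,
                "x": p.x,
                "y": p.y,
                "date": p.date,
                "census_threshold": getattr(p, "census_threshold", 10.0),
                "open_threshold": getattr(p, "open_threshold", float("nan")),
            }
        )
    return pd.DataFrame(rows)


def write_reference_plots(plots: list[ReferencePlot], trees_path, meta_path) -> None:
    """Write reference plots as a tree CSV plus a plot-metadata sidecar CSV."""
    frames = []
    for p in plots:
        df = p.trees.loc[:, list(TREE_COLUMNS)].copy()
        df.insert(0, "plot_id", p.plot_id)
        frames.append(df)
    trees = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=("plot_id",) + TREE_COLUMNS)
    )
    trees.to_csv(trees_path, index=False)
    _meta_frame(plots).to_csv(meta_path, index=False)


def read_reference_plots(trees_path, meta_path) -> list[ReferencePlot]:
    trees = pd.read_csv(trees_path)
    meta = pd.read_csv(meta_path)
    plots = []
    grouped = dict(tuple(trees.groupby("plot_id", sort=False))) if len(trees) else {}
    for row in meta.itertuples(index=False):
        df = grouped.get(row.plot_id)
        if df is None:
            df = pd.DataFrame(columns=TREE_COLUMNS)
        else:
            df = df.loc[:, list(TREE_COLUMNS)].reset_index(drop=True)
        plots.append(
            ReferencePlot(
                plot_id=str(row.plot_id),
                area_ha=float(row.area_ha),
                trees=df,
                x=float(row.x),
                y=float(row.y),
                date=float(row.date),
            )
        )
    return plots


def write_management_inventories(invs: list[ManagementInventory], classes_path, meta_path) -> None:
    """Write management inventories: one row per class × taxon.

    Wood densities per taxon are emitted alongside so that degraded
    synthetic data round-trips without an external wood-density table.
    """
    rows = []
    for inv in invs:
        for c in inv.classes:
            for taxon, n in sorted(c.taxon_counts.items()):
                wd_mean, wd_sd = inv.taxon_wd.get(taxon, (float("nan"), float("nan")))
                rows.append(
                    {
                        "plot_id": inv.plot_id,
                        "class_lo": c.class_lo,
                        "class_hi": OPEN_LABEL if c.class_hi is None else c.class_hi,
                        "taxon_id": taxon,
                        "count": n,
                        "sampling_fraction": c.p,
                        "wd_mean": wd_mean,
                        "wd_sd": wd_sd,
                    }
                )
    cols = ["plot_id", "class_lo", "class_hi", "taxon_id", "count",
            "sampling_fraction", "wd_mean", "wd_sd"]
    pd.DataFrame(rows, columns=cols).to_csv(classes_path, index=False)
    _meta_frame(invs).to_csv(meta_path, index=False)


def read_management_inventories(classes_path, meta_path) -> list[ManagementInventory]:
    table = pd.read_csv(classes_path)
    meta = pd.read_csv(meta_path)
    out = []
    grouped = dict(tuple(table.groupby("plot_id", sort=False))) if len(table) else {}
    for row in meta.itertuples(index=False):
        df = grouped.get(row.plot_id)
        classes: list[DiameterClassRecord] = []
        taxon_wd: dict[str, tuple[float, float]] = {}
        if df is not None:
            for (lo, hi, p), sub in df.groupby(["class_lo", "class_hi", "sampling_fraction"],
                                               sort=False):
                hi_val = None if str(hi) == OPEN_LABEL else float(hi)
                counts = {str(t): int(n) for t, n in zip(sub["taxon_id"], sub["count"])}
                classes.append(DiameterClassRecord(float(lo), hi_val, counts, float(p)))
            if "wd_mean" in df.columns:
                for t, wm, ws in zip(df["taxon_id"], df["wd_mean"], df["wd_sd"]):
                    if not (isinstance(wm, float) and math.isnan(wm)):
                        taxon_wd[str(t)] = (float(wm), float(ws))
        classes.sort(key=lambda c: c.class_lo)
        out.append(
            ManagementInventory(
                plot_id=str(row.plot_id),
                area_ha=float(row.area_ha),
                classes=classes,
                census_threshold=float(row.census_threshold),
                open_threshold=float(row.open_threshold),
                taxon_wd=taxon_wd,
                x=float(row.x),
                y=float(row.y),
                date=float(row.date),
            )
        )
    return out
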