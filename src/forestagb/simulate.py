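"""Synthetic forest stands with known ground truth, and their degradation.

The generator emulates the two inventory dialects end to end: reference
(scientific) plots are drawn from a configurable stem-size distribution
with a taxon pool carrying wood densities; the degradation operators then
turn a reference plot into a management inventory — binning DBH into
10-cm classes, pooling large trees into a right-censored open class,
thinning small classes by a per-tree binomial retention (the spatial
sampling fraction), and optionally removing the 10–20 cm class entirely.

Degradation is count-consistent with its inverse: binomial thinning with
retention p is exactly the sampling model whose Bayesian inverse is the
NegBin(r, p) expansion used at estimation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distributions import WeibullDBHModel
from .inventory import DiameterClassRecord, ManagementInventory, ReferencePlot

__all__ = [
    "TaxonEntry",
    "generate_taxon_table",
    "SyntheticForestConfig",
    "DegradationScenario",
    "generate_plot",
    "generate_plots",
    "degrade_plot",
    "split_plot",
]

CLASS_WIDTH = 10.0


@dataclass(frozen=True)
class TaxonEntry:
    taxon_id: str
    genus: str
    species: str
    wd_mean: float
    wd_sd: float
    rel_abundance: float

    def __post_init__(self) -> None:
        if not 0.08 <= self.wd_mean <= 1.39:
            raise ValueError("wd_mean outside physical bounds [0.08, 1.39]")
        if self.wd_sd < 0 or self.rel_abundance < 0:
            raise ValueError("wd_sd and rel_abundance must be non-negative")


def generate_taxon_table(
    n_taxa: int,
    seed: int | np.random.SeedSequence,
    wd_mu: float = 0.62,
    wd_sigma: float = 0.12,
    wd_bounds: tuple[float, float] = (0.2, 1.0),
    wd_sd: float = 0.07,
    abundance_decay: float = 0.97,
) -> list[TaxonEntry]:
    """A synthetic taxon pool standing in for a wood-density reference table.

    Taxon mean wood densities are drawn from Normal(0.62, 0.12) truncated
    to [0.2, 1.0] g/cm³ (rejection sampling); relative abundances follow
    a geometric, log-series-like decay (ratio 0.97) normalised to 1,
    producing a realistic dominance structure.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = wd_bounds
    wd = np.empty(n_taxa)
    filled = 0
    while filled < n_taxa:
        draw = rng.normal(wd_mu, wd_sigma, size=n_taxa - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        wd[filled:filled + keep.size] = keep
        filled += keep.size
    ab = abundance_decay ** np.arange(n_taxa)
    ab /= ab.sum()
    return [
        TaxonEntry(
            taxon_id=f"t{i:04d}",
            genus=f"genus{i // 5:03d}",
            species=f"sp{i:04d}",
            wd_mean=float(wd[i]),
            wd_sd=wd_sd,
            rel_abundance=float(ab[i]),
        )
        for i in range(n_taxa)
    ]


def taxon_table_frame(pool: list[TaxonEntry]) -> pd.DataFrame:
    """Taxon pool as a wood-density table (family/genus/species columns)."""
    return pd.DataFrame(
        {
            "family": [f"family{int(t.genus[5:]) // 4:03d}" for t in pool],
            "genus": [t.genus for t in pool],
            "species": [t.species for t in pool],
            "taxon_id": [t.taxon_id for t in pool],
            "wd_mean": [t.wd_mean for t in pool],
            "wd_sd": [t.wd_sd for t in pool],
            "rel_abundance": [t.rel_abundance for t in pool],
        }
    )


@dataclass(frozen=True)
class SyntheticForestConfig:
    """Study conditions of the synthetic stands.

    Defaults: 0.5-ha plots (the dominant management-plot size), 500
    stems/ha at DBH ≥ 10 cm (a typical stem density for the region's
    moist forests), diameters from the regional Weibull size model.
    """

    plot_area_ha: float = 0.5
    stem_density: float = 500.0
    dbh_model: WeibullDBHModel = field(default_factory=WeibullDBHModel)
    taxon_pool: tuple[TaxonEntry, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.plot_area_ha > 0:
            raise ValueError("plot_area_ha must be positive")
        if self.stem_density < 0:
            raise ValueError("stem_density must be non-negative")


@dataclass(frozen=True)
class DegradationScenario:
    """How a reference plot is degraded into the management dialect.

    ``sampling_fraction_by_class`` maps a 10-cm class lower bound to the
    spatial fraction p of the plot on which that class is censused;
    classes not listed are fully sampled (p = 1). ``drop_10_20`` removes
    the 10–20 cm class entirely (census threshold 20 cm).
    """

    open_class_threshold: float = 200.0
    census_threshold: float = 10.0
    sampling_fraction_by_class: dict[float, float] = field(default_factory=dict)
    drop_10_20: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        t = self.open_class_threshold
        if not (120.0 <= t <= 200.0 and t % 10 == 0):
            raise ValueError("open_class_threshold must be in {120, 130, ..., 200}")
        for lo, p in self.sampling_fraction_by_class.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"sampling fraction for class {lo} outside (0, 1]")
        if self.drop_10_20 and self.census_threshold < 20.0:
            raise ValueError("drop_10_20 implies census_threshold = 20")


def _plot_side_m(area_ha: float) -> float:
    return float(np.sqrt(area_ha * 1e4))


def generate_plot(
    config: SyntheticForestConfig,
    plot_id: str = "p0000",
    seed: int | np.random.SeedSequence | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
    date: float = 2005.0,
) -> ReferencePlot:
    """Draw one reference plot: Poisson stem count, Weibull diameters,
    taxa pro rata of pool abundances, uniform positions in a square plot."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pool = config.taxon_pool or tuple(generate_taxon_table(50, rng.integers(2**31)))
    n = int(rng.poisson(config.plot_area_ha * config.stem_density))
    dbh = config.dbh_model.trunc_rvs(n, rng)
    probs = np.array([t.rel_abundance for t in pool], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(pool), size=n, p=probs)
    side = _plot_side_m(config.plot_area_ha)
    trees = pd.DataFrame(
        {
            "dbh": dbh,
            "taxon_id": [pool[i].taxon_id for i in idx],
            "wd_mean": [pool[i].wd_mean for i in idx],
            "wd_sd": [pool[i].wd_sd for i in idx],
            "x": rng.uniform(0.0, side, size=n),
            "y": rng.uniform(0.0, side, size=n),
        }
    )
    return ReferencePlot(plot_id, config.plot_area_ha, trees, x=origin[0], y=origin[1], date=date)


def generate_plots(
    config: SyntheticForestConfig,
    n_plots: int,
    master_seed: int | None = None,
    coords: list[tuple[float, float]] | None = None,
) -> list[ReferencePlot]:
    """A batch of reference plots with per-plot seed substreams."""
    if isinstance(master_seed, np.random.SeedSequence):
        ss = master_seed
    else:
        ss = np.random.SeedSequence(config.seed if master_seed is None else master_seed)
    if not config.taxon_pool:
        pool_seed = ss.spawn(1)[0]
        pool = tuple(generate_taxon_table(50, pool_seed))
        config = replace(config, taxon_pool=pool)
    children = ss.spawn(n_plots)
    plots = []
    for i, child in enumerate(children):
        origin = coords[i] if coords is not None else (0.0, 0.0)
        plots.append(generate_plot(config, f"p{i:04d}", seed=child, origin=origin))
    return plots


def degrade_plot(
    plot: ReferencePlot,
    scenario: DegradationScenario,
    seed: int | np.random.SeedSequence,
) -> ManagementInventory:
    """Degrade a reference plot into the management dialect.

    DBH is binned into half-open [lo, lo+10) classes (label = lower
    bound, assignment by floor(D/10)·10); classes at/above the open
    threshold are pooled into the open class; each tree of a subsampled
    class is independently retained with probability p; classes below the
    census threshold are removed.
    """
    rng = np.random.default_rng(seed)
    dbh = plot.trees["dbh"].to_numpy(dtype=float)
    taxa = plot.trees["taxon_id"].to_numpy(dtype=object)
    lo_of = np.floor(dbh / CLASS_WIDTH) * CLASS_WIDTH
    lo_of = np.minimum(lo_of, scenario.open_class_threshold)

    census = 20.0 if scenario.drop_10_20 else scenario.census_threshold
    classes: list[DiameterClassRecord] = []
    present = np.unique(lo_of)
    for lo in sorted(present):
        if lo < census:
            continue
        is_open = lo >= scenario.open_class_threshold
        p = scenario.sampling_fraction_by_class.get(float(lo), 1.0)
        mask = lo_of == lo
        if p < 1.0:
            mask = mask & (rng.uniform(size=lo_of.shape) < p)
        sub = taxa[mask]
        counts: dict[str, int] = {}
        for t in sub:
            counts[t] = counts.get(t, 0) + 1
        classes.append(
            DiameterClassRecord(
                class_lo=float(lo),
                class_hi=None if is_open else float(lo + CLASS_WIDTH),
                taxon_counts=counts,
                p=float(p),
            )
        )
    taxon_wd = {
        str(t): (float(wm), float(ws))
        for t, wm, ws in zip(plot.trees["taxon_id"], plot.trees["wd_mean"], plot.trees["wd_sd"])
    }
    return ManagementInventory(
        plot_id=plot.plot_id,
        area_ha=plot.area_ha,
        classes=classes,
        census_threshold=census,
        open_threshold=scenario.open_class_threshold,
        taxon_wd=taxon_wd,
        x=plot.x,
        y=plot.y,
        date=plot.date,
    )


def split_plot(plot: ReferencePlot, n_parts: int = 2, fractions: tuple[float, float] = (0.5, 0.5)) -> list[ReferencePlot]:
    """Split a plot into two sub-plots along the x axis.

    Trees are partitioned by position at a cut placed at
    ``fractions[0]`` of the plot side; sub-plot areas sum to the
    original. Emulates the halving of 1-ha scientific plots into the
    dominant 0.5-ha management-plot size.
    """
    if n_parts != 2:
        raise NotImplementedError("only two-way splits are supported")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive and sum to 1")
    side = _plot_side_m(plot.area_ha)
    cut = fractions[0] * side
    left = plot.trees[plot.trees["x"] < cut].reset_index(drop=True)
    right = plot.trees[plot.trees["x"] >= cut].reset_index(drop=True)
    right = right.assign(x=right["x"] - cut)
    return [
        ReferencePlot(f"{plot.plot_id}_a", plot.area_ha * fractions[0], left,
                      x=plot.x, y=plot.y, date=plot.date),
        ReferencePlot(f"{plot.plot_id}_b", plot.area_ha * fractions[1], right,
                      x=plot.x + cut, y=plot.y, date=plot.date),
    ]
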