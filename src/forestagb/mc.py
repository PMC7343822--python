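"""Monte Carlo plot-AGB estimation: the central Model/Results pair.

``PlotAGBModel`` wraps one inventory (either dialect) together with the
allometric models, the size distribution used for diameter assignment,
and the error-source toggles; ``fit`` runs the Monte Carlo chain —
per iteration: small-tree expansion → diameter assignment → error draws
→ tree AGB → plot AGB (→ AGB₁₀₋₂₀ correction when the 10–20 cm class is
absent) — and returns a ``PlotAGBResults`` carrying the mean, variance
and coefficient of variation over iterations.

With every error source off the chain is fully deterministic (expansion
uses the expected count, assignment the class-conditional median), so the
Monte Carlo variance is exactly zero.
"""

from __future__ import annotations

import zlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allometry import (
    AGBModel,
    ErrorToggles,
    HeightModel,
    MIN_HEIGHT,
    draw_agb,
    draw_wood_density,
    lookup_wood_density,
)
from .distributions import WeibullDBHModel
from .inventory import ManagementInventory, ReferencePlot
from .standardize import (
    SHAPE_CLASS_LOS,
    CorrectionModel,
    expected_total,
    predict_agb_10_20,
    shape_metrics_from_class_agb,
)

__all__ = ["PlotAGBModel", "PlotAGBResults", "estimate_plot_agb", "batch_estimate"]


@dataclass
class PlotAGBResults:
    """Summary of the Monte Carlo AGB draws for one plot.

    All biomass quantities are per hectare (Mg·ha⁻¹); ``variance`` is in
    Mg²·ha⁻² and ``cv_pct`` = 100·√variance / mean_agb.
    """

    plot_id: str
    mean_agb: float
    variance: float
    cv_pct: float
    n_iter: int
    dbh_floor: float
    agb_ge20_mean: float
    agb_10_20_mean: float
    corrected: bool
    area_ha: float
    x: float = 0.0
    y: float = 0.0
    date: float = 2005.0
    empty: bool = False
    n_rejected: int = 0
    draws: np.ndarray | None = field(default=None, repr=False)

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def to_row(self) -> dict:
        return {
            "plot_id": self.plot_id,
            "mean_agb": self.mean_agb,
            "variance": self.variance,
            "cv_pct": self.cv_pct,
            "n_iter": self.n_iter,
            "dbh_floor": self.dbh_floor,
            "corrected": self.corrected,
            "agb_ge20_mean": self.agb_ge20_mean,
            "agb_10_20_mean": self.agb_10_20_mean,
            "area_ha": self.area_ha,
            "x": self.x,
            "y": self.y,
            "date": self.date,
        }

    def summary(self) -> str:
        lines = [
            f"Plot AGB estimate — {self.plot_id}",
            "-" * 40,
            f"mean AGB            {self.mean_agb:12.2f} Mg/ha",
            f"variance            {self.variance:12.2f} (Mg/ha)^2",
            f"CV                  {self.cv_pct:12.2f} %",
            f"AGB >= 20 cm        {self.agb_ge20_mean:12.2f} Mg/ha",
            f"AGB 10-20 cm        {self.agb_10_20_mean:12.2f} Mg/ha"
            + ("  (corrected)" if self.corrected else ""),
            f"iterations          {self.n_iter:12d}"
            + (f"  ({self.n_rejected} rejected)" if self.n_rejected else ""),
            f"DBH floor           {self.dbh_floor:12.0f} cm",
        ]
        return "\n".join(lines)


class PlotAGBModel:
    """Monte Carlo AGB model for one plot (scientific or management dialect).

    Parameters
    ----------
    inventory : ReferencePlot or ManagementInventory
    dbh_model : WeibullDBHModel, optional
        Size distribution used for continuous-diameter assignment
        (management dialect only). Defaults to the regional Weibull.
    height_model, agb_model : allometric models with error magnitudes.
    correction_model : CorrectionModel, optional
        Required when the inventory lacks the 10–20 cm class.
    toggles : ErrorToggles
        Which error sources to propagate; all off by default.
    wd_table : DataFrame, optional
        Wood-density table used to resolve taxa the inventory does not
        carry densities for.
    """

    def __init__(
        self,
        inventory: ReferencePlot | ManagementInventory,
        *,
        dbh_model: WeibullDBHModel | None = None,
        height_model: HeightModel | None = None,
        agb_model: AGBModel | None = None,
        correction_model: CorrectionModel | None = None,
        toggles: ErrorToggles | None = None,
        wd_table: pd.DataFrame | None = None,
        stratified_assignment: bool = True,
    ):
        if not isinstance(inventory, (ReferencePlot, ManagementInventory)):
            raise ValueError(f"unknown inventory dialect: {type(inventory).__name__}")
        self.inventory = inventory
        self.dbh_model = dbh_model or WeibullDBHModel()
        self.height_model = height_model or HeightModel()
        self.agb_model = agb_model or AGBModel()
        self.correction_model = correction_model
        self.toggles = toggles or ErrorToggles()
        self.wd_table = wd_table
        self.stratified_assignment = stratified_assignment
        if isinstance(inventory, ManagementInventory) and inventory.drop_10_20:
            if correction_model is None:
                raise ValueError(
                    "inventory lacks the 10-20 cm class: a correction_model is required"
                )

    # -- wood density resolution ------------------------------------------
    def _resolve_wd(self, taxon: str) -> tuple[float, float]:
        inv = self.inventory
        if isinstance(inv, ManagementInventory) and taxon in inv.taxon_wd:
            return inv.taxon_wd[taxon]
        if self.wd_table is not None:
            if "taxon_id" in self.wd_table.columns:
                hit = self.wd_table[self.wd_table["taxon_id"] == taxon]
                if len(hit):
                    return float(hit["wd_mean"].iloc[0]), float(hit["wd_sd"].iloc[0])
            rec = lookup_wood_density((None, None, taxon), self.wd_table)
            return rec.value, rec.sd
        raise ValueError(f"no wood density available for taxon {taxon!r}")

    # -- fitting -----------------------------------------------------------
    def fit(self, n_iter: int = 1000, seed=None) -> PlotAGBResults:
        if n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        rng = np.random.default_rng(seed)
        inv = self.inventory

        if isinstance(inv, ReferencePlot):
            empty = inv.n_trees == 0
            simulate = self._simulate_scientific
            dbh_floor, corrected = 10.0, False
        else:
            empty = inv.n_observed == 0 and not inv.drop_10_20
            simulate = self._simulate_management
            dbh_floor = 20.0 if inv.drop_10_20 else 10.0
            corrected = inv.drop_10_20 and self.correction_model is not None

        if empty:
            zeros = np.zeros(n_iter)
            return self._summarize(zeros, zeros, zeros, n_iter, dbh_floor, corrected,
                                   empty=True, n_rejected=0)

        if not self.toggles.any_on:
            total, a1020, age20 = (np.repeat(v, n_iter) for v in simulate(1, rng))
            n_rejected = 0
        else:
            total, a1020, age20 = simulate(n_iter, rng)
            n_rejected = 0
            bad = ~np.isfinite(total)
            while np.any(bad):
                n_rejected += int(bad.sum())
                if n_rejected > 100 * n_iter:
                    raise RuntimeError("Monte Carlo chain keeps producing non-finite AGB")
                rt, r1, r2 = simulate(int(bad.sum()), rng)
                total[bad], a1020[bad], age20[bad] = rt, r1, r2
                bad = ~np.isfinite(total)

        return self._summarize(total, a1020, age20, n_iter, dbh_floor, corrected,
                               empty=False, n_rejected=n_rejected)

    def _summarize(self, total, a1020, age20, n_iter, dbh_floor, corrected,
                   empty, n_rejected) -> PlotAGBResults:
        inv = self.inventory
        mean = float(total.mean())
        if n_iter > 1 and np.ptp(total) > 0.0:
            var = float(total.var(ddof=1))
        else:
            var = 0.0  # constant draws: exactly zero, no summation rounding
        cv = 100.0 * np.sqrt(var) / mean if mean > 0 else 0.0
        return PlotAGBResults(
            plot_id=inv.plot_id,
            mean_agb=mean,
            variance=var,
            cv_pct=float(cv),
            n_iter=n_iter,
            dbh_floor=dbh_floor,
            agb_ge20_mean=float(age20.mean()),
            agb_10_20_mean=float(a1020.mean()),
            corrected=corrected,
            area_ha=inv.area_ha,
            x=inv.x,
            y=inv.y,
            date=inv.date,
            empty=empty,
            n_rejected=n_rejected,
            draws=np.asarray(total, dtype=float),
        )

    # -- classical error draws (shared by both dialects) -------------------
    def _classical_agb(self, dbh, wd_mu, wd_sd, n_iter, rng, iter_idx=None):
        """Tree AGB with the classical (WD, H, AGB-model) errors applied.

        ``dbh`` etc. are either (n_iter, N) matrices / (N,) vectors to be
        broadcast, or flat arrays with ``iter_idx`` giving the iteration
        each tree belongs to (used for the variable-size expansion part;
        the per-iteration coefficient draw must then be indexed).
        """
        t = self.toggles
        hm, am = self.height_model, self.agb_model

        flat = iter_idx is not None
        shape = dbh.shape if flat else (n_iter, np.shape(dbh)[-1])

        if t.wd:
            wd = draw_wood_density(wd_mu, wd_sd, rng, size=shape)
        else:
            wd = wd_mu

        h = hm.predict(dbh)
        if t.height and hm.sigma_h > 0:
            h = h + rng.normal(0.0, hm.sigma_h, size=shape)
            h = np.maximum(h, MIN_HEIGHT)

        coef_z = None
        if t.agb:
            if self._coef_z is None:
                self._coef_z = rng.normal(size=(n_iter, 2))
            z = self._coef_z
            if flat:
                coef_z = (z[iter_idx, 0], z[iter_idx, 1])
            else:
                coef_z = (z[:, 0:1], z[:, 1:2])

        agb = draw_agb(wd, dbh, h, am, rng if t.agb else None, coef_z)
        if not flat and agb.ndim == 1:
            agb = np.broadcast_to(agb, shape)
        return agb

    # -- scientific dialect -------------------------------------------------
    def _simulate_scientific(self, n_iter: int, rng: np.random.Generator):
        inv: ReferencePlot = self.inventory
        self._coef_z = None
        dbh = inv.trees["dbh"].to_numpy(dtype=float)
        wd_mu = inv.trees["wd_mean"].to_numpy(dtype=float)
        wd_sd = inv.trees["wd_sd"].to_numpy(dtype=float)
        agb = self._classical_agb(dbh, wd_mu, wd_sd, n_iter, rng)
        small = dbh < 20.0
        a1020 = agb[:, small].sum(axis=1) / inv.area_ha
        total = agb.sum(axis=1) / inv.area_ha
        return total, a1020, total - a1020

    # -- management dialect --------------------------------------------------
    def _simulate_management(self, n_iter: int, rng: np.random.Generator):
        inv: ManagementInventory = self.inventory
        t = self.toggles
        dm = self.dbh_model
        self._coef_z = None

        # Fully sampled trees: fixed count, vectorised (n_iter, N) matrices.
        base_f_lo, base_f_hi = [], []
        base_wd_mu, base_wd_sd, base_lo = [], [], []
        class_slices = []  # contiguous [start, stop) column ranges per class
        expansions = []  # (class_lo, f_lo, f_hi, r, p, taxa, probs)
        for c in inv.classes:
            start = len(base_f_lo)
            hi = dm.d_max if c.class_hi is None else c.class_hi
            f_lo, f_hi = float(dm.cdf(c.class_lo)), float(dm.cdf(hi))
            taxa = sorted(c.taxon_counts)
            for taxon in taxa:
                n = c.taxon_counts[taxon]
                wm, ws = self._resolve_wd(taxon)
                base_f_lo += [f_lo] * n
                base_f_hi += [f_hi] * n
                base_wd_mu += [wm] * n
                base_wd_sd += [ws] * n
                base_lo += [c.class_lo] * n
            class_slices.append((start, len(base_f_lo)))
            if c.p < 1.0 and c.r > 0:
                comp = np.array([c.taxon_counts[x] for x in taxa], dtype=float)
                wd_pairs = np.array([self._resolve_wd(x) for x in taxa], dtype=float)
                expansions.append((c.class_lo, f_lo, f_hi, c.r, c.p,
                                   wd_pairs, comp / comp.sum()))

        base_f_lo = np.asarray(base_f_lo)
        base_f_hi = np.asarray(base_f_hi)
        base_wd_mu = np.asarray(base_wd_mu)
        base_wd_sd = np.asarray(base_wd_sd)
        base_lo = np.asarray(base_lo)
        n_base = base_f_lo.size

        area = inv.area_ha
        total = np.zeros(n_iter)
        a1020 = np.zeros(n_iter)
        # per-hectare AGB sums of the five shape classes, for S/I
        need_shape = inv.drop_10_20 and self.correction_model is not None
        shape_sums = np.zeros((n_iter, len(SHAPE_CLASS_LOS))) if need_shape else None

        if n_base:
            # Within-class quantiles are stratified by default: each of the
            # n_c trees of a class takes one equal-probability stratum
            # (randomly permuted across trees per iteration), which keeps
            # the per-tree marginal distribution while representing the
            # class distribution far more evenly than iid draws.
            u = np.empty((n_iter, n_base))
            for start, stop in class_slices:
                n_c = stop - start
                if n_c == 0:
                    continue
                if t.dbh_assign:
                    if self.stratified_assignment and n_c > 1:
                        strata = rng.permuted(
                            np.tile(np.arange(n_c, dtype=float), (n_iter, 1)), axis=1
                        )
                        u[:, start:stop] = (strata + rng.uniform(size=(n_iter, n_c))) / n_c
                    else:
                        u[:, start:stop] = rng.uniform(size=(n_iter, n_c))
                elif self.stratified_assignment and n_c > 1:
                    u[:, start:stop] = (np.arange(n_c) + 0.5) / n_c
                else:
                    u[:, start:stop] = 0.5
            dbh = np.asarray(dm.ppf(base_f_lo + u * (base_f_hi - base_f_lo)), dtype=float)
            agb = self._classical_agb(dbh, base_wd_mu, base_wd_sd, n_iter, rng)
            total += agb.sum(axis=1)
            mask_small = base_lo < 20.0
            if mask_small.any():
                a1020 += agb[:, mask_small].sum(axis=1)
            if need_shape:
                for j, lo in enumerate(SHAPE_CLASS_LOS):
                    m = base_lo == lo
                    if m.any():
                        shape_sums[:, j] += agb[:, m].sum(axis=1)

        for class_lo, f_lo, f_hi, r, p, wd_pairs, probs in expansions:
            if t.n_exp:
                x = rng.negative_binomial(r, p, size=n_iter)
            else:
                x = np.full(n_iter, expected_total(r, p) - r)
            m_total = int(x.sum())
            if m_total == 0:
                continue
            iter_idx = np.repeat(np.arange(n_iter), x)
            pick = rng.choice(len(probs), size=m_total, p=probs)
            wd_mu = wd_pairs[pick, 0]
            wd_sd = wd_pairs[pick, 1]
            if t.dbh_assign:
                u = rng.uniform(size=m_total)
            else:
                u = np.full(m_total, 0.5)
            dbh = np.asarray(dm.ppf(f_lo + u * (f_hi - f_lo)), dtype=float)
            agb_flat = self._classical_agb(dbh, wd_mu, wd_sd, n_iter, rng, iter_idx=iter_idx)
            sums = np.bincount(iter_idx, weights=agb_flat, minlength=n_iter)
            total += sums
            if class_lo < 20.0:
                a1020 += sums
            if need_shape and class_lo in SHAPE_CLASS_LOS:
                j = SHAPE_CLASS_LOS.index(class_lo)
                shape_sums[:, j] += sums

        total /= area
        a1020 /= area
        age20 = total - a1020

        if need_shape:
            s, i = shape_metrics_from_class_agb(shape_sums / area)
            pred = predict_agb_10_20(
                age20, s, i, self.correction_model,
                rng=rng if t.agb_cor else None,
                with_error=t.agb_cor,
            )
            a1020 = np.asarray(pred, dtype=float)
            total = age20 + a1020
        return total, a1020, age20


def estimate_plot_agb(
    inventory,
    *,
    toggles: ErrorToggles | None = None,
    n_iter: int = 1000,
    seed=None,
    **model_kw,
) -> PlotAGBResults:
    """One-call wrapper: build a ``PlotAGBModel`` and fit it."""
    return PlotAGBModel(inventory, toggles=toggles, **model_kw).fit(n_iter=n_iter, seed=seed)


def plot_seed(master_seed: int, plot_id: str) -> np.random.SeedSequence:
    """Per-plot seed substream keyed by (master seed, CRC32 of plot_id).

    Independent of plot order, so batch results do not depend on how the
    work is scheduled.
    """
    return np.random.SeedSequence(entropy=(int(master_seed), zlib.crc32(plot_id.encode())))


@dataclass
class BatchError:
    plot_id: str
    error: str


def batch_estimate(
    inventories,
    *,
    toggles: ErrorToggles | None = None,
    n_iter: int = 1000,
    master_seed: int = 0,
    workers: int = 1,
    **model_kw,
) -> tuple[list[PlotAGBResults], list[BatchError]]:
    """Estimate a list of plots with per-plot seed substreams.

    Results are identical whatever ``workers`` is; per-plot failures are
    collected as ``BatchError`` records rather than aborting the batch.
    """
    def run_one(inv):
        seed = plot_seed(master_seed, inv.plot_id)
        return PlotAGBModel(inv, toggles=toggles, **model_kw).fit(n_iter=n_iter, seed=seed)

    results: list[PlotAGBResults] = []
    errors: list[BatchError] = []
    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            futures = [(inv, pool.submit(run_one, inv)) for inv in inventories]
            for inv, fut in futures:
                try:
                    results.append(fut.result())
                except Exception as exc:  # noqa: BLE001 — per-plot isolation
                    errors.append(BatchError(getattr(inv, "plot_id", "?"), str(exc)))
    else:
        for inv in inventories:
            try:
                results.append(run_one(inv))
            except Exception as exc:  # noqa: BLE001 — per-plot isolation
                errors.append(BatchError(getattr(inv, "plot_id", "?"), str(exc)))
    return results, errors
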