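"""Degrade-and-validate experiments and major-axis regression.

The validation design mirrors how a biomass computation scheme for
degraded inventories is tested against research-grade data: reference
plots (continuous DBH) provide a reference AGB — the Monte Carlo mean
under the classical error sources (wood density, height model, AGB
model) — then each plot is degraded under a named scenario, re-estimated
with a chosen set of error sources, and the two are compared through

* the across-plot mean (and 2.5–97.5 percentile interval) of the
  plot-level CV — the *uncertainty* of the scheme, and
* the slope of the major-axis (MA) regression of estimated vs reference
  plot means — its *bias* (MA minimises perpendicular distances, so the
  roles of x and y are symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allometry import AGBModel, ErrorToggles, HeightModel
from .distributions import WeibullDBHModel
from .allometry import tree_agb
from .mc import PlotAGBModel, PlotAGBResults, plot_seed
from .simulate import DegradationScenario, SyntheticForestConfig, degrade_plot, \
    generate_plots, generate_taxon_table
from .standardize import (
    SHAPE_CLASS_LOS,
    CorrectionModel,
    fit_correction_model,
    shape_metrics_from_class_agb,
)

__all__ = [
    "MAResult",
    "major_axis",
    "ScenarioReport",
    "SCENARIOS",
    "SOURCE_TOGGLES",
    "VALIDATION_ROWS",
    "reference_estimates",
    "run_degradation_experiment",
    "decompose_error_sources",
    "calibrate_correction_model",
    "small_tree_agb_share",
    "standard_validation_summary",
]


# ---------------------------------------------------------------------------
# Major-axis regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MAResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    n: int


def _ma_slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    syy = ((y - ybar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    if sxy == 0.0:
        if sxx == syy:
            raise ValueError("major-axis slope undefined: no covariance structure")
        slope = 0.0 if sxx > syy else np.inf
    else:
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4.0 * sxy**2)) / (2.0 * sxy)
    intercept = ybar - slope * xbar if np.isfinite(slope) else np.nan
    return float(slope), float(intercept)


def major_axis(x, y, n_boot: int = 1000, seed=None) -> MAResult:
    """Major-axis regression of y on x with a bootstrap slope CI.

    The MA slope is the first principal axis of the centred scatter:
    slope = (S_yy − S_xx + √((S_yy−S_xx)² + 4S_xy²)) / (2S_xy). The 95%
    CI is percentile-bootstrap over plots (``n_boot`` resamples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    slope, intercept = _ma_slope_intercept(x, y)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        try:
            b, _ = _ma_slope_intercept(x[idx], y[idx])
        except ValueError:
            continue
        boots.append(b)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = min(lo, slope), max(hi, slope)
    else:
        lo = hi = slope
    return MAResult(slope, intercept, (float(lo), float(hi)), int(x.size))


# ---------------------------------------------------------------------------
# Scenario registry
# ---------------------------------------------------------------------------

#: Named degradation scenarios. ``best`` and ``worst`` are the two
#: bracketing situations found in management data: a 200-cm open class
#: with the 10–20 cm class sampled on 25% of the plot, vs a 120-cm open
#: class with classes 20–30/30–40 cm sampled on 12.5%/25% and the
#: 10–20 cm class absent (correction model required).
SCENARIOS: dict[str, DegradationScenario] = {
    "none": DegradationScenario(200.0, name="none"),
    "best": DegradationScenario(200.0, sampling_fraction_by_class={10.0: 0.25}, name="best"),
    "worst": DegradationScenario(
        120.0,
        census_threshold=20.0,
        sampling_fraction_by_class={20.0: 0.125, 30.0: 0.25},
        drop_10_20=True,
        name="worst",
    ),
    "dbh_200": DegradationScenario(200.0, name="dbh_200"),
    "dbh_120": DegradationScenario(120.0, name="dbh_120"),
    "nexp_light": DegradationScenario(
        200.0, sampling_fraction_by_class={10.0: 0.25}, name="nexp_light"
    ),
    "nexp_heavy": DegradationScenario(
        200.0,
        sampling_fraction_by_class={10.0: 0.125, 20.0: 0.125, 30.0: 0.25},
        name="nexp_heavy",
    ),
    "agb_cor": DegradationScenario(
        200.0, census_threshold=20.0, drop_10_20=True, name="agb_cor"
    ),
}

SOURCE_TOGGLES: dict[str, ErrorToggles] = {
    "WD": ErrorToggles(wd=True),
    "H": ErrorToggles(height=True),
    "AGB": ErrorToggles(agb=True),
    "DBH": ErrorToggles(dbh_assign=True),
    "N_exp": ErrorToggles(n_exp=True),
    "AGB_cor": ErrorToggles(agb_cor=True),
    "classical": ErrorToggles.classical(),
    "ALL": ErrorToggles.all_sources(),
}

#: Rows of the per-source decomposition table: (label, scenario name
#: or None for the raw scientific dialect, source toggles).
VALIDATION_ROWS: tuple[tuple[str, str | None, str], ...] = (
    ("WD", None, "WD"),
    ("H", None, "H"),
    ("AGB", None, "AGB"),
    ("DBH_200", "dbh_200", "DBH"),
    ("DBH_120", "dbh_120", "DBH"),
    ("N_exp_light", "nexp_light", "N_exp"),
    ("N_exp_heavy", "nexp_heavy", "N_exp"),
    ("AGB_cor", "agb_cor", "AGB_cor"),
    ("ALL_best", "best", "ALL"),
    ("ALL_worst", "worst", "ALL"),
)


@dataclass
class ScenarioReport:
    scenario_name: str
    sources: str
    mean_cv_pct: float
    cv_ci: tuple[float, float]
    ma: MAResult | None
    n_plots: int
    per_plot: pd.DataFrame = field(repr=False, default=None)

    def to_row(self) -> dict:
        return {
            "scenario": self.scenario_name,
            "sources": self.sources,
            "mean_cv_pct": self.mean_cv_pct,
            "cv_q2.5": self.cv_ci[0],
            "cv_q97.5": self.cv_ci[1],
            "ma_slope": self.ma.slope if self.ma else np.nan,
            "ma_slope_lo": self.ma.slope_ci[0] if self.ma else np.nan,
            "ma_slope_hi": self.ma.slope_ci[1] if self.ma else np.nan,
            "ma_intercept": self.ma.intercept if self.ma else np.nan,
            "n_plots": self.n_plots,
        }


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def reference_estimates(
    plots,
    n_iter: int = 1000,
    seed: int = 0,
    height_model: HeightModel | None = None,
    agb_model: AGBModel | None = None,
) -> list[PlotAGBResults]:
    """Reference AGB per plot: Monte Carlo mean under classical sources only."""
    out = []
    for p in plots:
        model = PlotAGBModel(p, toggles=ErrorToggles.classical(),
                             height_model=height_model, agb_model=agb_model)
        out.append(model.fit(n_iter=n_iter, seed=plot_seed(seed, "ref:" + p.plot_id)))
    return out


def run_degradation_experiment(
    reference_plots,
    scenario: DegradationScenario | str,
    sources: ErrorToggles | str = "ALL",
    n_iter: int = 1000,
    seed: int = 0,
    dbh_model: WeibullDBHModel | None = None,
    height_model: HeightModel | None = None,
    agb_model: AGBModel | None = None,
    correction_model: CorrectionModel | None = None,
    reference: list[PlotAGBResults] | None = None,
    compute_ma: bool = True,
) -> ScenarioReport:
    """Degrade reference plots under a scenario, re-estimate, and compare.

    ``sources`` names the error sources propagated in the re-estimation
    (a key of ``SOURCE_TOGGLES`` or an explicit ``ErrorToggles``); the
    reference is always the classical-source Monte Carlo mean on the
    undegraded plots.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    sources_name = sources if isinstance(sources, str) else "custom"
    toggles = SOURCE_TOGGLES[sources] if isinstance(sources, str) else sources
    if reference is None:
        reference = reference_estimates(plots=reference_plots, n_iter=n_iter, seed=seed,
                                        height_model=height_model, agb_model=agb_model)

    rows = []
    est_means, ref_means, cvs = [], [], []
    for plot, ref in zip(reference_plots, reference):
        inv = degrade_plot(plot, scenario, seed=plot_seed(seed, "deg:" + plot.plot_id))
        model = PlotAGBModel(
            inv,
            dbh_model=dbh_model,
            height_model=height_model,
            agb_model=agb_model,
            correction_model=correction_model if inv.drop_10_20 else None,
            toggles=toggles,
        )
        est = model.fit(n_iter=n_iter, seed=plot_seed(seed, "est:" + plot.plot_id))
        est_means.append(est.mean_agb)
        ref_means.append(ref.mean_agb)
        cvs.append(est.cv_pct)
        rows.append({"plot_id": plot.plot_id, "ref_agb": ref.mean_agb,
                     "est_agb": est.mean_agb, "cv_pct": est.cv_pct})

    cvs = np.asarray(cvs)
    ma = None
    if compute_ma and len(est_means) >= 3:
        ma = major_axis(ref_means, est_means, n_boot=1000, seed=seed)
    q_lo, q_hi = np.percentile(cvs, [2.5, 97.5])
    return ScenarioReport(
        scenario_name=scenario.name or "custom",
        sources=sources_name,
        mean_cv_pct=float(cvs.mean()),
        cv_ci=(float(q_lo), float(q_hi)),
        ma=ma,
        n_plots=len(cvs),
        per_plot=pd.DataFrame(rows),
    )


def decompose_error_sources(
    reference_plots,
    n_iter: int = 1000,
    seed: int = 0,
    dbh_model: WeibullDBHModel | None = None,
    height_model: HeightModel | None = None,
    agb_model: AGBModel | None = None,
    correction_model: CorrectionModel | None = None,
    rows: tuple = VALIDATION_ROWS,
    compute_ma: bool = False,
) -> pd.DataFrame:
    """Per-source uncertainty table: one row per (scenario, source) pair.

    Rows with scenario ``None`` estimate the raw scientific-dialect plots
    with a single classical source; the others degrade first.
    """
    reference = reference_estimates(plots=reference_plots, n_iter=n_iter, seed=seed,
                                    height_model=height_model, agb_model=agb_model)
    out = []
    for label, scen_name, source in rows:
        if scen_name is None:
            cvs = []
            for p in reference_plots:
                model = PlotAGBModel(p, toggles=SOURCE_TOGGLES[source],
                                     height_model=height_model, agb_model=agb_model)
                res = model.fit(n_iter=n_iter, seed=plot_seed(seed, f"{label}:{p.plot_id}"))
                cvs.append(res.cv_pct)
            cvs = np.asarray(cvs)
            q_lo, q_hi = np.percentile(cvs, [2.5, 97.5])
            report = ScenarioReport(label, source, float(cvs.mean()),
                                    (float(q_lo), float(q_hi)), None, len(cvs))
        else:
            report = run_degradation_experiment(
                reference_plots, SCENARIOS[scen_name], source,
                n_iter=n_iter, seed=seed, dbh_model=dbh_model,
                height_model=height_model, agb_model=agb_model,
                correction_model=correction_model, reference=reference,
                compute_ma=compute_ma,
            )
        row = report.to_row()
        row["scenario"] = label
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Correction-model calibration and the standard validation summary
# ---------------------------------------------------------------------------

def calibrate_correction_model(
    plots,
    height_model: HeightModel | None = None,
    agb_model: AGBModel | None = None,
) -> CorrectionModel:
    """Fit the AGB₁₀₋₂₀ correction model on reference-dialect calibration plots.

    Per plot, AGB₁₀₋₂₀, AGB_≥20 and the shape metrics S and I are computed
    deterministically (no error draws) from the measured tree list; the
    correction model is then an OLS fit across plots. Its residual sd
    epsilon carries the across-plot variability the predictors miss.
    """
    hm = height_model or HeightModel()
    am = agb_model or AGBModel()
    rows = []
    for p in plots:
        dbh = p.trees["dbh"].to_numpy(dtype=float)
        wd = p.trees["wd_mean"].to_numpy(dtype=float)
        agb = tree_agb(wd, dbh, hm.predict(dbh), am) / p.area_ha
        a1020 = agb[dbh < 20.0].sum()
        age20 = agb[dbh >= 20.0].sum()
        class_sums = [agb[(dbh >= lo) & (dbh < lo + 10.0)].sum() for lo in SHAPE_CLASS_LOS]
        s, i = shape_metrics_from_class_agb(np.array(class_sums))
        rows.append((a1020, age20, float(s), float(i)))
    arr = np.array(rows)
    return fit_correction_model(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


def small_tree_agb_share(plots, height_model=None, agb_model=None) -> float:
    """Across-plot mean of 100 · AGB₁₀₋₂₀ / AGB_≥20 (deterministic allometry)."""
    hm = height_model or HeightModel()
    am = agb_model or AGBModel()
    shares = []
    for p in plots:
        dbh = p.trees["dbh"].to_numpy(dtype=float)
        wd = p.trees["wd_mean"].to_numpy(dtype=float)
        agb = tree_agb(wd, dbh, hm.predict(dbh), am)
        ge20 = agb[dbh >= 20.0].sum()
        if ge20 > 0:
            shares.append(100.0 * agb[dbh < 20.0].sum() / ge20)
    return float(np.mean(shares))


def standard_validation_summary(
    n_plots: int = 200,
    n_iter: int = 1000,
    seed: int = 0,
    n_calib: int = 1000,
    n_share_plots: int = 500,
    plot_area_ha: float = 0.5,
    stem_density: float = 500.0,
) -> dict[str, dict]:
    """The package's standard degrade-and-validate benchmark.

    Generates ``n_plots`` synthetic 0.5-ha reference plots from the default
    regional Weibull size model, computes the classical-source reference
    AGB per plot, then runs the named degradation scenarios and reports,
    for each quantity, its value and the problem size used:

    * ``ma_slope_dbh_200`` — major-axis slope of re-estimated (classical +
      diameter assignment, 200-cm open class) vs reference plot AGB;
    * ``cv_classical`` — mean plot CV, classical sources on raw plots;
    * ``cv_all_best`` / ``cv_all_worst`` — mean plot CV, all applicable
      sources under the bracketing degradation scenarios;
    * ``agb_share_10_20`` — mean 100·AGB₁₀₋₂₀/AGB_≥20;
    * ``cv_nexp_heavy`` — expansion-only CV, heaviest subsampling;
    * ``cv_dbh_200`` — assignment-only CV, 200-cm open class.
    """
    ss = np.random.SeedSequence(seed)
    pool_seed, plots_seed, calib_seed, share_seed, exp_seed = ss.spawn(5)
    pool = tuple(generate_taxon_table(50, pool_seed))
    forest = SyntheticForestConfig(plot_area_ha=plot_area_ha, stem_density=stem_density,
                                   taxon_pool=pool)
    plots = generate_plots(forest, n_plots, master_seed=plots_seed)
    calib = generate_plots(forest, n_calib, master_seed=calib_seed)
    share_plots = generate_plots(forest, n_share_plots, master_seed=share_seed)
    correction = calibrate_correction_model(calib)
    exp_seed = int(exp_seed.generate_state(1)[0] % (2**31))

    reference = reference_estimates(plots, n_iter=n_iter, seed=exp_seed)
    ref_cvs = np.array([r.cv_pct for r in reference])

    def run(scenario, sources):
        return run_degradation_experiment(
            plots, scenario, sources, n_iter=n_iter, seed=exp_seed,
            correction_model=correction, reference=reference,
        )

    dbh_ma = run("dbh_200", ErrorToggles(wd=True, height=True, agb=True, dbh_assign=True))
    dbh_only = run("dbh_200", "DBH")
    nexp_heavy = run("nexp_heavy", "N_exp")
    best = run("best", "ALL")
    worst = run("worst", "ALL")

    return {
        "ma_slope_dbh_200": {"value": float(dbh_ma.ma.slope), "n": n_plots},
        "cv_classical": {"value": float(ref_cvs.mean()), "n": n_plots},
        "cv_all_best": {"value": best.mean_cv_pct, "n": n_plots},
        "cv_all_worst": {"value": worst.mean_cv_pct, "n": n_plots},
        "agb_share_10_20": {"value": small_tree_agb_share(share_plots), "n": n_share_plots},
        "cv_nexp_heavy": {"value": nexp_heavy.mean_cv_pct, "n": n_plots},
        "cv_dbh_200": {"value": dbh_only.mean_cv_pct, "n": n_plots},
    }
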