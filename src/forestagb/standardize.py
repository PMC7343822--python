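"""Standardisation of management-inventory records to scientific-equivalent data.

Three operations bridge the gap between the two dialects:

1. **diameter assignment** — draw a continuous DBH for each tree recorded
   in a diameter class, by inverse-transform sampling from the fitted
   size distribution conditioned on the class bounds;
2. **small-tree expansion** — expand the count r observed in the sampled
   spatial fraction p of a class to the whole plot by adding a negative
   binomial draw X ~ NegBin(r, p) (failures before the r-th success,
   success probability p; E[r + X] = r/p), assigning taxa to simulated
   trees pro rata of the observed composition;
3. **AGB₁₀₋₂₀ correction** — when the 10–20 cm class was never sampled,
   predict its per-hectare biomass from AGB_≥20 and two shape metrics of
   the cumulated-biomass curve (slope S, intercept I) with a linear model
   AGB₁₀₋₂₀ = a + b·AGB_≥20 + c·S + d·I + ε.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .distributions import WeibullDBHModel

__all__ = [
    "assign_diameter",
    "expand_small_trees",
    "expected_total",
    "assign_species_pro_rata",
    "ShapeMetrics",
    "compute_shape_metrics",
    "shape_metrics_from_class_agb",
    "CorrectionModel",
    "fit_correction_model",
    "predict_agb_10_20",
    "SHAPE_CLASS_LOS",
]

#: Lower bounds of the diameter classes entering the S/I fit (cumulated
#: biomass from 20 cm up to 70 cm).
SHAPE_CLASS_LOS = (20.0, 30.0, 40.0, 50.0, 60.0)
_SHAPE_X = np.array([lo + 10.0 for lo in SHAPE_CLASS_LOS])  # class upper bounds


def assign_diameter(
    lo: float,
    hi: float | None,
    model: WeibullDBHModel,
    rng: np.random.Generator | None = None,
    size: int = 1,
    u=None,
) -> np.ndarray:
    """Continuous DBH draws for trees recorded in class [lo, hi).

    D = F⁻¹(F(lo) + u·(F(hi) − F(lo))) with u ~ Uniform(0, 1); ``hi=None``
    denotes the open class, bounded above by the model's d_max. Passing
    ``u`` explicitly (scalar or array) makes the draw deterministic.
    """
    if u is None:
        if rng is None:
            raise ValueError("either rng or u must be given")
        u = rng.uniform(size=size)
    return model.conditional_ppf(lo, hi, u)


def expand_small_trees(r: int, p: float, rng: np.random.Generator | None = None) -> int:
    """Expanded whole-plot count r + X with X ~ NegBin(r, p).

    X counts failures before the r-th success at success probability p,
    so E[X] = r(1−p)/p and E[r + X] = r/p, the natural inverse of
    binomial thinning with retention probability p. r = 0 or p = 1
    returns r unchanged.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("sampling fraction p must be in (0, 1]")
    if r < 0:
        raise ValueError("observed count r must be non-negative")
    if r == 0 or p == 1.0:
        return int(r)
    if rng is None:
        raise ValueError("rng required for stochastic expansion")
    return int(r + rng.negative_binomial(r, p))


def expected_total(r: int, p: float) -> int:
    """Deterministic stand-in for the expansion: r + round(E[X])."""
    if not 0.0 < p <= 1.0:
        raise ValueError("sampling fraction p must be in (0, 1]")
    if r == 0 or p == 1.0:
        return int(r)
    return int(r + round(r * (1.0 - p) / p))


def assign_species_pro_rata(
    n_new: int,
    observed_composition: Mapping[str, int],
    rng: np.random.Generator,
) -> list[str]:
    """Taxon labels for simulated trees, multinomial pro rata of observed counts."""
    if n_new < 0:
        raise ValueError("n_new must be non-negative")
    if n_new == 0:
        return []
    taxa = [t for t, n in observed_composition.items() if n > 0]
    counts = np.array([observed_composition[t] for t in taxa], dtype=float)
    if not taxa:
        raise ValueError("cannot assign taxa from an empty composition")
    probs = counts / counts.sum()
    idx = rng.choice(len(taxa), size=n_new, p=probs)
    return [taxa[i] for i in idx]


@dataclass(frozen=True)
class ShapeMetrics:
    """Slope S (Mg·ha⁻¹·cm⁻¹) and intercept I (Mg·ha⁻¹) of the
    cumulated-biomass-by-class line fitted from 20 cm up to 70 cm."""

    S: float
    I: float


def _shape_from_y(y: np.ndarray) -> tuple[float, float]:
    x = _SHAPE_X
    xbar = x.mean()
    slope = ((x - xbar) * (y - y.mean(axis=-1, keepdims=True))).sum(axis=-1) / (
        (x - xbar) ** 2
    ).sum()
    intercept = y.mean(axis=-1) - slope * xbar
    return slope, intercept


def compute_shape_metrics(class_agb: Mapping[float, float]) -> ShapeMetrics:
    """S and I from per-class AGB (Mg·ha⁻¹) of classes 20–30 … 60–70.

    y_j is the cumulative AGB of trees with 20 ≤ DBH < x_j for class
    upper bounds x_j ∈ {30, …, 70}; S and I are the OLS slope and
    intercept of y on x.
    """
    missing = [lo for lo in SHAPE_CLASS_LOS if lo not in class_agb]
    if missing:
        raise ValueError(f"missing diameter classes {missing} for shape metrics")
    y = np.cumsum([float(class_agb[lo]) for lo in SHAPE_CLASS_LOS])
    s, i = _shape_from_y(y)
    return ShapeMetrics(float(s), float(i))


def shape_metrics_from_class_agb(class_agb_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised S/I: rows are observations, columns the five classes 20…60."""
    y = np.cumsum(np.asarray(class_agb_matrix, dtype=float), axis=-1)
    return _shape_from_y(y)


@dataclass(frozen=True)
class CorrectionModel:
    """Linear model AGB₁₀₋₂₀ = a + b·AGB_≥20 + c·S + d·I + ε (all Mg·ha⁻¹).

    ``epsilon`` is the residual standard error; the error term is drawn
    N(0, epsilon²) per prediction and the result is floored at 0.
    """

    a: float
    b: float
    c: float
    d: float
    epsilon: float
    r2_calib: float = float("nan")

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")

    def predict(
        self,
        agb_ge20,
        s,
        i,
        rng: np.random.Generator | None = None,
        with_error: bool = False,
    ) -> np.ndarray:
        return predict_agb_10_20(agb_ge20, s, i, self, rng=rng, with_error=with_error)


def fit_correction_model(
    agb_10_20: Sequence[float],
    agb_ge20: Sequence[float],
    s: Sequence[float],
    i: Sequence[float],
) -> CorrectionModel:
    """OLS fit of the AGB₁₀₋₂₀ correction model on calibration plots."""
    y = np.asarray(agb_10_20, dtype=float)
    X = np.column_stack([
        np.asarray(agb_ge20, dtype=float),
        np.asarray(s, dtype=float),
        np.asarray(i, dtype=float),
    ])
    if len(y) < 10:
        raise ValueError("need at least 10 calibration plots")
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("rank-deficient calibration design")
    res = sm.OLS(y, exog).fit()
    a, b, c, d = (float(v) for v in res.params)
    return CorrectionModel(a, b, c, d, float(np.sqrt(res.mse_resid)), float(res.rsquared))


def predict_agb_10_20(
    agb_ge20,
    s,
    i,
    model: CorrectionModel,
    rng: np.random.Generator | None = None,
    with_error: bool = False,
) -> np.ndarray:
    """AGB of the unsampled 10–20 cm class (Mg·ha⁻¹), floored at zero."""
    agb_ge20 = np.asarray(agb_ge20, dtype=float)
    pred = model.a + model.b * agb_ge20 + model.c * np.asarray(s) + model.d * np.asarray(i)
    if with_error:
        if rng is None:
            raise ValueError("rng required when with_error is set")
        pred = pred + rng.normal(0.0, model.epsilon, size=np.shape(pred))
    return np.maximum(pred, 0.0)
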