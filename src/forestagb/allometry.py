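"""Tree-level allometric models and their stochastic error draws.

Three models turn an inventory record into tree aboveground biomass (AGB):

* wood density ρ (g/cm³), resolved from a reference table at the finest
  taxonomic level available (species → genus → family → dataset mean);
* height H (m) from an asymptotic height–diameter model
  H = a_H·(1 − exp(−b_H·D^c_H));
* tree AGB (Mg) from the pantropical power-law model
  AGB = α·(ρ·D²·H)^β / 1000.

Each model carries an error structure used by the Monte Carlo engine:
per-tree truncated-normal wood-density draws, per-tree additive height
residuals, and an AGB-model error split into a per-iteration draw of the
coefficients (shared across all trees of the plot, hence not averaging
out with tree count) plus an independent per-tree log-normal residual.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "WoodDensityRecord",
    "HeightModel",
    "AGBModel",
    "ErrorToggles",
    "WD_BOUNDS",
    "lookup_wood_density",
    "predict_height",
    "tree_agb",
    "draw_wood_density",
    "draw_heights",
    "draw_agb",
    "truncated_normal",
]

#: Physical bounds for wood-density draws (g/cm³): extreme values of the
#: global wood-density compilation.
WD_BOUNDS = (0.08, 1.39)

#: Minimum tree height (m): breast height, below which a DBH cannot exist.
MIN_HEIGHT = 1.3


@dataclass(frozen=True)
class WoodDensityRecord:
    value: float
    sd: float
    resolution_level: str  # species | genus | family | dataset

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("wood density must be positive")
        if self.sd < 0:
            raise ValueError("wood density sd must be non-negative")


@dataclass(frozen=True)
class HeightModel:
    """Asymptotic (Weibull-form) height–diameter model with regional defaults.

    Defaults are the central-Africa parametrisation of the regional H–D
    model; ``sigma_h`` is the residual standard deviation of predicted
    heights (m), applied as an additive normal error per tree.
    """

    a_h: float = 50.453
    b_h: float = 0.0471
    c_h: float = 0.8120
    sigma_h: float = 5.0

    def __post_init__(self) -> None:
        if not (self.a_h > 0 and self.b_h > 0 and self.c_h > 0):
            raise ValueError("height-model parameters must be positive")
        if self.sigma_h < 0:
            raise ValueError("sigma_h must be non-negative")

    def predict(self, dbh) -> np.ndarray:
        dbh = np.asarray(dbh, dtype=float)
        if np.any(dbh <= 0):
            raise ValueError("dbh must be positive")
        return self.a_h * (1.0 - np.exp(-self.b_h * dbh**self.c_h))


@dataclass(frozen=True)
class AGBModel:
    """Pantropical AGB power law AGB(kg) = α·(ρ·D²·H)^β.

    ``sigma_ln`` is the residual sd of the model on the log scale,
    drawn independently per tree; ``coef_rel_sd`` is the relative sd of
    the per-iteration normal draw of (α, β), shared across all trees of a
    plot within one Monte Carlo iteration. The default ``coef_rel_sd`` is
    calibrated so that the classical-error plot CV on default synthetic
    stands matches field-reported uncertainty levels (see docs/methods.md).
    """

    alpha: float = 0.0673
    beta: float = 0.976
    sigma_ln: float = 0.357
    coef_rel_sd: float = 0.0045

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")
        if self.sigma_ln < 0 or self.coef_rel_sd < 0:
            raise ValueError("error magnitudes must be non-negative")


@dataclass(frozen=True)
class ErrorToggles:
    """Which error sources the Monte Carlo engine propagates."""

    wd: bool = False
    height: bool = False
    agb: bool = False
    dbh_assign: bool = False
    n_exp: bool = False
    agb_cor: bool = False

    @classmethod
    def none(cls) -> "ErrorToggles":
        return cls()

    @classmethod
    def classical(cls) -> "ErrorToggles":
        """Wood density + height model + AGB model errors."""
        return cls(wd=True, height=True, agb=True)

    @classmethod
    def all_sources(cls) -> "ErrorToggles":
        return cls(wd=True, height=True, agb=True, dbh_assign=True, n_exp=True, agb_cor=True)

    def with_(self, **kw) -> "ErrorToggles":
        return replace(self, **kw)

    @property
    def any_on(self) -> bool:
        return any((self.wd, self.height, self.agb, self.dbh_assign, self.n_exp, self.agb_cor))


def predict_height(dbh, model: HeightModel) -> np.ndarray:
    """H = a_H·(1 − exp(−b_H·D^c_H)); increasing in D, bounded by a_H."""
    return model.predict(dbh)


def tree_agb(wd, dbh, h, model: AGBModel) -> np.ndarray:
    """Tree AGB in Mg from wood density (g/cm³), DBH (cm), height (m)."""
    wd = np.asarray(wd, dtype=float)
    dbh = np.asarray(dbh, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(wd <= 0) or np.any(dbh <= 0) or np.any(h <= 0):
        raise ValueError("wood density, dbh and height must be positive")
    return model.alpha * (wd * dbh**2 * h) ** model.beta / 1000.0


def lookup_wood_density(
    taxon: tuple[str | None, str | None, str | None],
    table: pd.DataFrame,
) -> WoodDensityRecord:
    """Resolve (family, genus, species) against a wood-density table.

    The table has columns ``family, genus, species, wd_mean, wd_sd``.
    Species-level match is preferred, then genus mean, then family mean,
    then the dataset mean; the sd of a pooled level is the sd of member
    means (dataset level: sd of all values).
    """
    if table is None or len(table) == 0:
        raise ValueError("wood density table is empty")
    family, genus, species = taxon
    if species is not None and genus is not None:
        hit = table[(table["genus"] == genus) & (table["species"] == species)]
        if len(hit):
            return WoodDensityRecord(
                float(hit["wd_mean"].mean()),
                float(hit["wd_sd"].mean()),
                "species",
            )
    if genus is not None:
        hit = table[table["genus"] == genus]
        if len(hit):
            sd = float(hit["wd_mean"].std(ddof=1)) if len(hit) > 1 else float(hit["wd_sd"].iloc[0])
            return WoodDensityRecord(float(hit["wd_mean"].mean()), sd, "genus")
    if family is not None and "family" in table.columns:
        hit = table[table["family"] == family]
        if len(hit):
            sd = float(hit["wd_mean"].std(ddof=1)) if len(hit) > 1 else float(hit["wd_sd"].iloc[0])
            return WoodDensityRecord(float(hit["wd_mean"].mean()), sd, "family")
    values = table["wd_mean"].to_numpy(dtype=float)
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else float(table["wd_sd"].iloc[0])
    return WoodDensityRecord(float(values.mean()), sd, "dataset")


def truncated_normal(
    mean, sd, bounds: tuple[float, float], rng: np.random.Generator, size=None
) -> np.ndarray:
    """Normal(mean, sd) draws truncated to ``bounds`` by rejection.

    Vectorised rejection: out-of-bound draws are redrawn until all fall
    inside. With the default wood-density bounds the acceptance rate is
    essentially 1, so the loop terminates immediately in practice.
    """
    mean = np.asarray(mean, dtype=float)
    shape = mean.shape if size is None else size
    mean = np.broadcast_to(mean, shape)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), shape)
    lo, hi = bounds
    out = np.atleast_1d(np.asarray(rng.normal(mean, sd)))
    mean1, sd1 = np.broadcast_to(mean, out.shape), np.broadcast_to(sd, out.shape)
    bad = (out < lo) | (out > hi)
    # zero-sd entries at the mean are inside by construction (validated inputs)
    while np.any(bad):
        out[bad] = rng.normal(mean1[bad], sd1[bad])
        bad = (out < lo) | (out > hi)
    return out.reshape(shape)


def draw_wood_density(
    wd_mean: np.ndarray, wd_sd: np.ndarray, rng: np.random.Generator, size=None
) -> np.ndarray:
    """Per-tree truncated-normal wood density draw."""
    return truncated_normal(wd_mean, wd_sd, WD_BOUNDS, rng, size=size)


def draw_heights(
    dbh: np.ndarray, model: HeightModel, rng: np.random.Generator | None
) -> np.ndarray:
    """Predicted heights, plus an additive N(0, sigma_h) residual when rng given.

    Heights are floored at breast height (1.3 m).
    """
    h = model.predict(dbh)
    if rng is not None and model.sigma_h > 0:
        h = h + rng.normal(0.0, model.sigma_h, size=h.shape)
    return np.maximum(h, MIN_HEIGHT)


def draw_agb(
    wd: np.ndarray,
    dbh: np.ndarray,
    h: np.ndarray,
    model: AGBModel,
    rng: np.random.Generator | None,
    coef_z: tuple[float, float] | np.ndarray | None = None,
) -> np.ndarray:
    """Tree AGB with (optionally) the AGB-model error applied.

    ``coef_z`` carries the per-iteration standard-normal pair perturbing
    (α, β); it must be shared across all trees of one iteration. When an
    ``rng`` is given, an independent per-tree log-normal residual
    exp(N(0, sigma_ln)) is applied on top.
    """
    alpha, beta = model.alpha, model.beta
    if coef_z is not None:
        z_a, z_b = coef_z
        alpha = alpha * (1.0 + model.coef_rel_sd * z_a)
        beta = beta * (1.0 + model.coef_rel_sd * z_b)
        alpha = np.maximum(alpha, 1e-12)
        beta = np.maximum(beta, 1e-12)
    agb = alpha * (wd * dbh**2 * h) ** beta / 1000.0
    if rng is not None and model.sigma_ln > 0:
        agb = agb * np.exp(rng.normal(0.0, model.sigma_ln, size=np.shape(agb)))
    return agb
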