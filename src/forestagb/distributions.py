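"""Tree diameter (DBH) distributions for binned, right-censored inventories.

Management inventories record stem diameters in 10-cm classes with an open
(right-censored) top class. To recover continuous diameters, a parametric
size distribution is fitted to the binned counts by maximum likelihood and
later used for conditional inverse-transform sampling within each class.

Three candidate families are supported (two-parameter Weibull, exponential,
two-parameter gamma), each defined on a truncated support [d_min, d_max].
Model selection across families and candidate d_max values uses AIC with
Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "WeibullDBHModel",
    "BinnedDiameterData",
    "DiameterDistributionModel",
    "DBHFitResult",
    "fit_dbh_model",
    "NoFitError",
]

FAMILIES = ("weibull", "exponential", "gamma")

#: Default scale/shape of the regional size distribution fitted to
#: central-African management inventories (2-parameter Weibull).
DEFAULT_SCALE = 8.593
DEFAULT_SHAPE = 0.737
DEFAULT_D_MIN = 10.0
DEFAULT_D_MAX = 400.0


class NoFitError(ValueError):
    """Raised when binned data cannot identify a size distribution."""


def _frozen_dist(family: str, scale: float, shape: float):
    if family == "weibull":
        return stats.weibull_min(shape, scale=scale)
    if family == "exponential":
        return stats.expon(scale=scale)
    if family == "gamma":
        return stats.gamma(shape, scale=scale)
    raise ValueError(f"unknown distribution family {family!r}; expected one of {FAMILIES}")


@dataclass(frozen=True)
class WeibullDBHModel:
    """Parametric DBH distribution truncated to [d_min, d_max].

    Despite the name (the Weibull is the default and recommended family),
    the same container carries the exponential and gamma candidates; for
    the exponential the shape parameter is ignored.

    Parameters
    ----------
    scale : float
        Scale parameter (cm); the λ of the Weibull.
    shape : float
        Shape parameter (dimensionless); the k of the Weibull.
    d_min, d_max : float
        Truncation bounds of the support (cm). d_min is the census
        threshold of the reference dialect (10 cm); d_max is the maximum
        diameter a tree may reach, which also bounds the open class.
    family : str
        One of ``weibull``, ``exponential``, ``gamma``.
    """

    scale: float = DEFAULT_SCALE
    shape: float = DEFAULT_SHAPE
    d_min: float = DEFAULT_D_MIN
    d_max: float = DEFAULT_D_MAX
    family: str = "weibull"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not (self.scale > 0 and self.shape > 0):
            raise ValueError("scale and shape must be positive")
        if not 0 < self.d_min < self.d_max:
            raise ValueError("need 0 < d_min < d_max")

    @cached_property
    def _dist(self):
        return _frozen_dist(self.family, self.scale, self.shape)

    # -- untruncated family ------------------------------------------------
    def cdf(self, x):
        return self._dist.cdf(x)

    def pdf(self, x):
        return self._dist.pdf(x)

    def ppf(self, q):
        return self._dist.ppf(q)

    # -- truncated distribution on [d_min, d_max] --------------------------
    @cached_property
    def _norm(self) -> tuple[float, float]:
        f_lo = float(self._dist.cdf(self.d_min))
        f_hi = float(self._dist.cdf(self.d_max))
        return f_lo, f_hi - f_lo

    def trunc_cdf(self, x):
        f_lo, span = self._norm
        x = np.asarray(x, dtype=float)
        out = (self._dist.cdf(np.clip(x, self.d_min, self.d_max)) - f_lo) / span
        return np.clip(out, 0.0, 1.0)

    def trunc_pdf(self, x):
        f_lo, span = self._norm
        x = np.asarray(x, dtype=float)
        inside = (x >= self.d_min) & (x <= self.d_max)
        return np.where(inside, self._dist.pdf(x) / span, 0.0)

    def trunc_rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-transform draws from the truncated distribution."""
        f_lo, span = self._norm
        u = rng.uniform(size=size)
        return np.asarray(self._dist.ppf(f_lo + u * span), dtype=float)

    def class_prob(self, lo: float, hi: float | None = None) -> float:
        """Probability mass of diameter class [lo, hi) under truncation.

        ``hi=None`` denotes the open class [lo, d_max].
        """
        hi = self.d_max if hi is None else min(hi, self.d_max)
        _, span = self._norm
        return float(self._dist.cdf(hi) - self._dist.cdf(max(lo, self.d_min))) / span

    def conditional_ppf(self, lo: float, hi: float | None, u) -> np.ndarray:
        """Quantile of the distribution conditioned on the class [lo, hi).

        This is the inverse-transform assignment kernel:
        D = F⁻¹(F(lo) + u·(F(hi) − F(lo))).
        """
        hi = self.d_max if hi is None else hi
        if lo < self.d_min - 1e-9 or hi > self.d_max + 1e-9 or hi <= lo:
            raise ValueError(f"class [{lo}, {hi}) outside support [{self.d_min}, {self.d_max}]")
        f_lo = self._dist.cdf(lo)
        f_hi = self._dist.cdf(hi)
        u = np.asarray(u, dtype=float)
        d = np.asarray(self._dist.ppf(f_lo + u * (f_hi - f_lo)), dtype=float)
        return np.clip(d, lo, hi)

    def conditional_median(self, lo: float, hi: float | None) -> float:
        return float(self.conditional_ppf(lo, hi, 0.5))

    def with_params(self, **kw) -> "WeibullDBHModel":
        return replace(self, **kw)


@dataclass(frozen=True)
class BinnedDiameterData:
    """Histogram of stem counts by diameter class, with an optional open class.

    ``class_lo``/``class_hi`` are the closed-class bounds (half-open
    [lo, hi) bins); ``open_lo`` is the lower bound of the right-censored
    class when present.
    """

    class_lo: tuple[float, ...]
    class_hi: tuple[float, ...]
    counts: tuple[int, ...]
    open_lo: float | None = None
    open_count: int = 0

    def __post_init__(self) -> None:
        if not (len(self.class_lo) == len(self.class_hi) == len(self.counts)):
            raise ValueError("class_lo, class_hi and counts must have equal length")
        if any(h <= l for l, h in zip(self.class_lo, self.class_hi)):
            raise ValueError("class_hi must exceed class_lo")
        if any(c < 0 for c in self.counts) or self.open_count < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_dbh(
        cls,
        dbh: np.ndarray,
        width: float = 10.0,
        open_threshold: float | None = None,
        d_min: float = DEFAULT_D_MIN,
    ) -> "BinnedDiameterData":
        """Bin continuous diameters into half-open classes (label = lower bound)."""
        dbh = np.asarray(dbh, dtype=float)
        lo_of = np.floor(dbh / width) * width
        if open_threshold is None:
            open_threshold = np.inf
        closed = lo_of[lo_of < open_threshold]
        n_open = int(np.sum(lo_of >= open_threshold))
        if closed.size:
            lo_max = closed.max()
        else:
            lo_max = d_min
        edges = np.arange(d_min, lo_max + width, width)
        lo_list, hi_list, n_list = [], [], []
        for lo in edges:
            n = int(np.sum(closed == lo))
            if n:
                lo_list.append(float(lo))
                hi_list.append(float(lo + width))
                n_list.append(n)
        open_lo = float(open_threshold) if np.isfinite(open_threshold) else None
        return cls(tuple(lo_list), tuple(hi_list), tuple(n_list), open_lo, n_open)

    @property
    def n_total(self) -> int:
        return int(sum(self.counts) + self.open_count)

    @property
    def n_cells(self) -> int:
        """Number of histogram cells with positive count (incl. open class)."""
        return sum(1 for c in self.counts if c > 0) + (1 if self.open_count > 0 else 0)


@dataclass
class DBHFitResult:
    """One fitted candidate (family, d_max) with its AIC bookkeeping."""

    model: WeibullDBHModel
    log_likelihood: float
    aic: float
    n_params: int
    converged: bool
    akaike_weight: float = field(default=float("nan"))


class DiameterDistributionModel:
    """Censored-binned maximum-likelihood model for one (family, d_max) candidate.

    The likelihood is multinomial over the histogram cells, with cell
    probabilities given by the family CDF normalised to the truncated
    support [d_min, d_max]; the open class contributes
    F(d_max) − F(open_lo).
    """

    def __init__(
        self,
        data: BinnedDiameterData,
        family: str = "weibull",
        d_min: float = DEFAULT_D_MIN,
        d_max: float = DEFAULT_D_MAX,
    ):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        if data.n_total == 0:
            raise NoFitError("all class counts are zero")
        if data.n_cells < 2:
            raise NoFitError("a single occupied diameter class cannot identify a distribution")
        self.data = data
        self.family = family
        self.d_min = float(d_min)
        self.d_max = float(d_max)
        self.n_params = 1 if family == "exponential" else 2

    def _params_to_model(self, log_params: np.ndarray) -> WeibullDBHModel:
        scale = float(np.exp(log_params[0]))
        shape = float(np.exp(log_params[1])) if self.n_params == 2 else 1.0
        return WeibullDBHModel(scale, shape, self.d_min, self.d_max, self.family)

    def loglike(self, log_params: np.ndarray) -> float:
        try:
            model = self._params_to_model(np.asarray(log_params, dtype=float))
        except (ValueError, OverflowError):
            return -np.inf
        d = self.data
        ll = 0.0
        for lo, hi, n in zip(d.class_lo, d.class_hi, d.counts):
            if n == 0:
                continue
            p = model.class_prob(lo, hi)
            if not p > 0:
                return -np.inf
            ll += n * np.log(p)
        if d.open_count > 0:
            if d.open_lo is None:
                raise ValueError("open_count > 0 but open_lo is None")
            p = model.class_prob(d.open_lo, None)
            if not p > 0:
                return -np.inf
            ll += d.open_count * np.log(p)
        return float(ll)

    def fit(self, start: Sequence[float] | None = None) -> DBHFitResult:
        """Maximise the multinomial log-likelihood (Nelder–Mead on log-params)."""
        if start is None:
            starts = [
                np.log([DEFAULT_SCALE, DEFAULT_SHAPE][: self.n_params]),
                np.log([20.0, 1.5][: self.n_params]),
            ]
        else:
            starts = [np.log(np.asarray(start, dtype=float))]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                lambda lp: -self.loglike(lp), x0, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        model = self._params_to_model(best.x)
        llf = -float(best.fun)
        aic = 2.0 * self.n_params - 2.0 * llf
        return DBHFitResult(model, llf, aic, self.n_params, bool(best.success))


def fit_dbh_model(
    data: BinnedDiameterData,
    families: Sequence[str] = FAMILIES,
    dmax_grid: Sequence[float] = (300.0, 350.0, 400.0, 450.0, 500.0),
    d_min: float = DEFAULT_D_MIN,
) -> list[DBHFitResult]:
    """Fit every (family, d_max) candidate and rank them by AIC.

    Returns results sorted by ascending AIC with Akaike weights
    w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2) over the whole candidate set.
    """
    results: list[DBHFitResult] = []
    for family in families:
        for d_max in dmax_grid:
            if data.open_lo is not None and data.open_lo >= d_max:
                continue  # open class empty of support under this candidate
            results.append(DiameterDistributionModel(data, family, d_min, d_max).fit())
    if not results:
        raise NoFitError("no admissible (family, d_max) candidate")
    aics = np.array([r.aic for r in results])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for r, wi in zip(results, w):
        r.akaike_weight = float(wi)
    return sorted(results, key=lambda r: r.aic)
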