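"""Fitting the ten candidate distribution families to a sum series.

The candidate roster, in the canonical comparison order, is

    Normal, Exponential, Beta, Pareto, Uniform, Laplace,
    Student's t, Logistic, Gumbel (right), F

Each family is fitted with the estimator appropriate to it:

* closed forms where they exist — Normal (sample mean, population-MLE
  standard deviation), Exponential (rate = 1/mean, no location shift),
  Pareto (x_m = min(x), alpha = n / sum(log(x_i/x_m))), Uniform
  (a = min, b = max), Laplace (location = median, scale = mean absolute
  deviation from the median, its MLE);
* Beta by MLE after min–max normalization of the data to [eps, 1-eps],
  with the normalization recorded so the fit can be evaluated back on
  the original temperature-sum scale;
* Student's t, Logistic and Gumbel by numeric MLE in location–scale
  form (Nelder–Mead, moment-based initialization);
* F by a method-of-moments estimate: the scale is profiled out through
  the first moment and the two degrees of freedom are matched to the
  second and third moments of the mean-standardized sample.

Exponential and Pareto deliberately get *no* affine extension: their
estimators pin the support, which is what makes them fit concentrated
temperature sums poorly — a property the downstream comparison relies on.

Evaluation (``pdf``/``cdf``/``ppf``/``sample``) always happens on the
original data scale; families fitted through a normalization record are
mapped back by the affine change of variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize, special, stats

from .frames import SumSeries

#: the closed roster, in comparison (and tie-break) order
FAMILIES: tuple[str, ...] = (
    "normal",
    "exponential",
    "beta",
    "pareto",
    "uniform",
    "laplace",
    "student_t",
    "logistic",
    "gumbel_r",
    "f",
)

_POSITIVE_ONLY = {"exponential", "pareto", "f"}
_MIN_N = {"student_t": 5, "f": 5}


class FitError(ValueError):
    """Base class for distribution-fitting failures."""


class DegenerateDataError(FitError):
    """Data carry no usable spread (e.g. all values equal)."""


class ConvergenceError(FitError):
    """A numeric estimator failed to converge."""


@dataclass(frozen=True)
class NormalizationRecord:
    """Affine map used before fitting, kept for back-transformation.

    The working variable is ``y = (x - x_min) / (x_max - x_min)``; for the
    Beta family y is additionally clipped to ``[eps, 1-eps]``.
    """

    x_min: float
    x_max: float
    eps: float = 0.0

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ValueError("x_max must exceed x_min")
        if not 0.0 <= self.eps < 0.5:
            raise ValueError("eps must lie in [0, 0.5)")

    @property
    def scale(self) -> float:
        return self.x_max - self.x_min

    def forward(self, x):
        return (np.asarray(x, float) - self.x_min) / self.scale

    def inverse(self, y):
        return self.x_min + np.asarray(y, float) * self.scale


@dataclass(frozen=True)
class FitParams:
    """One fitted family: named parameters, fitting method, optional normalization."""

    family: str
    params: Mapping[str, float]
    method: str  # closed_form | mle | moments
    normalization: NormalizationRecord | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))


def _as_array(sums) -> np.ndarray:
    x = sums.values if isinstance(sums, SumSeries) else np.asarray(sums, float)
    x = np.asarray(x, float).ravel()
    if x.size and not np.all(np.isfinite(x)):
        raise FitError("data contain non-finite values")
    return x


def normalize_unit(sums, eps: float = 1e-6) -> tuple[np.ndarray, NormalizationRecord]:
    """Min–max map to the unit interval, clipped to [eps, 1-eps].

    Requires at least two distinct values; constant data are degenerate
    (a Beta fit would be undefined).
    """
    x = _as_array(sums)
    if x.size < 2 or np.ptp(x) == 0:
        raise DegenerateDataError("need at least two distinct values to normalize")
    rec = NormalizationRecord(float(x.min()), float(x.max()), float(eps))
    y = rec.forward(x)
    if eps > 0:
        y = np.clip(y, eps, 1.0 - eps)
    return y, rec


# ---------------------------------------------------------------------------
# numeric MLE (location–scale form) for t / logistic / gumbel_r

_NM_OPTIONS = {"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000, "maxfev": 4000}


def _mle_locscale(dist, x: np.ndarray, init: list[float], n_shapes: int) -> list[float]:
    """Minimize the negative log-likelihood over (shapes, loc, log scale).

    Shape parameters and the scale are optimized on the log axis to keep
    them positive.  Raises :class:`ConvergenceError` on failure.
    """

    def pack(theta):
        shapes = [math.exp(t) for t in theta[:n_shapes]]
        loc, log_s = theta[n_shapes], theta[n_shapes + 1]
        return shapes, loc, math.exp(log_s)

    def nll(theta):
        shapes, loc, scale = pack(theta)
        with np.errstate(all="ignore"):
            ll = dist.logpdf(x, *shapes, loc=loc, scale=scale)
        if not np.all(np.isfinite(ll)):
            return 1e300
        return -float(ll.sum())

    theta0 = [math.log(v) for v in init[:n_shapes]] + [init[n_shapes], math.log(init[n_shapes + 1])]
    res = optimize.minimize(nll, theta0, method="Nelder-Mead", options=_NM_OPTIONS)
    if not res.success or not np.isfinite(res.fun) or res.fun >= 1e299:
        raise ConvergenceError(
            f"{dist.name} MLE did not converge after {res.nit} iterations: {res.message}"
        )
    shapes, loc, scale = pack(res.x)
    return [*shapes, loc, scale]


# ---------------------------------------------------------------------------
# F-distribution method of moments


def _fit_f_moments(x: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments estimate of (d1, d2) plus the profiled scale.

    The sample is standardized to unit mean (z = x / mean(x)), which
    profiles the scale out through the first moment; the model for z is
    F(d1, d2) / E[F].  The degrees of freedom are then matched to the
    *log*-moments of z — E[ln F] and Var[ln F] have exact digamma /
    trigamma closed forms and are far better conditioned than raw second
    and third moments, whose sample estimates are dominated by the F
    distribution's heavy right tail.  The scale mapping the fitted F back
    to the data is mean(x) * (d2 - 2) / d2.
    """
    mean_x = float(x.mean())
    lz = np.log(x / mean_x)
    m, v = float(lz.mean()), float(lz.var())
    if v <= 0:
        raise DegenerateDataError("F fit needs positive spread")

    def residuals(p):
        d1, d2 = p
        # E[ln F] = psi(d1/2) - ln(d1/2) - psi(d2/2) + ln(d2/2)
        mod_m = (
            special.digamma(d1 / 2) - math.log(d1 / 2)
            - special.digamma(d2 / 2) + math.log(d2 / 2)
            - math.log(d2 / (d2 - 2.0))  # the unit-mean standardization shift
        )
        mod_v = special.polygamma(1, d1 / 2) + special.polygamma(1, d2 / 2)
        return [mod_m - m, mod_v / v - 1.0]

    best = None
    for start in ((2.0, 10.0), (5.0, 30.0), (20.0, 100.0), (80.0, 400.0)):
        try:
            res = optimize.least_squares(
                residuals, start, bounds=([0.5, 2.05], [500.0, 500.0]),
                xtol=1e-14, ftol=1e-14,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise ConvergenceError("F method-of-moments estimate did not converge")
    d1, d2 = float(best.x[0]), float(best.x[1])
    scale = mean_x * (d2 - 2.0) / d2
    return d1, d2, scale


# ---------------------------------------------------------------------------
# per-family fitting


def fit_family(sums, family: str) -> FitParams:
    """Fit one family to the data with its designated estimator.

    Preconditions: sample size >= 3 (>= 5 for Student's t and F); strictly
    positive data for the positivity-constrained families (Exponential,
    Pareto, F); non-degenerate spread wherever a scale is estimated.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = _as_array(sums)
    min_n = _MIN_N.get(family, 3)
    if x.size < min_n:
        raise FitError(f"{family} fit needs at least {min_n} observations, got {x.size}")
    if family in _POSITIVE_ONLY and np.any(x <= 0):
        raise FitError(f"{family} fit requires strictly positive data")
    if np.ptp(x) == 0 and family != "exponential":
        raise DegenerateDataError(f"{family} fit is undefined for constant data")
    return _FITTERS[family](x)


def _fit_normal(x):
    mu = float(x.mean())
    sigma = float(x.std())  # population (MLE) std
    if sigma <= 0:
        raise DegenerateDataError("normal fit needs positive spread")
    return FitParams("normal", {"mu": mu, "sigma": sigma}, "closed_form")


def _fit_exponential(x):
    lam = 1.0 / float(x.mean())
    return FitParams("exponential", {"lam": lam}, "closed_form")


def _fit_beta(x):
    y, rec = normalize_unit(x, eps=1e-6)
    # boundary compression: the min-max map sends the sample extremes to the
    # very edges of (0, 1), where their log-likelihood terms would dominate
    # the MLE; pulling every point toward 1/2 by half a rank spacing keeps
    # the shapes finite and stable (standard practice for unit-interval fits)
    n = y.size
    y = (y * (n - 1) + 0.5) / n
    alpha, beta_, _, _ = stats.beta.fit(y, floc=0.0, fscale=1.0)
    if not (np.isfinite(alpha) and np.isfinite(beta_) and alpha > 0 and beta_ > 0):
        raise ConvergenceError("beta MLE returned invalid shape parameters")
    return FitParams(
        "beta", {"alpha": float(alpha), "beta": float(beta_)}, "mle", normalization=rec
    )


def _fit_pareto(x):
    x_m = float(x.min())
    logs = np.log(x / x_m)
    total = float(logs.sum())
    if total <= 0:
        raise DegenerateDataError("pareto fit is undefined for constant data")
    alpha = x.size / total
    return FitParams("pareto", {"alpha": float(alpha), "x_m": x_m}, "closed_form")


def _fit_uniform(x):
    a, b = float(x.min()), float(x.max())
    if not b > a:
        raise DegenerateDataError("uniform fit needs a < b")
    return FitParams("uniform", {"a": a, "b": b}, "closed_form")


def _fit_laplace(x):
    mu = float(np.median(x))
    b = float(np.mean(np.abs(x - mu)))
    if b <= 0:
        raise DegenerateDataError("laplace fit needs positive spread")
    return FitParams("laplace", {"mu": mu, "b": b}, "closed_form")


def _fit_student_t(x):
    std = float(x.std())
    g2 = float(stats.kurtosis(x, fisher=True))
    nu0 = 4.0 + 6.0 / g2 if g2 > 0.1 else 20.0
    nu0 = min(max(nu0, 2.5), 100.0)
    scale0 = std * math.sqrt((nu0 - 2.0) / nu0) if nu0 > 2 else std
    nu, loc, scale = _mle_locscale(stats.t, x, [nu0, float(x.mean()), scale0], 1)
    return FitParams("student_t", {"nu": nu, "loc": loc, "scale": scale}, "mle")


def _fit_logistic(x):
    s0 = float(x.std()) * math.sqrt(3.0) / math.pi
    loc, scale = _mle_locscale(stats.logistic, x, [float(x.mean()), s0], 0)
    return FitParams("logistic", {"mu": loc, "s": scale}, "mle")


def _fit_gumbel_r(x):
    beta0 = float(x.std()) * math.sqrt(6.0) / math.pi
    loc0 = float(x.mean()) - np.euler_gamma * beta0
    loc, scale = _mle_locscale(stats.gumbel_r, x, [loc0, beta0], 0)
    return FitParams("gumbel_r", {"mu": loc, "beta_g": scale}, "mle")


def _fit_f(x):
    d1, d2, scale = _fit_f_moments(x)
    rec = NormalizationRecord(0.0, scale)
    return FitParams("f", {"d1": d1, "d2": d2}, "moments", normalization=rec)


_FITTERS = {
    "normal": _fit_normal,
    "exponential": _fit_exponential,
    "beta": _fit_beta,
    "pareto": _fit_pareto,
    "uniform": _fit_uniform,
    "laplace": _fit_laplace,
    "student_t": _fit_student_t,
    "logistic": _fit_logistic,
    "gumbel_r": _fit_gumbel_r,
    "f": _fit_f,
}


# ---------------------------------------------------------------------------
# evaluation on the original data scale


def _frozen(fit: FitParams):
    """The scipy frozen distribution on the fit's working scale."""
    p = fit.params
    if fit.family == "normal":
        return stats.norm(p["mu"], p["sigma"])
    if fit.family == "exponential":
        return stats.expon(scale=1.0 / p["lam"])
    if fit.family == "beta":
        return stats.beta(p["alpha"], p["beta"])
    if fit.family == "pareto":
        return stats.pareto(p["alpha"], scale=p["x_m"])
    if fit.family == "uniform":
        return stats.uniform(p["a"], p["b"] - p["a"])
    if fit.family == "laplace":
        return stats.laplace(p["mu"], p["b"])
    if fit.family == "student_t":
        return stats.t(p["nu"], loc=p["loc"], scale=p["scale"])
    if fit.family == "logistic":
        return stats.logistic(p["mu"], p["s"])
    if fit.family == "gumbel_r":
        return stats.gumbel_r(p["mu"], p["beta_g"])
    if fit.family == "f":
        return stats.f(p["d1"], p["d2"])
    raise ValueError(f"unknown family {fit.family!r}")


def pdf(fit: FitParams, x) -> np.ndarray | float:
    """Density on the original data scale (0 outside the support)."""
    dist = _frozen(fit)
    rec = fit.normalization
    xa = np.asarray(x, float)
    if rec is None:
        out = dist.pdf(xa)
    else:
        out = dist.pdf(rec.forward(xa)) / rec.scale
    out = np.where(np.isfinite(out), out, 0.0)
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def cdf(fit: FitParams, x) -> np.ndarray | float:
    """Cumulative probability on the original data scale."""
    dist = _frozen(fit)
    rec = fit.normalization
    xa = np.asarray(x, float)
    out = dist.cdf(xa if rec is None else rec.forward(xa))
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def ppf(fit: FitParams, q) -> np.ndarray | float:
    """Quantile function on the original data scale."""
    dist = _frozen(fit)
    rec = fit.normalization
    y = dist.ppf(np.asarray(q, float))
    out = y if rec is None else rec.inverse(y)
    return float(out) if np.isscalar(q) else np.asarray(out)


def sample(fit: FitParams, n: int, seed=None) -> np.ndarray:
    """n reproducible draws from the fitted distribution, original scale."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    y = _frozen(fit).rvs(size=n, random_state=rng)
    rec = fit.normalization
    return np.asarray(y if rec is None else rec.inverse(y), float)


def fit_to_record(fit: FitParams) -> dict[str, str]:
    """Flat key-value form of a fit, for text reports."""
    rec = {"family": fit.family, "method": fit.method}
    for k, v in fit.params.items():
        rec[k] = f"{v:.6g}"
    if fit.normalization is not None:
        rec["x_min"] = f"{fit.normalization.x_min:.6g}"
        rec["x_max"] = f"{fit.normalization.x_max:.6g}"
        if fit.normalization.eps:
            rec["eps"] = f"{fit.normalization.eps:.3g}"
    return rec
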