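"""Parametric summaries of frailty-index distributions.

Individual-level data often cannot leave a secure trial repository, but the
parameters of a fitted distribution can.  This module fits lognormal,
gamma, Weibull and generalised gamma distributions to an FI sample by
maximum likelihood, compares fit with the Kolmogorov–Smirnov statistic, and
derives CDF-based summaries (category prevalences, upper centiles) that are
exportable without row-level data.

The generalised gamma uses the Stacy parameterisation

    f(x) = p / (a**d * Gamma(d / p)) * x**(d - 1) * exp(-(x / a)**p)

with scale ``a > 0``, shape ``d > 0`` and power ``p > 0``; ``p = 1`` gives
the gamma distribution and ``d = p`` the Weibull.  It maps onto
``scipy.stats.gengamma(a=d/p, c=p, scale=a)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import EmptySampleError, FitError

FAMILIES = ("lognormal", "gamma", "weibull", "gengamma")
#: Free parameter count per family (location fixed at 0 throughout).
N_PARAMS = {"lognormal": 2, "gamma": 2, "weibull": 2, "gengamma": 3}

MIN_SAMPLE = 30


@dataclass(frozen=True)
class FittedDistribution:
    """A maximum-likelihood fit of one positive-support family to an FI sample."""

    family: str
    params: Mapping[str, float]
    loglik: float
    n: int
    ks: float | None = None
    converged: bool = True
    message: str = ""
    _frozen: object = field(default=None, repr=False, compare=False)

    def frozen(self):
        """The scipy frozen distribution for this fit."""
        if self._frozen is not None:
            return self._frozen
        dist = _make_frozen(self.family, self.params)
        object.__setattr__(self, "_frozen", dist)
        return dist

    def cdf(self, x):
        return self.frozen().cdf(x)

    def ppf(self, q):
        return self.frozen().ppf(q)

    def pdf(self, x):
        return self.frozen().pdf(x)


def _make_frozen(family: str, params: Mapping[str, float]):
    if family == "lognormal":
        return stats.lognorm(s=params["sigma"], scale=math.exp(params["mu"]))
    if family == "gamma":
        return stats.gamma(params["shape"], scale=params["scale"])
    if family == "weibull":
        return stats.weibull_min(params["shape"], scale=params["scale"])
    if family == "gengamma":
        a, d, p = params["a"], params["d"], params["p"]
        return stats.gengamma(a=d / p, c=p, scale=a)
    raise FitError(f"unknown family {family!r}; expected one of {FAMILIES}")


def gengamma_distribution(a: float, d: float, p: float) -> FittedDistribution:
    """Construct a generalised-gamma :class:`FittedDistribution` directly
    from Stacy parameters (no fitting), e.g. for imported trial summaries."""
    if min(a, d, p) <= 0:
        raise FitError("Stacy parameters a, d, p must all be strictly positive")
    return FittedDistribution(
        family="gengamma", params={"a": a, "d": d, "p": p}, loglik=float("nan"), n=0
    )


def _validate_sample(sample, n_deficits: int | None) -> np.ndarray:
    x = np.asarray(sample, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < MIN_SAMPLE:
        raise EmptySampleError(f"need at least {MIN_SAMPLE} values to fit, got {len(x)}")
    if np.any(x < 0):
        raise FitError("frailty index values must be non-negative")
    if np.ptp(x) == 0:
        raise FitError("sample is constant; no parametric fit is identifiable")
    if np.any(x == 0):
        if n_deficits is None:
            raise FitError(
                "sample contains exact zeros; pass n_deficits so zeros can be "
                "shifted to 1/(2*n_deficits) before positive-support fitting"
            )
        x = np.where(x == 0, 1.0 / (2 * n_deficits), x)
    return x


def _gengamma_nll(theta: np.ndarray, x: np.ndarray) -> float:
    a, d, p = np.exp(theta)
    ad = d / p
    ll = stats.gengamma.logpdf(x, a=ad, c=p, scale=a)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(ll.sum())


def _fit_gengamma(x: np.ndarray) -> tuple[dict, float, bool, str]:
    """Multi-start MLE for the Stacy generalised gamma.

    Starts at the gamma MLE (p = 1), the Weibull MLE (d = p) and a
    heavy-left start; because those nested fits are themselves candidate
    solutions, the returned log-likelihood can never fall below theirs.
    """
    g_shape, _, g_scale = stats.gamma.fit(x, floc=0)
    w_shape, _, w_scale = stats.weibull_min.fit(x, floc=0)
    starts = [
        np.log([g_scale, g_shape, 1.0]),          # gamma member
        np.log([w_scale, w_shape, w_shape]),       # weibull member
        np.log([float(np.median(x)), 2.0, 0.5]),   # long-tailed start
    ]
    candidates: list[tuple[float, np.ndarray, bool, str]] = []
    for t0 in starts:
        candidates.append((_gengamma_nll(t0, x), t0, True, "start"))
        res = optimize.minimize(
            _gengamma_nll, t0, args=(x,), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000, "maxfev": 6000},
        )
        if np.isfinite(res.fun):
            candidates.append((float(res.fun), res.x, bool(res.success), res.message))
    nll, theta, ok, msg = min(candidates, key=lambda c: c[0])
    if not np.isfinite(nll):
        raise FitError("generalised gamma fit failed: non-finite likelihood at every start")
    a, d, p = np.exp(theta)
    return {"a": float(a), "d": float(d), "p": float(p)}, -nll, ok, str(msg)


def fit_parametric(
    sample, family: str, n_deficits: int | None = None
) -> FittedDistribution:
    """Maximum-likelihood fit of one family to an FI sample.

    Values must be positive; exact zeros (possible in low-frailty samples)
    are shifted to ``1 / (2 * n_deficits)`` when ``n_deficits`` is given,
    otherwise they are an error.  Location is fixed at 0 for every family.
    """
    x = _validate_sample(sample, n_deficits)
    if family == "lognormal":
        logs = np.log(x)
        mu, sigma = float(np.mean(logs)), float(np.std(logs))
        params = {"mu": mu, "sigma": sigma}
        conv, msg = True, "closed form"
    elif family == "gamma":
        shape, _, scale = stats.gamma.fit(x, floc=0)
        params = {"shape": float(shape), "scale": float(scale)}
        conv, msg = True, "scipy MLE, floc=0"
    elif family == "weibull":
        shape, _, scale = stats.weibull_min.fit(x, floc=0)
        params = {"shape": float(shape), "scale": float(scale)}
        conv, msg = True, "scipy MLE, floc=0"
    elif family == "gengamma":
        params, loglik, conv, msg = _fit_gengamma(x)
        return FittedDistribution(
            family=family, params=params, loglik=loglik, n=len(x), converged=conv, message=msg
        )
    else:
        raise FitError(f"unknown family {family!r}; expected one of {FAMILIES}")
    frozen = _make_frozen(family, params)
    loglik = float(np.sum(frozen.logpdf(x)))
    if not np.isfinite(loglik):
        raise FitError(f"{family} fit produced a non-finite log-likelihood")
    return FittedDistribution(
        family=family, params=params, loglik=loglik, n=len(x), converged=conv, message=msg
    )


def ks_statistic(sample, fitted: FittedDistribution) -> float:
    """Kolmogorov–Smirnov statistic D = sup |ECDF - F| using both one-sided
    ECDF limits at each observation (so D is exact, not grid-based)."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n == 0:
        raise EmptySampleError("KS statistic needs a non-empty sample")
    f = fitted.cdf(x)
    d_plus = np.max(np.arange(1, n + 1) / n - f)
    d_minus = np.max(f - np.arange(0, n) / n)
    return float(max(d_plus, d_minus))


def fit_with_ks(sample, family: str, n_deficits: int | None = None) -> FittedDistribution:
    fit = fit_parametric(sample, family, n_deficits=n_deficits)
    return replace(fit, ks=ks_statistic(np.asarray(sample, float), fit))


def select_best_fit(
    sample,
    families: Sequence[str] = FAMILIES,
    n_deficits: int | None = None,
    tie_tol: float | None = None,
) -> tuple[FittedDistribution, dict[str, FittedDistribution]]:
    """Fit several families and pick the one with the smallest KS statistic.

    KS differences smaller than the statistic's own sampling scale are
    treated as ties (default ``tie_tol = 0.5 / sqrt(n)``) and broken toward
    the family with fewer parameters, so a 2-parameter member is preferred
    over the generalised gamma when they fit equally well.  Returns the
    selected fit and the dict of all successful fits.
    """
    if len(families) == 0:
        raise FitError("no families supplied")
    fits: dict[str, FittedDistribution] = {}
    failures: dict[str, str] = {}
    for fam in families:
        try:
            fits[fam] = fit_with_ks(sample, fam, n_deficits=n_deficits)
        except (FitError, EmptySampleError) as exc:
            failures[fam] = str(exc)
    if not fits:
        raise FitError(f"all fits failed: {failures}")
    if tie_tol is None:
        n = next(iter(fits.values())).n
        tie_tol = 0.5 / math.sqrt(n)
    d_min = min(f.ks for f in fits.values())  # type: ignore[arg-type]
    candidates = [f for f in fits.values() if f.ks <= d_min + tie_tol]  # type: ignore[operator]
    best = min(candidates, key=lambda f: (N_PARAMS[f.family], f.ks))
    return best, fits


def model_summary(
    fitted: FittedDistribution,
    boundaries: Sequence[float] = (0.12, 0.24, 0.36),
    q: float = 0.99,
) -> dict:
    """CDF-based summary of a fitted distribution.

    Category prevalences (percent) are CDF differences over the category
    intervals, with the top category taking all remaining upper-tail mass;
    the quantile is the inverse CDF at ``q`` (checked against the CDF).
    """
    b = [0.0, *[float(x) for x in boundaries]]
    cdf_vals = [float(fitted.cdf(x)) for x in b] + [1.0]
    names = ("robust", "mild", "moderate", "severe")
    prevalence = {
        name: 100.0 * (cdf_vals[i + 1] - cdf_vals[i]) for i, name in enumerate(names)
    }
    quant = float(fitted.ppf(q))
    return {
        "family": fitted.family,
        "params": dict(fitted.params),
        "prevalence": prevalence,
        "quantile_q": q,
        "quantile": quant,
        "cdf_at_quantile": float(fitted.cdf(quant)),
    }
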