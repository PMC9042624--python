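"""Parametric survival distributions used as flexible-parametric baselines.

Four families are provided, each through a common :class:`DistributionSpec`
handle: exponential (rate ``lam``), Gompertz (shape ``eta``, rate ``b``),
generalized gamma in the Prentice location/scale/shape parameterization
(``mu``, ``sigma``, ``kappa``) and the original four-parameter generalized F
(``mu``, ``sigma``, shapes ``s1``, ``s2``).

All computation is done in log space; survival, hazard, cumulative hazard,
log-density, censored log-likelihood, quantiles and inverse-CDF sampling are
exposed as module functions.

Parameterizations
-----------------
Gompertz
    hazard ``h(t) = b * exp(eta * t)``, cumulative hazard
    ``Lambda(t) = (b/eta) * (exp(eta*t) - 1)`` (``b*t`` in the ``eta -> 0``
    limit, computed with ``expm1`` for stability).  For ``eta < 0`` the
    distribution is improper: ``S(t)`` plateaus at ``exp(b/eta) > 0`` and a
    draw may be infinite.

Generalized gamma (Prentice)
    With ``w = (log t - mu)/sigma`` and ``gamma = kappa**-2``,
    ``gamma * exp(kappa*w)`` follows a standard Gamma(``gamma``) variate for
    ``kappa > 0`` (upper tail for ``kappa < 0``); ``kappa = 0`` is the
    log-normal.  ``kappa = 1`` gives the Weibull, ``kappa = sigma = 1`` the
    exponential.

Generalized F (original parameterization)
    With ``w = (log t - mu)/sigma``, ``exp(w)`` follows a scaled beta-prime
    law whose density in ``w`` is
    ``(s1/s2)**s1 * exp(s1*w) / ((1 + s1*exp(w)/s2)**(s1+s2) * B(s1, s2))``.
    Equivalently ``exp(w) ~ F(2*s1, 2*s2)`` (Fisher's F), which this module
    exploits for the CDF and quantile.  As ``s2 -> inf`` the family tends to
    the generalized gamma with ``kappa = 1/sqrt(s1)``, ``sigma_gg =
    sigma/sqrt(s1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "survival",
    "log_survival",
    "cumulative_hazard",
    "hazard",
    "log_density",
    "density",
    "censored_loglik",
    "quantile",
    "sample",
    "ImproperDistributionError",
]

FAMILIES = ("exponential", "gompertz", "gengamma", "genf")

_PARAM_NAMES = {
    "exponential": ("lam",),
    "gompertz": ("eta", "b"),
    "gengamma": ("mu", "sigma", "kappa"),
    "genf": ("mu", "sigma", "s1", "s2"),
}

# parameters constrained strictly positive, per family
_POSITIVE = {
    "exponential": ("lam",),
    "gompertz": ("b",),
    "gengamma": ("sigma",),
    "genf": ("sigma", "s1", "s2"),
}


class ImproperDistributionError(ValueError):
    """Raised when sampling an improper distribution without an explicit policy."""


@dataclass(frozen=True)
class DistributionSpec:
    """A survival family plus a named parameter vector.

    Parameters
    ----------
    family
        One of ``exponential``, ``gompertz``, ``gengamma``, ``genf``.
    params
        Mapping of parameter names to values; the required names per family
        are ``lam`` / ``eta, b`` / ``mu, sigma, kappa`` / ``mu, sigma, s1, s2``.
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        expected = set(_PARAM_NAMES[self.family])
        got = set(self.params)
        if got != expected:
            raise ValueError(
                f"{self.family} requires parameters {sorted(expected)}, got {sorted(got)}"
            )
        for name in _POSITIVE[self.family]:
            if not np.isfinite(self.params[name]) or self.params[name] <= 0:
                raise ValueError(
                    f"{self.family} parameter {name!r} must be finite and > 0, "
                    f"got {self.params[name]}"
                )
        for name, value in self.params.items():
            if not np.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value}")

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    @property
    def n_params(self) -> int:
        return len(self.params)

    def as_flat_dict(self) -> dict:
        """Flat key-value representation for result files."""
        out = {"family": self.family}
        out.update({k: float(v) for k, v in self.params.items()})
        return out


def _check_times(t, positive: bool = False) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(np.isnan(t)):
        raise ValueError("times contain NaN")
    if positive:
        if np.any(t <= 0):
            raise ValueError("times must be strictly positive")
    elif np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t


def log_survival(spec: DistributionSpec, t) -> np.ndarray:
    """log S(t), vectorized over ``t >= 0``."""
    t = _check_times(t)
    p = spec.params
    if spec.family == "exponential":
        return -p["lam"] * t
    if spec.family == "gompertz":
        return -_gompertz_cumhaz(t, p["eta"], p["b"])
    if spec.family == "gengamma":
        return _gengamma_logsf(t, p["mu"], p["sigma"], p["kappa"])
    # genf
    return _genf_logsf(t, p["mu"], p["sigma"], p["s1"], p["s2"])


def survival(spec: DistributionSpec, t) -> np.ndarray:
    """Survival function S(t) = Pr(T > t)."""
    return np.exp(log_survival(spec, t))


def cumulative_hazard(spec: DistributionSpec, t) -> np.ndarray:
    """Cumulative hazard Lambda(t) = -log S(t)."""
    return -log_survival(spec, t)


def _gompertz_cumhaz(t, eta, b):
    # (b/eta)(e^{eta t} - 1); expm1 keeps the eta ~ 0 limit (b t) exact.
    t = np.asarray(t, dtype=float)
    if abs(eta) < 1e-300:
        return b * t
    with np.errstate(over="ignore"):  # overflow -> inf cumulative hazard (S=0)
        return (b / eta) * np.expm1(eta * t)


def _gengamma_logsf(t, mu, sigma, kappa):
    # mu may be a vector (per-subject location); broadcast against t
    t, mu = np.broadcast_arrays(np.asarray(t, dtype=float), mu)
    out = np.zeros(t.shape)
    pos = t > 0
    if not np.any(pos):
        return out
    w = (np.log(t[pos]) - mu[pos]) / sigma
    if kappa == 0.0:  # log-normal limit
        out[pos] = stats.norm.logsf(w)
        return out
    g = kappa**-2
    u = g * np.exp(kappa * w)
    if kappa > 0:
        sf = special.gammaincc(g, u)
    else:
        sf = special.gammainc(g, u)
    with np.errstate(divide="ignore"):
        out[pos] = np.log(sf)
    return out


def _genf_logsf(t, mu, sigma, s1, s2):
    t, mu = np.broadcast_arrays(np.asarray(t, dtype=float), mu)
    out = np.zeros(t.shape)
    pos = t > 0
    if not np.any(pos):
        return out
    w = (np.log(t[pos]) - mu[pos]) / sigma
    # exp(w) ~ F(2 s1, 2 s2); survival via the regularized incomplete beta of
    # the complement, computed directly for tail accuracy.
    z = s1 * np.exp(w)
    # S = I_{s2/(s2+z)}(s2, s1)
    sf = special.betainc(s2, s1, s2 / (s2 + z))
    with np.errstate(divide="ignore"):
        out[pos] = np.log(sf)
    return out


def log_density(spec: DistributionSpec, t) -> np.ndarray:
    """log f(t) for ``t > 0``."""
    t = _check_times(t, positive=True)
    p = spec.params
    if spec.family == "exponential":
        return np.log(p["lam"]) - p["lam"] * t
    if spec.family == "gompertz":
        return np.log(p["b"]) + p["eta"] * t - _gompertz_cumhaz(t, p["eta"], p["b"])
    if spec.family == "gengamma":
        return _gengamma_logpdf(t, p["mu"], p["sigma"], p["kappa"])
    return _genf_logpdf(t, p["mu"], p["sigma"], p["s1"], p["s2"])


def _gengamma_logpdf(t, mu, sigma, kappa):
    w = (np.log(t) - mu) / sigma
    if kappa == 0.0:
        return stats.norm.logpdf(w) - np.log(sigma * t)
    g = kappa**-2
    return (
        np.log(abs(kappa))
        - np.log(sigma * t)
        - special.gammaln(g)
        + g * np.log(g)
        + g * (kappa * w - np.exp(kappa * w))
    )


def _genf_logpdf(t, mu, sigma, s1, s2):
    w = (np.log(t) - mu) / sigma
    return (
        s1 * (np.log(s1) - np.log(s2))
        + s1 * w
        - (s1 + s2) * np.log1p(s1 * np.exp(w) / s2)
        - special.betaln(s1, s2)
        - np.log(sigma * t)
    )


def density(spec: DistributionSpec, t) -> np.ndarray:
    return np.exp(log_density(spec, t))


def hazard(spec: DistributionSpec, t) -> np.ndarray:
    """Hazard h(t) = f(t)/S(t); t=0 allowed only where the limit is finite."""
    t = np.asarray(t, dtype=float)
    if spec.family == "exponential":
        _check_times(t)
        return np.full_like(t, spec["lam"])
    if spec.family == "gompertz":
        _check_times(t)
        return spec["b"] * np.exp(spec["eta"] * t)
    if np.any(t <= 0):
        raise ValueError(f"hazard of {spec.family} requires t > 0")
    return np.exp(log_density(spec, t) - log_survival(spec, t))


def censored_loglik(spec: DistributionSpec, times, events) -> float:
    """Right-censored log-likelihood: sum of log f over events, log S over censored.

    Returns ``-inf`` (rather than raising) when a time is impossible under the
    parameters, so optimizers can step through bad regions.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.shape != events.shape:
        raise ValueError(
            f"times and events have different shapes: {times.shape} vs {events.shape}"
        )
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("events must be 0/1")
    events = events.astype(bool)
    if np.any(times < 0) or np.any(times[events] <= 0):
        return -np.inf
    with np.errstate(over="ignore", invalid="ignore"):
        ll = 0.0
        if np.any(events):
            ll += float(np.sum(log_density(spec, times[events])))
        if np.any(~events):
            ll += float(np.sum(log_survival(spec, times[~events])))
    if not np.isfinite(ll):
        return -np.inf
    return ll


def quantile(spec: DistributionSpec, q) -> np.ndarray:
    """Inverse CDF: smallest t with F(t) >= q, for q in [0, 1)."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("quantile levels must lie in [0, 1)")
    p = spec.params
    if spec.family == "exponential":
        return -np.log1p(-q) / p["lam"]
    if spec.family == "gompertz":
        eta, b = p["eta"], p["b"]
        e = -np.log1p(-q)  # target cumulative hazard
        if abs(eta) < 1e-300:
            return e / b
        arg = 1.0 + eta * e / b
        out = np.full_like(q, np.inf)
        ok = arg > 0
        out[ok] = np.log(arg[ok]) / eta
        return out
    if spec.family == "gengamma":
        mu, sigma, kappa = p["mu"], p["sigma"], p["kappa"]
        if kappa == 0.0:
            w = stats.norm.ppf(q)
        else:
            g = kappa**-2
            u = special.gammaincinv(g, q) if kappa > 0 else special.gammainccinv(g, q)
            w = np.log(u / g) / kappa
        return np.exp(mu + sigma * w)
    mu, sigma, s1, s2 = p["mu"], p["sigma"], p["s1"], p["s2"]
    fq = stats.f.ppf(q, 2 * s1, 2 * s2)
    return np.exp(mu + sigma * np.log(fq))


def sample(
    spec: DistributionSpec,
    n: int,
    rng_seed,
    *,
    allow_improper: bool = False,
) -> np.ndarray:
    """Draw ``n`` inverse-CDF samples.

    A Gompertz with negative shape is improper (probability ``exp(b/eta)`` of
    never failing); by default this raises :class:`ImproperDistributionError`.
    With ``allow_improper=True`` such draws come back as ``inf`` and the
    caller must censor them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if (
        spec.family == "gompertz"
        and spec["eta"] < 0
        and not allow_improper
    ):
        raise ImproperDistributionError(
            "Gompertz with eta < 0 is improper (positive mass at infinity); "
            "pass allow_improper=True to receive inf draws for censoring"
        )
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    u = rng.uniform(size=n)
    return quantile(spec, u)
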