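"""Stage-2 survival model fitting on PLS scores.

Flexible parametric models (exponential, Gompertz, generalized gamma,
generalized F) are fit by censored maximum likelihood with the components
entering the location parameter — the log rate for exponential/Gompertz
(proportional-hazards form) and the log-time location ``mu`` for the
generalized gamma/F (accelerated-failure-time form).  Ancillary scale/shape
parameters are covariate-free.  A Cox model with Breslow tie handling and
Breslow baseline serves as the semiparametric reference.

Optimization is quasi-Newton (BFGS) on transformed parameters (log scale for
positive quantities), seeded from an exponential fit and from jittered
restarts; the generalized F starts from the generalized-gamma fit mapped to
the nested point.  Non-convergence is reported, never silently ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .distributions import (
    DistributionSpec,
    _genf_logpdf,
    _genf_logsf,
    _gengamma_logpdf,
    _gengamma_logsf,
    _gompertz_cumhaz,
    cumulative_hazard,
)
from .pls import PLSDecomposition, back_project, transform

__all__ = [
    "FittedModel",
    "fit_fpm",
    "fit_cox",
    "compare",
    "cumhaz_curve",
    "model_loglik",
]

_N_ANCILLARY = {"exponential": 1, "gompertz": 2, "gengamma": 3, "genf": 4}


@dataclass
class FittedModel:
    """A fitted stage-2 survival model.

    ``baseline_spec`` holds the distribution at zero scores (the intercept is
    folded into the rate/location parameter); ``component_coefs`` act on the
    log rate (exponential, Gompertz) or the location ``mu`` (generalized
    gamma/F).  For ``family == "cox"`` the baseline is the Breslow estimator
    stored in ``baseline_hazard``.
    """

    family: str
    component_coefs: np.ndarray
    baseline_spec: DistributionSpec | None
    loglik: float
    n_params: int
    n_obs: int
    n_events: int
    converged: bool
    covariate_coefs: np.ndarray | None = None
    grad_norm: float = np.nan
    baseline_hazard: pd.DataFrame | None = None  # cox only: time, increment
    diagnostics: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n_obs) * self.n_params

    @property
    def n_components(self) -> int:
        return len(self.component_coefs)

    def summary_row(self) -> dict:
        return {
            "family": self.family,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
        }


def _validate_inputs(scores, times, events):
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.size == 0:
        scores = scores.reshape(len(times), 0)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("events must be coded 0/1")
    events = events.astype(int)
    if times.shape != events.shape or scores.shape[0] != times.shape[0]:
        raise ValueError("scores, times and events must have matching lengths")
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if np.any(times < 0) or np.any(times[events == 1] <= 0):
        raise ValueError("times must be >= 0 and > 0 for events")
    return scores, times, events


def model_loglik(family, theta, scores, times, events):
    """Censored log-likelihood of the AFT/PH construction at raw parameters.

    ``theta`` layout: ``[intercept, coefs (A), ancillary...]`` with ancillary
    = [] (exponential), [eta] (gompertz), [log sigma, kappa] (gengamma),
    [log sigma, log s1, log s2] (genf).  Returns ``-inf`` when the parameters
    are impossible, so optimizers can probe freely.
    """
    A = scores.shape[1]
    intercept = theta[0]
    lp = intercept + scores @ theta[1 : 1 + A]
    anc = theta[1 + A :]
    ev = events == 1
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if family == "exponential":
            lam = np.exp(lp)
            logf = lp - lam * times
            logS = -lam * times
        elif family == "gompertz":
            eta = anc[0]
            b = np.exp(lp)
            ch = _gompertz_cumhaz(times, eta, b)
            logf = lp + eta * times - ch
            logS = -ch
        elif family == "gengamma":
            sigma = np.exp(anc[0])
            kappa = anc[1]
            logf = _gengamma_logpdf(times, lp, sigma, kappa)
            logS = _gengamma_logsf(times, lp, sigma, kappa)
        elif family == "genf":
            sigma, s1, s2 = np.exp(anc)
            logf = _genf_logpdf(times, lp, sigma, s1, s2)
            logS = _genf_logsf(times, lp, sigma, s1, s2)
        else:
            raise ValueError(f"unknown family {family!r}")
        ll = float(np.sum(np.where(ev, logf, logS)))
    return ll if np.isfinite(ll) else -np.inf


def _theta_to_spec(family, theta, A) -> tuple[DistributionSpec, np.ndarray]:
    intercept = theta[0]
    coefs = np.asarray(theta[1 : 1 + A], dtype=float)
    anc = theta[1 + A :]
    if family == "exponential":
        spec = DistributionSpec("exponential", {"lam": float(np.exp(intercept))})
    elif family == "gompertz":
        spec = DistributionSpec(
            "gompertz", {"eta": float(anc[0]), "b": float(np.exp(intercept))}
        )
    elif family == "gengamma":
        spec = DistributionSpec(
            "gengamma",
            {
                "mu": float(intercept),
                "sigma": float(np.exp(anc[0])),
                "kappa": float(anc[1]),
            },
        )
    else:
        spec = DistributionSpec(
            "genf",
            {
                "mu": float(intercept),
                "sigma": float(np.exp(anc[0])),
                "s1": float(np.exp(anc[1])),
                "s2": float(np.exp(anc[2])),
            },
        )
    return spec, coefs


def _exponential_start(scores, times, events):
    A = scores.shape[1]
    lam0 = max(events.sum(), 0.5) / times.sum()
    return np.concatenate([[np.log(lam0)], np.zeros(A)])


def _starts_for(family, scores, times, events, exp_theta, gg_theta=None):
    """Primary start point(s) for each family, seeded from nested fits."""
    A = scores.shape[1]
    starts = []
    if family == "exponential":
        starts.append(exp_theta.copy())
    elif family == "gompertz":
        # exponential is the eta -> 0 boundary of the Gompertz
        starts.append(np.concatenate([exp_theta, [1e-3]]))
        starts.append(np.concatenate([exp_theta, [-1e-3]]))
    elif family == "gengamma":
        # exponential == gengamma(mu=-log lam, sigma=1, kappa=1); the AFT
        # location flips the sign of PH log-rate coefficients
        mu = np.concatenate([[-exp_theta[0]], -exp_theta[1 : 1 + A]])
        starts.append(np.concatenate([mu, [0.0, 1.0]]))
        starts.append(np.concatenate([mu, [0.0, 0.5]]))
    elif family == "genf":
        if gg_theta is not None:
            mu, coefs = gg_theta[0], gg_theta[1 : 1 + A]
            sigma, kappa = np.exp(gg_theta[1 + A]), gg_theta[1 + A + 1]
            if kappa > 0.05:
                # genf(mu, sigma*sqrt(s1), s1, s2->inf) -> gengamma(mu, sigma, kappa)
                s1 = min(kappa**-2, 50.0)
                starts.append(
                    np.concatenate(
                        [[mu], coefs, [np.log(sigma / kappa), np.log(s1), 3.0]]
                    )
                )
        mu = np.concatenate([[-exp_theta[0]], -exp_theta[1 : 1 + A]])
        starts.append(np.concatenate([mu, [0.0, 0.0, 0.0]]))  # log-logistic-ish
    return starts


def fit_fpm(
    scores,
    times,
    events,
    family: str,
    *,
    decomp: PLSDecomposition | None = None,
    n_restarts: int = 2,
) -> FittedModel:
    """Fit a flexible parametric model on PLS scores by censored MLE.

    Components enter the log rate (exponential/Gompertz) or location
    (generalized gamma/F) linearly; ancillary parameters are covariate-free.
    On top of the nested-fit start points, ``n_restarts`` jittered restarts
    (fixed internal seed) guard against local optima.  If ``decomp`` is given
    the component coefficients are back-projected to the covariate scale
    (sign-flipped for the PH families so that, as for the AFT families,
    positive always means longer survival).
    """
    if family not in _N_ANCILLARY:
        raise ValueError(f"unknown family {family!r}; use fit_cox for cox")
    scores, times, events = _validate_inputs(scores, times, events)
    A = scores.shape[1]
    n_params = A + _N_ANCILLARY[family]

    exp_theta = _exponential_start(scores, times, events)
    if family != "exponential":
        exp_fit = _optimize("exponential", [exp_theta], scores, times, events)
        if exp_fit is not None:
            exp_theta = exp_fit[0]
    gg_theta = None
    if family == "genf":
        gg = fit_fpm(scores, times, events, "gengamma", n_restarts=n_restarts)
        if gg.converged:
            p = gg.baseline_spec.params
            gg_theta = np.concatenate(
                [[p["mu"]], gg.component_coefs, [np.log(p["sigma"]), p["kappa"]]]
            )

    starts = _starts_for(family, scores, times, events, exp_theta, gg_theta)
    rng = np.random.default_rng(20220419)  # internal, fixed: jitter only
    base = starts[0]
    for _ in range(n_restarts):
        starts.append(base + rng.normal(scale=0.3, size=base.size))

    best = _optimize(family, starts, scores, times, events)
    if best is None:
        return FittedModel(
            family=family,
            component_coefs=np.zeros(A),
            baseline_spec=None,
            loglik=-np.inf,
            n_params=n_params,
            n_obs=len(times),
            n_events=int(events.sum()),
            converged=False,
            diagnostics={"reason": "all starts produced non-finite likelihood"},
        )
    theta, ll, grad_norm, success = best
    spec, coefs = _theta_to_spec(family, theta, A)
    cov_coefs = None
    if decomp is not None and A > 0:
        reported = coefs if family in ("gengamma", "genf") else -coefs
        cov_coefs = back_project(decomp, reported)
    return FittedModel(
        family=family,
        component_coefs=coefs,
        baseline_spec=spec,
        loglik=ll,
        n_params=n_params,
        n_obs=len(times),
        n_events=int(events.sum()),
        converged=success,
        covariate_coefs=cov_coefs,
        grad_norm=grad_norm,
        diagnostics={"theta": theta.tolist()},
    )


def _optimize(family, starts, scores, times, events):
    """Minimize the negative log-likelihood from multiple starts; keep the best."""

    def nll(theta):
        return -model_loglik(family, theta, scores, times, events)

    best = None
    for x0 in starts:
        if not np.isfinite(nll(np.asarray(x0, dtype=float))):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                nll,
                x0,
                method="BFGS",
                jac="3-point",  # central differences beat the fwd-diff noise floor
                options={"gtol": 1e-9, "maxiter": 500},
            )
            # polish: BFGS with numeric gradients sometimes stops early
            res2 = optimize.minimize(
                nll,
                res.x,
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 4000},
            )
        theta = res2.x if res2.fun <= res.fun else res.x
        ll = -min(res.fun, res2.fun)
        if not np.isfinite(ll):
            continue
        grad = optimize.approx_fprime(theta, nll, 1.49e-8 * np.maximum(np.abs(theta), 1.0))
        grad_norm = float(np.max(np.abs(grad)) / (1.0 + abs(ll)))
        success = bool(res.success or res2.success or grad_norm < 1e-5)
        cand = (theta, ll, grad_norm, success)
        if best is None or ll > best[1] + 1e-10 or (
            abs(ll - best[1]) <= 1e-10 and success and not best[3]
        ):
            best = cand
    return best


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties, Breslow baseline)
# ---------------------------------------------------------------------------


def _cox_neg_logpl(beta, scores, times, events):
    """Negative Breslow partial log-likelihood (vectorized over risk sets)."""
    lp = scores @ beta
    order = np.argsort(-times, kind="stable")  # descending time
    lp_o = lp[order]
    t_o = times[order]
    ev_o = events[order] == 1
    # log cumulative sum of exp(lp) over the risk set {j: t_j >= t_i};
    # shift by the global max so the running sum cannot overflow
    m = lp_o.max()
    csum = np.cumsum(np.exp(lp_o - m))
    logrisk = np.log(csum) + m
    # Breslow ties: every subject with the same time shares the full risk set,
    # i.e. the cumulative sum at the last position of its (descending) group
    n = len(t_o)
    group_end = np.flatnonzero(np.r_[t_o[1:] != t_o[:-1], True])
    logrisk_tied = logrisk[group_end[np.searchsorted(group_end, np.arange(n))]]
    return -float(np.sum(lp_o[ev_o] - logrisk_tied[ev_o]))


def _cox_neg_grad(beta, scores, times, events):
    """Analytic gradient of the negative Breslow partial log-likelihood."""
    lp = scores @ beta
    order = np.argsort(-times, kind="stable")
    s_o = scores[order]
    lp_o = lp[order]
    t_o = times[order]
    ev_o = events[order] == 1
    m = lp_o.max()
    w = np.exp(lp_o - m)
    denom = np.cumsum(w)
    numer = np.cumsum(s_o * w[:, None], axis=0)
    n = len(t_o)
    group_end = np.flatnonzero(np.r_[t_o[1:] != t_o[:-1], True])
    idx = group_end[np.searchsorted(group_end, np.arange(n))]
    risk_mean = numer[idx] / denom[idx][:, None]
    return np.sum(risk_mean[ev_o] - s_o[ev_o], axis=0)


def cox_partial_loglik(beta, scores, times, events) -> float:
    """Breslow partial log-likelihood at ``beta``."""
    scores, times, events = _validate_inputs(scores, times, events)
    return -_cox_neg_logpl(np.asarray(beta, dtype=float), scores, times, events)


def _breslow_baseline(beta, scores, times, events) -> pd.DataFrame:
    """Breslow baseline cumulative-hazard increments at distinct event times."""
    lp = scores @ beta
    risk = np.exp(lp)
    event_times = np.unique(times[events == 1])
    inc = np.empty_like(event_times)
    for i, s in enumerate(event_times):
        d = np.sum((times == s) & (events == 1))
        inc[i] = d / risk[times >= s].sum()
    return pd.DataFrame({"time": event_times, "increment": inc})


def fit_cox(scores, times, events, *, decomp: PLSDecomposition | None = None) -> FittedModel:
    """Cox proportional hazards on PLS scores (Breslow ties and baseline)."""
    scores, times, events = _validate_inputs(scores, times, events)
    A = scores.shape[1]
    if A == 0:
        raise ValueError("Cox model requires at least one component")
    variances = scores[events == 1].std(axis=0) if events.sum() > 1 else scores.std(axis=0)
    if np.any(scores.std(axis=0) == 0):
        return FittedModel(
            family="cox",
            component_coefs=np.zeros(A),
            baseline_spec=None,
            loglik=-np.inf,
            n_params=A,
            n_obs=len(times),
            n_events=int(events.sum()),
            converged=False,
            diagnostics={"reason": "zero-variance component: flat partial likelihood"},
        )
    res = optimize.minimize(
        _cox_neg_logpl,
        np.zeros(A),
        args=(scores, times, events),
        jac=_cox_neg_grad,
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    grad = _cox_neg_grad(res.x, scores, times, events)
    ll = -float(res.fun)
    grad_norm = float(np.max(np.abs(grad)) / (1.0 + abs(ll)))
    converged = bool(res.success or grad_norm < 1e-5) and np.all(np.abs(res.x) < 50)
    cov_coefs = None
    if decomp is not None:
        # hazard scale: flip so positive = longer survival, as for AFT reports
        cov_coefs = back_project(decomp, -res.x)
    return FittedModel(
        family="cox",
        component_coefs=res.x,
        baseline_spec=None,
        loglik=ll,
        n_params=A,
        n_obs=len(times),
        n_events=int(events.sum()),
        converged=converged,
        covariate_coefs=cov_coefs,
        grad_norm=grad_norm,
        baseline_hazard=_breslow_baseline(res.x, scores, times, events),
        diagnostics={"variances": variances.tolist()},
    )


def compare(models) -> pd.DataFrame:
    """Rank fitted models by AIC (ties by BIC then family name).

    All models must be fit on the same data (checked via n_obs/n_events).
    """
    models = list(models)
    if not models:
        raise ValueError("no models to compare")
    key = (models[0].n_obs, models[0].n_events)
    for m in models:
        if (m.n_obs, m.n_events) != key:
            raise ValueError(
                "models were fit on different datasets "
                f"(n_obs/n_events {key} vs {(m.n_obs, m.n_events)})"
            )
    rows = [m.summary_row() for m in models]
    df = pd.DataFrame(rows)
    return df.sort_values(["aic", "bic", "family"], kind="stable").reset_index(drop=True)


def cumhaz_curve(
    model: FittedModel,
    decomp: PLSDecomposition | None,
    x_profile,
    t_grid,
) -> pd.DataFrame:
    """Cumulative hazard over ``t_grid`` at a covariate profile.

    Parametric families give the smooth closed-form curve at the profile's
    linear predictor; the Cox model gives the Breslow step function.  Grid
    points that would overflow the Gompertz exponential are clipped with a
    warning.
    """
    if not model.converged:
        raise ValueError("cumhaz_curve requires a converged model")
    t_grid = np.asarray(t_grid, dtype=float)
    if decomp is not None:
        s = transform(decomp, np.asarray(x_profile, dtype=float))[0]
    else:
        s = np.zeros(model.n_components)
    lp = float(s @ model.component_coefs)

    if model.family == "cox":
        bh = model.baseline_hazard
        ch = np.array(
            [bh.loc[bh["time"] <= t, "increment"].sum() for t in t_grid]
        ) * np.exp(lp)
        return pd.DataFrame({"t": t_grid, "family": "cox", "cumhaz": ch})

    p = dict(model.baseline_spec.params)
    if model.family == "exponential":
        p["lam"] *= np.exp(lp)
    elif model.family == "gompertz":
        p["b"] *= np.exp(lp)
        eta = p["eta"]
        if eta > 0:
            t_max = 700.0 / eta
            if np.any(t_grid > t_max):
                warnings.warn(
                    f"Gompertz cumulative hazard overflows beyond t={t_max:.3g}; "
                    "clipping grid",
                    UserWarning,
                    stacklevel=2,
                )
                t_grid = np.minimum(t_grid, t_max)
    else:
        p["mu"] += lp
    spec = DistributionSpec(model.family, p)
    ch = cumulative_hazard(spec, t_grid)
    return pd.DataFrame({"t": t_grid, "family": model.family, "cumhaz": ch})
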