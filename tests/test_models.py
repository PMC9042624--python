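"""Stage-2 fitting: closed-form MLEs, Cox oracles, comparison, curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from plsfpm import (
    DistributionSpec,
    SimulationConfig,
    censored_loglik,
    compare,
    cumhaz_curve,
    fit_cox,
    fit_fpm,
    fit_pls,
    sample,
    simulate_survival,
)
from plsfpm.models import _cox_neg_logpl, cox_partial_loglik, model_loglik


def no_scores(n):
    return np.empty((n, 0))


class TestFpmClosedForms:
    def test_exponential_mle_no_censoring(self, rng):
        t = rng.exponential(scale=2.0, size=200)
        m = fit_fpm(no_scores(200), t, np.ones(200, int), "exponential")
        assert m.converged
        assert m.baseline_spec["lam"] == pytest.approx(200 / t.sum(), abs=1e-8)
        # reported loglik equals the censored loglik at the fitted baseline
        assert m.loglik == pytest.approx(
            censored_loglik(m.baseline_spec, t, np.ones(200, int)), rel=1e-10
        )

    def test_exponential_mle_with_censoring(self, rng):
        t = rng.exponential(scale=2.0, size=200)
        e = (rng.uniform(size=200) < 0.7).astype(int)
        m = fit_fpm(no_scores(200), t, e, "exponential")
        assert m.baseline_spec["lam"] == pytest.approx(e.sum() / t.sum(), abs=1e-8)

    def test_gompertz_recovery_single_draw(self):
        spec = DistributionSpec("gompertz", {"eta": 0.1, "b": 0.1})
        t = sample(spec, 2000, rng_seed=5)
        m = fit_fpm(no_scores(2000), t, np.ones(2000, int), "gompertz")
        assert m.converged
        assert m.baseline_spec["b"] == pytest.approx(0.1, rel=0.25)
        assert m.baseline_spec["eta"] == pytest.approx(0.1, rel=0.25)

    @pytest.mark.parametrize("family", ["exponential", "gompertz", "gengamma", "genf"])
    def test_scaled_gradient_small_at_optimum(self, family, default_dataset):
        ds = default_dataset
        d = fit_pls(ds.X, ds.time, 2)
        m = fit_fpm(d.scores, ds.time, ds.event, family)
        assert m.converged
        assert m.grad_norm < 1e-5

    def test_aic_bic_identities(self, default_dataset):
        ds = default_dataset
        d = fit_pls(ds.X, ds.time, 2)
        m = fit_fpm(d.scores, ds.time, ds.event, "gompertz")
        assert m.aic == pytest.approx(-2 * m.loglik + 2 * m.n_params)
        assert m.bic == pytest.approx(-2 * m.loglik + np.log(m.n_obs) * m.n_params)
        assert m.n_params == 2 + 2  # A components + (eta, b)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError, match="family"):
            fit_fpm(no_scores(5), np.ones(5), np.ones(5, int), "weibull")
        with pytest.raises(ValueError, match="0/1"):
            fit_fpm(no_scores(3), [1.0, 2.0, 3.0], [1, 2, 0], "exponential")


class TestCox:
    def test_two_group_matches_bisection_oracle(self, rng):
        group = np.repeat([0.0, 1.0], 25)
        t = np.concatenate(
            [rng.exponential(1.0, 25), rng.exponential(0.5, 25)]
        )
        t += rng.uniform(0, 1e-9, 50)  # guarantee no ties
        e = np.ones(50, int)
        s = group[:, None]

        def score(beta):  # derivative of the Breslow partial loglik
            h = 1e-6
            return (
                _cox_neg_logpl(np.array([beta - h]), s, t, e)
                - _cox_neg_logpl(np.array([beta + h]), s, t, e)
            ) / (2 * h)

        root = optimize.bisect(score, -5.0, 5.0, xtol=1e-10)
        m = fit_cox(s, t, e)
        assert m.converged
        assert m.component_coefs[0] == pytest.approx(root, abs=1e-5)

    def test_matches_lifelines_without_ties(self, default_dataset):
        lifelines = pytest.importorskip("lifelines")
        ds = default_dataset
        d = fit_pls(ds.X, ds.time, 2)
        m = fit_cox(d.scores, ds.time, ds.event)
        df = pd.DataFrame(
            {"t": ds.time, "e": ds.event, "s1": d.scores[:, 0], "s2": d.scores[:, 1]}
        )
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(m.component_coefs, cph.params_.values, atol=1e-5)
        assert m.loglik == pytest.approx(cph.log_likelihood_, rel=1e-8)

    def test_breslow_ties_hand_computed_toy(self):
        # 5 subjects, times (1,1,2,3,3), events (1,1,1,1,0), covariate x
        t = np.array([1.0, 1.0, 2.0, 3.0, 3.0])
        e = np.array([1, 1, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0])[:, None]
        beta = 0.3
        r = np.exp(beta * x.ravel())
        # Breslow: both events at t=1 use the full risk set {1..5}
        expected = (
            beta * (1 + 0 + 1 + 0)
            - 2 * np.log(r.sum())
            - np.log(r[2:].sum())
            - np.log(r[3:].sum())
        )
        assert cox_partial_loglik(np.array([beta]), x, t, e) == pytest.approx(expected)

    def test_zero_variance_component_flagged(self):
        s = np.ones((20, 1))
        t = np.linspace(1, 20, 20)
        m = fit_cox(s, t, np.ones(20, int))
        assert not m.converged
        assert "flat" in m.diagnostics["reason"]

    def test_pls_cox_on_orthonormal_scores_equals_plain_cox(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n, p = 80, 3
        M = rng.normal(size=(n, p))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        X = Q[:, :p]  # orthonormal columns, mean zero
        t = rng.exponential(np.exp(-X @ np.array([1.0, -0.5, 0.2])))
        e = np.ones(n, int)
        d = fit_pls(X, t, p, standardize=False)
        m = fit_cox(d.scores, t, e, decomp=d)
        # back-projected (sign-flipped) coefficients equal plain Cox on X
        m_plain = fit_cox(X, t, e)
        np.testing.assert_allclose(
            -m.covariate_coefs, m_plain.component_coefs, atol=1e-6
        )
        # independent cross-check at the two optimizers' joint tolerance
        df = pd.DataFrame(X, columns=["a", "b", "c"]).assign(t=t, e=e)
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(-m.covariate_coefs, cph.params_.values, atol=1e-4)


class TestCompare:
    def test_identical_models_tie_stably(self, default_dataset):
        ds = default_dataset
        d = fit_pls(ds.X, ds.time, 2)
        m = fit_fpm(d.scores, ds.time, ds.event, "exponential")
        table = compare([m, m])
        assert len(table) == 2
        assert table["aic"].nunique() == 1

    def test_mixed_datasets_rejected(self, default_dataset):
        ds = default_dataset
        d = fit_pls(ds.X, ds.time, 2)
        m1 = fit_fpm(d.scores, ds.time, ds.event, "exponential")
        m2 = fit_fpm(d.scores[:50], ds.time[:50], ds.event[:50], "exponential")
        with pytest.raises(ValueError, match="different datasets"):
            compare([m1, m2])

    def test_gompertz_never_beats_exponential_by_more_than_its_extra_param(self, rng):
        # on exponential data the nested Gompertz can gain at most its penalty
        t = rng.exponential(1.0, size=300)
        e = np.ones(300, int)
        m_exp = fit_fpm(no_scores(300), t, e, "exponential")
        m_gom = fit_fpm(no_scores(300), t, e, "gompertz")
        assert m_gom.loglik >= m_exp.loglik - 1e-6  # nesting
        assert m_exp.aic <= m_gom.aic + 2.0 + 1e-6


class TestCurves:
    def test_exponential_curve_is_line(self, default_dataset):
        ds = default_dataset
        d = fit_pls(ds.X, ds.time, 2)
        m = fit_fpm(d.scores, ds.time, ds.event, "exponential", decomp=d)
        grid = np.linspace(0, 12, 121)
        curve = cumhaz_curve(m, d, d.centers, grid)
        lam = m.baseline_spec["lam"]  # mean profile -> zero scores
        np.testing.assert_allclose(curve["cumhaz"], lam * grid, rtol=1e-8, atol=1e-12)

    @pytest.mark.parametrize("family", ["exponential", "gompertz", "gengamma", "genf"])
    def test_fpm_curves_monotone(self, family, default_dataset):
        ds = default_dataset
        d = fit_pls(ds.X, ds.time, 2)
        m = fit_fpm(d.scores, ds.time, ds.event, family, decomp=d)
        curve = cumhaz_curve(m, d, ds.X[3], np.arange(0, 12.1, 0.1))
        assert np.all(np.diff(curve["cumhaz"]) >= -1e-12)

    def test_cox_step_count_equals_distinct_event_times(self):
        ds = simulate_survival(SimulationConfig(seed=3, censoring=("admin", 8.0)))
        d = fit_pls(ds.X, ds.time, 2)
        m = fit_cox(d.scores, ds.time, ds.event)
        # grid with one point between every pair of adjacent distinct event
        # times, so each Breslow increment lands in its own cell
        uniq = np.unique(ds.time[ds.event == 1])
        grid = np.concatenate([[0.0], (uniq[1:] + uniq[:-1]) / 2, [uniq[-1] + 1]])
        curve = cumhaz_curve(m, d, ds.X.mean(axis=0), grid)
        n_steps = np.sum(np.diff(curve["cumhaz"]) > 0)
        n_distinct = len(np.unique(ds.time[ds.event == 1]))
        assert n_steps == n_distinct


class TestRecoveryAcrossFamilies:
    @pytest.mark.parametrize(
        "family,params",
        [
            ("exponential", {"lam": 0.8}),
            ("gengamma", {"mu": 1.0, "sigma": 0.7, "kappa": 0.6}),
        ],
    )
    def test_intercept_only_mle_bias_small(self, family, params):
        spec = DistributionSpec(family, params)
        rel_errs = []
        for seed in range(5):
            t = sample(spec, 2000, rng_seed=100 + seed)
            m = fit_fpm(no_scores(2000), t, np.ones(2000, int), family)
            assert m.converged
            for k, v in params.items():
                rel_errs.append(abs(m.baseline_spec[k] - v) / max(abs(v), 0.1))
        assert np.median(rel_errs) < 0.10

    def test_loglik_consistent_with_model_loglik(self, default_dataset):
        ds = default_dataset
        d = fit_pls(ds.X, ds.time, 2)
        m = fit_fpm(d.scores, ds.time, ds.event, "gengamma")
        theta = np.asarray(m.diagnostics["theta"])
        assert m.loglik == pytest.approx(
            model_loglik("gengamma", theta, d.scores, ds.time, ds.event)
        )
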