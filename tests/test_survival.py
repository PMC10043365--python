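"""Parametric survival curves, MLE fitting, model selection, KM utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nsclc_cea import (FAMILIES, KMCurve, ParametricSurvival, SimSpec,
                       fit_all_families, fit_mle, ipd_frame, km_estimate,
                       reconstruct_ipd, select_best, simulate_ipd,
                       survival_at)
from nsclc_cea.survival import FitResult

LOGNORMAL_OS_ATEZO = ParametricSurvival("lognormal",
                                        {"mu": 3.075809, "sigma": 1.794862})
LOGLOGISTIC_PFS_CHEMO = ParametricSurvival("loglogistic",
                                           {"lambda": 0.06143, "gamma": 1.70390})


class TestClosedForms:
    def test_survival_starts_at_one(self):
        assert survival_at(LOGNORMAL_OS_ATEZO, 0.0) == pytest.approx(1.0)

    def test_lognormal_median_is_exp_mu(self):
        t_med = np.exp(3.075809)
        assert survival_at(LOGNORMAL_OS_ATEZO, t_med) == pytest.approx(0.5)
        assert LOGNORMAL_OS_ATEZO.median == pytest.approx(t_med)

    def test_loglogistic_median_closed_form(self):
        # S(t) = 1/(1 + lambda t^gamma) = 1/2 at t = (1/lambda)^(1/gamma)
        t_med = (1.0 / 0.06143) ** (1.0 / 1.70390)
        assert survival_at(LOGLOGISTIC_PFS_CHEMO, t_med) == pytest.approx(0.5)

    def test_weibull_and_exponential_forms(self):
        w = ParametricSurvival("weibull", {"shape": 1.4, "scale": 10.0})
        assert survival_at(w, 10.0) == pytest.approx(np.exp(-1.0))
        e = ParametricSurvival("exponential", {"rate": 0.2})
        assert survival_at(e, 5.0) == pytest.approx(np.exp(-1.0))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            LOGNORMAL_OS_ATEZO.sf(-1.0)

    @pytest.mark.parametrize("family,params", [
        ("lognormal", {"mu": 1.0, "sigma": -0.5}),
        ("loglogistic", {"lambda": 0.0, "gamma": 1.0}),
        ("weibull", {"shape": 1.0}),
        ("nonsense", {"rate": 1.0}),
    ])
    def test_invalid_params_rejected(self, family, params):
        with pytest.raises(ValueError):
            ParametricSurvival(family, params)


@settings(max_examples=60, derandomize=True)
@given(
    family=st.sampled_from(FAMILIES),
    p1=st.floats(0.2, 3.0),
    p2=st.floats(0.2, 3.0),
    t1=st.floats(0.0, 80.0),
    dt=st.floats(0.0, 40.0),
)
def test_survival_monotone_and_bounded(family, p1, p2, t1, dt):
    """For every family S(0)=1, S is non-increasing and within [0, 1]."""
    params = {
        "exponential": {"rate": p1},
        "weibull": {"shape": p1, "scale": 5 * p2},
        "loglogistic": {"lambda": 0.1 * p1, "gamma": p2},
        "lognormal": {"mu": p1, "sigma": p2},
    }[family]
    m = ParametricSurvival(family, params)
    s1, s2 = m.sf(t1), m.sf(t1 + dt)
    assert m.sf(0.0) == pytest.approx(1.0)
    assert 0.0 <= s2 <= s1 <= 1.0


class TestFitMLE:
    def test_exponential_closed_form_mle(self):
        # uncensored: rate_hat = n_events / total observed time
        rng = np.random.default_rng(5)
        t = rng.exponential(scale=8.0, size=400)
        ipd = ipd_frame(t, np.ones_like(t, dtype=int))
        fit = fit_mle(ipd, "exponential")
        assert fit.model.params["rate"] == pytest.approx(len(t) / t.sum(), rel=1e-4)
        # analytic log-likelihood at the MLE: n log(rate) - rate * total
        rate = len(t) / t.sum()
        ll = len(t) * np.log(rate) - rate * t.sum()
        assert fit.loglik == pytest.approx(ll, rel=1e-6)
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)
        assert fit.bic == pytest.approx(np.log(len(t)) - 2 * fit.loglik)

    def test_censored_lognormal_parameter_recovery(self):
        ipd = simulate_ipd(SimSpec(model=LOGNORMAL_OS_ATEZO, n=20_000,
                                   censor_time=33.0, seed=42))
        fit = fit_mle(ipd, "lognormal")
        assert fit.model.params["mu"] == pytest.approx(3.075809, abs=0.05)

    def test_fitted_loglik_dominates_truth(self):
        """MLE dominance: fitted params cannot have lower likelihood than the
        generating params on the same data."""
        model = ParametricSurvival("weibull", {"shape": 1.4, "scale": 10.0})
        ipd = simulate_ipd(SimSpec(model=model, n=2_000, censor_time=25.0, seed=3))
        fit = fit_mle(ipd, "weibull")
        t = ipd["time_months"].to_numpy()
        ev = ipd["event"].to_numpy().astype(bool)

        def loglik(m):
            d = m._dist()
            return d.logpdf(t[ev]).sum() + d.logsf(t[~ev]).sum()

        assert loglik(fit.model) >= loglik(model) - 1e-6

    def test_true_family_wins_model_selection(self):
        model = ParametricSurvival("weibull", {"shape": 1.4, "scale": 10.0})
        wins = 0
        seeds = range(5)
        for seed in seeds:
            ipd = simulate_ipd(SimSpec(model=model, n=5_000,
                                       censor_time=40.0, seed=seed))
            best = select_best(fit_all_families(ipd))
            wins += best.model.family == "weibull"
        assert wins >= len(seeds) - 1

    def test_no_events_rejected(self):
        ipd = ipd_frame([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(ValueError):
            fit_mle(ipd, "lognormal")

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            fit_mle(ipd_frame([1.0], [1]), "exponential")


class TestSelectBest:
    def _fit(self, family, aic, bic):
        m = ParametricSurvival(family, {"rate": 1.0} if family == "exponential"
                               else {"mu": 0.0, "sigma": 1.0})
        ll = -(aic - 2 * len(m.params)) / 2
        return FitResult(model=m, loglik=ll, aic=aic, bic=bic, n=10)

    def test_minimal_aic_wins(self):
        fits = [self._fit("exponential", 100, 90),
                self._fit("lognormal", 90, 95),
                self._fit("exponential", 95, 80)]
        assert select_best(fits).aic == 90

    def test_aic_tie_broken_by_bic(self):
        fits = [self._fit("exponential", 80, 50), self._fit("lognormal", 80, 40)]
        assert select_best(fits).bic == 40

    def test_full_tie_broken_by_family_order(self):
        fits = [self._fit("lognormal", 80, 50), self._fit("exponential", 80, 50)]
        assert select_best(fits).model.family == "exponential"

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestKaplanMeier:
    def test_distinct_event_times_step_sizes(self):
        ipd = ipd_frame(np.arange(1.0, 11.0), np.ones(10, dtype=int))
        km = km_estimate(ipd)
        # drops by 1/remaining at each time; last value 0
        assert km.surv[-1] == pytest.approx(0.0)
        assert km.step_interp(1.5) == pytest.approx(0.9)
        assert km.step_interp(5.5) == pytest.approx(0.5)

    def test_all_censored_stays_at_one(self):
        km = km_estimate(ipd_frame([2.0, 4.0, 9.0], [0, 0, 0]))
        assert np.allclose(km.surv, 1.0)

    def test_large_sample_matches_closed_form_median(self):
        ipd = simulate_ipd(SimSpec(model=LOGLOGISTIC_PFS_CHEMO, n=50_000,
                                   censor_time=200.0, seed=11))
        km = km_estimate(ipd)
        t_med = (1.0 / 0.06143) ** (1.0 / 1.70390)
        assert km.step_interp(t_med) == pytest.approx(0.5, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(pd.DataFrame({"time_months": [], "event": []}))


class TestReconstructIPD:
    def test_single_interval_proportions_forced(self):
        curve = KMCurve(times=np.array([0.0, 6.0]), surv=np.array([1.0, 0.6]))
        ipd = reconstruct_ipd(curve, total_n=100, censor_time=33.0)
        events = ipd[ipd["event"] == 1]
        censored = ipd[ipd["event"] == 0]
        assert len(events) == 40 and (events["time_months"] <= 6.0).all()
        assert len(censored) == 60 and (censored["time_months"] == 33.0).all()

    def test_flat_curve_all_censored(self):
        curve = KMCurve(times=np.array([0.0, 5.0, 10.0]), surv=np.ones(3))
        ipd = reconstruct_ipd(curve, total_n=25, censor_time=12.0)
        assert (ipd["event"] == 0).all() and len(ipd) == 25

    def test_increasing_survival_rejected(self):
        with pytest.raises(ValueError):
            KMCurve(times=np.array([0.0, 1.0]), surv=np.array([0.5, 0.9]))

    def test_round_trip_sup_norm(self):
        """reconstruct o km_estimate approximately the identity (no interval
        censoring)."""
        model = ParametricSurvival("lognormal", {"mu": 2.2, "sigma": 1.5})
        src = simulate_ipd(SimSpec(model=model, n=200, censor_time=36.0, seed=9))
        km_src = km_estimate(src)
        rec = reconstruct_ipd(km_src, total_n=200, censor_time=36.0)
        km_rec = km_estimate(rec)
        grid = np.linspace(0.0, 36.0, 400)
        gap = np.abs(km_src.step_interp(grid) - km_rec.step_interp(grid))
        assert gap.max() < 0.02
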