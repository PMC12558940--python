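import numpy as np
import pytest
from scipy import integrate, stats

from sclc_cea.survival import (
    FAMILIES,
    SurvivalDistribution,
    fit_mle,
    loglikelihood,
    quantile,
    rank_models,
    survival_at,
)

# one representative parameter set per family (time unit: months)
EXAMPLES = {
    "exponential": {"rate": 0.08},
    "weibull": {"shape": 1.4, "scale": 12.0},
    "gompertz": {"shape": 0.05, "rate": 0.04},
    "gamma": {"shape": 2.0, "rate": 0.15},
    "generalized_gamma": {"a": 1.5, "c": 0.9, "scale": 10.0},
    "loglogistic": {"scale": 16.50756, "shape": 1.70402},
    "lognormal": {"mu": 2.4, "sigma": 0.8},
}


def dist(family):
    return SurvivalDistribution(family, EXAMPLES[family])


class TestClosedForms:
    def test_loglogistic_median_equals_scale(self):
        d = SurvivalDistribution("loglogistic", {"scale": 2.0, "shape": 1.0})
        assert survival_at(d, 2.0) == pytest.approx(0.5)
        assert quantile(d, 0.5) == pytest.approx(2.0)

    def test_loglogistic_closed_form_arithmetic(self):
        d = SurvivalDistribution("loglogistic", {"scale": 2.0, "shape": 1.0})
        assert survival_at(d, 6.0) == pytest.approx(0.25)  # 1 / (1 + 3)

    def test_exponential_quantile_closed_form(self):
        d = SurvivalDistribution("exponential", {"rate": 0.3})
        for p in (0.1, 0.5, 0.9):
            assert quantile(d, p) == pytest.approx(-np.log1p(-p) / 0.3)

    def test_survival_at_zero_is_one(self):
        for family in FAMILIES:
            assert survival_at(dist(family), 0.0) == 1.0

    def test_negative_time_rejected(self, loglogistic_os):
        with pytest.raises(ValueError):
            survival_at(loglogistic_os, -1.0)

    def test_quantile_domain(self, loglogistic_os):
        for bad in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(ValueError):
                quantile(loglogistic_os, bad)


def test_loglogistic_against_hazard_integration_oracle(loglogistic_os):
    """S(t) must equal exp(-integral of the hazard), the hazard evaluated
    through an independent implementation (scipy.stats.fisk)."""
    frozen = stats.fisk(c=1.70402, scale=16.50756)

    def hazard(u):
        return frozen.pdf(u) / frozen.sf(u)

    for t in (3.0, 12.0, 30.0):
        cum_haz, err = integrate.quad(hazard, 0.0, t, limit=200)
        assert survival_at(loglogistic_os, t) == pytest.approx(
            np.exp(-cum_haz), abs=max(1e-9, 10 * err)
        )


@pytest.mark.parametrize("family", sorted(FAMILIES))
def test_survival_monotone_and_bounded(family):
    grid = np.linspace(0, 200, 2001)
    s = survival_at(dist(family), grid)
    assert np.all((s >= 0) & (s <= 1))
    assert np.all(np.diff(s) <= 1e-12)


@pytest.mark.parametrize("family", sorted(FAMILIES))
def test_quantile_survival_round_trip(family):
    d = dist(family)
    for p in (0.05, 0.3, 0.5, 0.7, 0.95):
        t = quantile(d, p)
        assert survival_at(d, t) == pytest.approx(1.0 - p, abs=1e-8)


def test_generalized_gamma_quantile_matches_bisection():
    d = dist("generalized_gamma")
    lo, hi = 1e-9, 1e4
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if survival_at(d, mid) > 0.7:  # S(t) = 1 - p with p = 0.3
            lo = mid
        else:
            hi = mid
    assert quantile(d, 0.3) == pytest.approx(0.5 * (lo + hi), rel=1e-6)


def test_gompertz_negative_shape_warns_and_plateaus():
    with pytest.warns(UserWarning, match="plateau"):
        d = SurvivalDistribution("gompertz", {"shape": -0.1, "rate": 0.02})
    assert survival_at(d, 1e6) > 0.0


class TestFitting:
    def test_exponential_mle_closed_form(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10.0, size=400)
        e = (t < 15.0).astype(int)
        t = np.minimum(t, 15.0)
        fit = fit_mle(t, e, "exponential")
        assert fit.dist.params["rate"] == pytest.approx(e.sum() / t.sum(), abs=1e-8)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.bic == pytest.approx(fit.k * np.log(fit.n) - 2 * fit.loglik)

    def test_loglogistic_parameter_recovery(self):
        true = SurvivalDistribution(
            "loglogistic", {"scale": 16.50756, "shape": 1.70402}
        )
        rng = np.random.default_rng(2024)
        u = rng.uniform(size=10_000)
        t = np.asarray(quantile(true, u))
        fit = fit_mle(t, np.ones_like(t), "loglogistic")
        assert fit.dist.params["scale"] == pytest.approx(16.50756, rel=0.02)
        assert fit.dist.params["shape"] == pytest.approx(1.70402, rel=0.02)

    def test_fitted_loglik_beats_truth(self):
        true = dist("weibull")
        rng = np.random.default_rng(5)
        t = np.asarray(quantile(true, rng.uniform(size=500)))
        e = np.ones_like(t)
        fit = fit_mle(t, e, "weibull")
        ll_true = loglikelihood("weibull", true.values(), t, e)
        assert fit.loglik >= ll_true - 1e-6

    def test_censored_fit_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        true = SurvivalDistribution("loglogistic", {"scale": 8.0, "shape": 2.0})
        rng = np.random.default_rng(11)
        t = np.asarray(quantile(true, rng.uniform(size=800)))
        cens = rng.exponential(20.0, size=800)
        obs, ev = np.minimum(t, cens), (t <= cens).astype(int)
        ours = fit_mle(obs, ev, "loglogistic")
        llf = lifelines.LogLogisticFitter().fit(obs, ev)
        assert ours.dist.params["scale"] == pytest.approx(llf.alpha_, rel=1e-4)
        assert ours.dist.params["shape"] == pytest.approx(llf.beta_, rel=1e-4)
        assert ours.loglik == pytest.approx(llf.log_likelihood_, rel=1e-6)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="2 observed events"):
            fit_mle([1.0, 2.0, 3.0], [0, 0, 0], "exponential")

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            fit_mle([1.0, 0.0], [1, 1], "weibull")


class TestRanking:
    def _fake_fit(self, family, loglik, k, n=100):
        params = dict(EXAMPLES[family])
        d = SurvivalDistribution(family, params)
        from sclc_cea.survival import FitResult

        return FitResult(
            dist=d,
            loglik=loglik,
            aic=2 * k - 2 * loglik,
            bic=k * np.log(n) - 2 * loglik,
            n=n,
            k=k,
        )

    def test_single_fit_zero_delta(self):
        table = rank_models([self._fake_fit("exponential", -100.0, 1)])
        assert table.delta_aic.tolist() == [0.0]

    def test_parsimony_breaks_equal_loglik(self):
        fits = [
            self._fake_fit("weibull", -100.0, 2),
            self._fake_fit("exponential", -100.0, 1),
        ]
        table = rank_models(fits)
        assert table.family.tolist() == ["exponential", "weibull"]

    def test_differing_n_rejected(self):
        fits = [
            self._fake_fit("exponential", -100.0, 1, n=100),
            self._fake_fit("weibull", -90.0, 2, n=200),
        ]
        with pytest.raises(ValueError, match="differing"):
            rank_models(fits)

    def test_ranking_reproducible_from_logliks(self):
        """AIC order recomputed independently from the stored logliks/k."""
        true = SurvivalDistribution("loglogistic", {"scale": 10.0, "shape": 1.9})
        rng = np.random.default_rng(3)
        t = np.asarray(quantile(true, rng.uniform(size=1500)))
        e = np.ones_like(t)
        fits = [fit_mle(t, e, fam) for fam in sorted(FAMILIES)]
        table = rank_models(fits)
        recomputed = sorted(fits, key=lambda f: 2 * f.k - 2 * f.loglik)
        assert table.family.tolist() == [f.dist.family for f in recomputed]

    def test_model_selection_recovers_generating_family(self):
        true = SurvivalDistribution("loglogistic", {"scale": 16.5, "shape": 1.7})
        rng = np.random.default_rng(17)
        t = np.asarray(quantile(true, rng.uniform(size=2500)))
        e = np.ones_like(t)
        fits = [fit_mle(t, e, fam) for fam in sorted(FAMILIES)]
        table = rank_models(fits)
        # generalized gamma nests several families; the generating family
        # must at worst sit within 2 AIC of the top
        assert table.family.iloc[0] == "loglogistic" or (
            table[table.family == "loglogistic"].delta_aic.iloc[0] < 2.0
        )
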