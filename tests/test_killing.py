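"""Tests for Poisson apoptosis-count models and their comparison."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import poisson

from ctldyn.killing import (
    PoissonKillFit, compare_models, fit_poisson_linear, fit_poisson_massaction,
    poisson_band,
)
from ctldyn.observation import IntravitalPosition


def pos(n_ctl, n_tc, tau_h, kills, group=None, day=6.0):
    return IntravitalPosition("m", day, float(tau_h), float(n_ctl), float(n_tc),
                              tc_apoptosis=float(kills), group=group)


def numerical_mle(positions, model):
    """Grid-free 1-D likelihood maximisation, independent of the closed form."""
    tau = np.array([p.duration for p in positions]) / 24.0
    expo = np.array([p.n_ctl for p in positions]) * tau
    if model == "mass-action":
        expo = expo * np.array([p.n_tc for p in positions])
    kills = np.array([p.tc_apoptosis for p in positions])

    def nll(lam):
        mu = lam * expo
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(kills > 0, kills * np.log(mu), 0.0)
        return -np.sum(term - mu)

    hi = max(10.0 * kills.sum() / expo.sum(), 1e-6)
    res = minimize_scalar(nll, bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-14})
    return res.x


class TestClosedFormMLE:
    def test_linear_rate_pools_counts_over_exposures(self):
        # kills 1+1 over exposures 5*2h + 10*1h = 20 CTL*h -> 0.1/h = 2.4/day
        fit = fit_poisson_linear([pos(5, 100, 2.0, 1), pos(10, 100, 1.0, 1)])
        assert fit.rate == pytest.approx(2.4)

    def test_massaction_rate(self):
        # 4 kills / (2 CTL * 100 TC * 1 h) = 0.02 /CTL/TC/h = 0.48 /CTL/TC/day
        fit = fit_poisson_massaction([pos(2, 100, 1.0, 4)])
        assert fit.rate == pytest.approx(0.48)

    def test_zero_kills_give_zero_rate(self):
        fit = fit_poisson_linear([pos(5, 100, 2.0, 0), pos(3, 50, 1.0, 0)])
        assert fit.rate == 0.0

    def test_constant_tumour_count_links_the_two_models(self):
        positions = [pos(5, 80, 2.0, 1), pos(10, 80, 1.0, 2), pos(3, 80, 3.0, 0)]
        lin = fit_poisson_linear(positions)
        ma = fit_poisson_massaction(positions)
        assert ma.rate == pytest.approx(lin.rate / 80.0)

    def test_all_exposures_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_poisson_linear([pos(0, 100, 2.0, 0)])

    @pytest.mark.parametrize("model,fitter", [
        ("linear", fit_poisson_linear), ("mass-action", fit_poisson_massaction),
    ])
    def test_closed_form_agrees_with_numerical_maximisation(self, model, fitter, rng):
        for _ in range(25):
            n = rng.integers(3, 12)
            positions = [
                pos(rng.integers(1, 30), rng.integers(20, 300),
                    rng.uniform(1.0, 3.0), rng.poisson(1.2))
                for _ in range(n)
            ]
            if sum(p.tc_apoptosis for p in positions) == 0:
                continue
            fit = fitter(positions)
            lam = numerical_mle(positions, model)
            assert fit.rate == pytest.approx(lam, rel=1e-6, abs=1e-10)

    def test_information_criteria_identities(self):
        fit = fit_poisson_linear([pos(5, 100, 2.0, 1), pos(10, 100, 1.0, 2)])
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.log_likelihood)
        assert fit.bic == pytest.approx(
            fit.n_params * np.log(fit.n_obs) - 2 * fit.log_likelihood)

    def test_per_treatment_grouping_fits_one_rate_per_group(self):
        positions = [pos(5, 100, 2.0, 1, group="ACT-only"),
                     pos(10, 100, 1.0, 3, group="ACT+mAb"),
                     pos(8, 100, 2.0, 2, group="ACT+mAb")]
        fit = fit_poisson_linear(positions, grouping="per-treatment")
        assert fit.n_params == 2
        assert set(fit.rates) == {"ACT-only", "ACT+mAb"}
        assert fit.rates["ACT-only"] == pytest.approx(1.0 / 10.0 * 24.0)


class TestModelComparison:
    def test_fewer_parameters_win_at_equal_likelihood(self):
        base = fit_poisson_linear([pos(5, 100, 2.0, 1), pos(10, 100, 1.0, 2)])
        bloated = dataclasses.replace(
            base, model="mass-action", n_params=2,
            aic=2 * 2 - 2 * base.log_likelihood,
            bic=2 * np.log(base.n_obs) - 2 * base.log_likelihood,
        )
        table = compare_models([bloated, base])
        assert table.iloc[0]["model"] == "linear"
        assert table.iloc[0]["delta_aic"] == 0.0

    def test_mismatched_observation_sets_rejected(self):
        a = fit_poisson_linear([pos(5, 100, 2.0, 1)])
        b = fit_poisson_linear([pos(5, 100, 2.0, 2)])
        with pytest.raises(ValueError):
            compare_models([a, b])

    def test_linear_data_select_linear_model_by_aic(self, rng):
        wins = 0
        for _ in range(40):
            positions = []
            for _ in range(200):
                n_tc = rng.uniform(60.0, 300.0)        # 5-fold variation
                n_ctl = int(rng.integers(1, 30))
                tau = rng.uniform(1.0, 3.0)
                kills = rng.poisson(0.44 * n_ctl * tau / 24.0)
                positions.append(pos(n_ctl, n_tc, tau, kills))
            lin = fit_poisson_linear(positions)
            ma = fit_poisson_massaction(positions)
            wins += lin.aic < ma.aic
        assert wins >= 0.9 * 40

    def test_common_rate_data_prefer_pooled_by_bic(self, rng):
        pooled_wins = 0
        for _ in range(20):
            positions = []
            for g in ("ACT-only", "ACT+mAb"):
                for _ in range(60):
                    n_ctl = int(rng.integers(2, 25))
                    tau = rng.uniform(1.0, 3.0)
                    kills = rng.poisson(0.6 * n_ctl * tau / 24.0)
                    positions.append(pos(n_ctl, 100, tau, kills, group=g))
            pooled = fit_poisson_linear(positions, "pooled")
            split = fit_poisson_linear(positions, "per-treatment")
            pooled_wins += pooled.bic < split.bic
        assert pooled_wins > 10


class TestPoissonBand:
    def test_zero_rate_band_collapses_to_zero(self):
        band = poisson_band([0.0, 5.0, 20.0], rate=0.0, duration=2.0)
        assert (band[["expected", "lower", "upper"]] == 0.0).all().all()

    def test_band_quantiles_are_exact_poisson_inverse_cdf(self):
        # expected count 3: the 5-95% interval of Poisson(3) is [1, 6]
        band = poisson_band([3.0], rate=1.0, duration=24.0)
        assert band["expected"].iloc[0] == pytest.approx(3.0)
        assert band["lower"].iloc[0] == 1.0
        assert band["upper"].iloc[0] == 6.0
        # cross-check by direct pmf summation
        assert poisson.cdf(0, 3.0) < 0.05 <= poisson.cdf(1, 3.0)
        assert poisson.cdf(5, 3.0) < 0.95 <= poisson.cdf(6, 3.0)

    def test_expectation_linear_in_ctl_count(self):
        band = poisson_band([5.0, 10.0], rate=0.44, duration=2.0)
        assert band["expected"].iloc[1] == pytest.approx(2 * band["expected"].iloc[0])
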