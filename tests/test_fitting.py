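"""Flux estimation: recovery, precision, goodness of fit, invariances."""

import numpy as np
import pytest

from dhaflux import (
    FitConfig,
    InputError,
    KineticParameters,
    MetaboliteParams,
    SeriesWeight,
    TimeCourse,
    estimate_precision,
    fit_timecourse,
    generate_culture,
    goodness_of_fit,
    predict,
)
from dhaflux.synthetic import GeneratorConfig, NoiseSpec, wildtype_params

NO_NOISE = dict(biomass_noise=NoiseSpec(), metabolite_noise=NoiseSpec())


def make_culture(params, seed=None, **kw):
    if seed is None:
        cfg = GeneratorConfig(params=params, **NO_NOISE, **kw)
    else:
        cfg = GeneratorConfig(params=params, seed=seed, **kw)
    return generate_culture(cfg)


class TestPointEstimates:
    def test_noiseless_recovery_to_machine_precision(self, noiseless_culture):
        tc, truth = noiseless_culture
        fit = fit_timecourse(tc, FitConfig(k_fixed={"DHA": 0.0086}))
        assert fit.converged
        assert fit.estimates.mu == pytest.approx(truth.mu, rel=1e-6)
        assert fit.estimates.x0 == pytest.approx(truth.x0, rel=1e-6)
        assert fit.estimates.metabolite("DHA").q == pytest.approx(-5.2, rel=1e-6)

    def test_noisy_recovery_within_three_bootstrap_sd(self, noisy_culture, wt_fit_config):
        tc, truth = noisy_culture
        fit = fit_timecourse(tc, wt_fit_config, with_precision=True)
        prec = fit.precision
        assert abs(fit.estimates.mu - truth.mu) < 3 * prec.sd["mu"]
        assert abs(fit.estimates.metabolite("DHA").q - (-5.2)) < 3 * prec.sd["q:DHA"]

    def test_null_flux_recovered_within_two_sd(self):
        params = KineticParameters(
            x0=0.0185, mu=0.15,
            metabolites=(MetaboliteParams(name="tracer", m0=10.0, q=0.0, k=0.0),),
        )
        tc, _ = make_culture(params, seed=5)
        cfg = FitConfig(seed=5)
        fit = fit_timecourse(tc, cfg, with_precision=True)
        q = fit.estimates.metabolite("tracer").q
        assert abs(q) < 2 * fit.precision.sd["q:tracer"] + 1e-9

    def test_lag_phase_recovered(self):
        params = KineticParameters(
            x0=0.0185, mu=0.15, t_lag=4.0,
            metabolites=(MetaboliteParams(name="DHA", m0=15.0, q=-5.2, k=0.0086),),
        )
        tc, _ = make_culture(params)
        fit = fit_timecourse(tc, FitConfig(estimate_lag=True, k_fixed={"DHA": 0.0086}))
        assert fit.estimates.t_lag == pytest.approx(4.0, abs=1e-3)
        assert fit.estimates.mu == pytest.approx(0.15, rel=1e-4)

    def test_ignoring_degradation_inflates_uptake(self, noiseless_culture):
        # data generated with k = 0.0086 but fitted with k = 0: the abiotic
        # loss is booked as biological uptake, so |q| is biased upward
        tc, _ = noiseless_culture
        fit = fit_timecourse(tc, FitConfig(k_fixed={"DHA": 0.0}))
        assert abs(fit.estimates.metabolite("DHA").q) > 5.2

    def test_co_estimating_k_on_rich_data(self):
        # identifiability of k needs a visible abiotic phase: long sampling
        params = wildtype_params().with_metabolite(
            MetaboliteParams(name="DHA", m0=15.0, q=-0.5, k=0.05)
        )
        tc, _ = make_culture(params, interval=1.0)
        fit = fit_timecourse(tc, FitConfig(co_estimate_k=True))
        assert fit.estimates.metabolite("DHA").k == pytest.approx(0.05, rel=1e-3)

    def test_insufficient_points_rejected(self):
        tc = TimeCourse(
            times=[0.0, 1.0, 2.0],
            biomass=[0.02, 0.03, 0.04],
            metabolites={"M": [1.0, 0.9, 0.8]},
        )
        with pytest.raises(InputError, match="biomass"):
            fit_timecourse(tc)

    def test_short_metabolite_series_rejected(self):
        tc = TimeCourse(
            times=[0.0, 1.0, 2.0, 3.0],
            biomass=[0.02, 0.03, 0.04, 0.05],
            metabolites={"M": [1.0, 0.9, np.nan, np.nan]},
        )
        with pytest.raises(InputError, match="'M'"):
            fit_timecourse(tc)


class TestInvariances:
    def test_metabolite_column_order(self):
        params = KineticParameters(
            x0=0.0185, mu=0.15,
            metabolites=(
                MetaboliteParams(name="A", m0=15.0, q=-5.2, k=0.0086),
                MetaboliteParams(name="B", m0=2.0, q=0.5, k=0.0),
            ),
        )
        tc, _ = make_culture(params, seed=3)
        swapped = TimeCourse(
            times=tc.times,
            biomass=tc.biomass,
            biomass_unit=tc.biomass_unit,
            metabolites={"B": tc.metabolites["B"], "A": tc.metabolites["A"]},
        )
        cfg = FitConfig(k_fixed={"A": 0.0086})
        f1 = fit_timecourse(tc, cfg)
        f2 = fit_timecourse(swapped, cfg)
        for name in ("x0", "mu", "q:A", "q:B"):
            assert f1.parameter_series()[name] == pytest.approx(
                f2.parameter_series()[name], rel=1e-8
            )

    def test_uniform_series_rescaling_with_sigma(self, noisy_culture):
        # rescaling a metabolite series together with its sigma (a unit
        # change) leaves mu and x0 untouched and scales q and M0 linearly
        tc, _ = noisy_culture
        scale = 1000.0
        scaled = TimeCourse(
            times=tc.times,
            biomass=tc.biomass,
            metabolites={"DHA": tc.metabolites["DHA"] * scale},
        )
        w = {"DHA": SeriesWeight(relative=0.02, floor=0.05)}
        w_scaled = {"DHA": SeriesWeight(relative=0.02, floor=0.05 * scale)}
        base_bounds = {"q": (-50.0, 50.0)}
        scaled_bounds = {"q": (-50.0 * scale, 50.0 * scale)}
        f1 = fit_timecourse(tc, FitConfig(k_fixed={"DHA": 0.0086}, weights=w, bounds=base_bounds))
        f2 = fit_timecourse(
            scaled, FitConfig(k_fixed={"DHA": 0.0086}, weights=w_scaled, bounds=scaled_bounds)
        )
        assert f2.estimates.mu == pytest.approx(f1.estimates.mu, rel=1e-6)
        assert f2.estimates.x0 == pytest.approx(f1.estimates.x0, rel=1e-6)
        assert f2.estimates.metabolite("DHA").q == pytest.approx(
            scale * f1.estimates.metabolite("DHA").q, rel=1e-6
        )

    def test_objective_not_worse_than_initialization(self, noisy_culture, wt_fit_config):
        tc, _ = noisy_culture
        fit = fit_timecourse(tc, wt_fit_config)
        assert fit.objective <= fit.initial_objective + 1e-12

    def test_fit_window_excludes_points(self, noisy_culture, wt_fit_config):
        tc, _ = noisy_culture
        cfg = FitConfig(k_fixed={"DHA": 0.0086}, window=(0.0, 12.0), seed=42)
        fit = fit_timecourse(tc, cfg)
        assert fit.n_obs == 2 * np.sum(tc.times <= 12.0)


class TestPrecision:
    def test_noiseless_data_negligible_spread(self, noiseless_culture):
        tc, _ = noiseless_culture
        w = {
            "biomass": SeriesWeight(absolute=1e-8),
            "DHA": SeriesWeight(absolute=1e-8),
        }
        cfg = FitConfig(k_fixed={"DHA": 0.0086}, weights=w, seed=0, mc_iterations=20)
        fit = fit_timecourse(tc, cfg)
        prec = estimate_precision(tc, fit, cfg)
        assert all(sd < 1e-6 for sd in prec.sd.values())

    def test_halving_noise_halves_parameter_sd(self, wt_params):
        tc, _ = make_culture(
            wt_params, seed=11,
            biomass_noise=NoiseSpec(0.05, 0.0), metabolite_noise=NoiseSpec(0.02, 0.0),
        )

        def config(brel, mrel):
            return FitConfig(
                k_fixed={"DHA": 0.0086}, seed=3, mc_iterations=200,
                weights={
                    "biomass": SeriesWeight(relative=brel, floor=1e-9),
                    "DHA": SeriesWeight(relative=mrel, floor=1e-9),
                },
            )

        fit = fit_timecourse(tc, config(0.05, 0.02))
        full = estimate_precision(tc, fit, config(0.05, 0.02))
        half = estimate_precision(tc, fit, config(0.025, 0.01))
        for name in ("mu", "q:DHA"):
            assert 1.6 < full.sd[name] / half.sd[name] < 2.4

    def test_bootstrap_deterministic_given_seed(self, noisy_culture, wt_fit_config):
        tc, _ = noisy_culture
        fit = fit_timecourse(tc, wt_fit_config)
        p1 = estimate_precision(tc, fit, wt_fit_config)
        p2 = estimate_precision(tc, fit, wt_fit_config)
        assert p1.sd == p2.sd

    def test_seed_required(self, noisy_culture):
        tc, _ = noisy_culture
        cfg = FitConfig(k_fixed={"DHA": 0.0086})
        fit = fit_timecourse(tc, cfg)
        with pytest.raises(InputError, match="seed"):
            estimate_precision(tc, fit, cfg)

    def test_recovery_and_interval_coverage_over_replicates(self):
        # 50 synthetic wild-type cultures at default noise: median relative
        # error of mu and q below 5%, and the 95% bootstrap intervals cover
        # the generating values at a frequency consistent with their label
        errors_mu, errors_q, cover_mu, cover_q = [], [], 0, 0
        n_rep = 50
        for s in range(n_rep):
            tc, _ = generate_culture(GeneratorConfig(seed=1000 + s))
            cfg = FitConfig(k_fixed={"DHA": 0.0086}, seed=s, mc_iterations=100)
            fit = fit_timecourse(tc, cfg, with_precision=True)
            errors_mu.append(abs(fit.estimates.mu - 0.15) / 0.15)
            q = fit.estimates.metabolite("DHA").q
            errors_q.append(abs(q - (-5.2)) / 5.2)
            prec = fit.precision
            cover_mu += prec.ci_low["mu"] <= 0.15 <= prec.ci_high["mu"]
            cover_q += prec.ci_low["q:DHA"] <= -5.2 <= prec.ci_high["q:DHA"]
        assert np.median(errors_mu) < 0.05
        assert np.median(errors_q) < 0.05
        assert 0.85 * n_rep <= cover_mu <= n_rep
        assert 0.85 * n_rep <= cover_q <= n_rep


class TestGoodnessOfFit:
    def test_perfect_fit_unit_correlation(self, noiseless_culture):
        tc, truth = noiseless_culture
        fit = fit_timecourse(tc, FitConfig(k_fixed={"DHA": 0.0086}))
        pearson, pooled = goodness_of_fit(tc, fit)
        assert pearson["biomass"] == pytest.approx(1.0, abs=1e-9)
        assert pearson["DHA"] == pytest.approx(1.0, abs=1e-9)
        assert pooled == pytest.approx(1.0, abs=1e-9)

    def test_anticorrelated_observations(self, noiseless_culture):
        tc, truth = noiseless_culture
        fit = fit_timecourse(tc, FitConfig(k_fixed={"DHA": 0.0086}))
        curves = predict(fit.estimates, tc.times)
        flipped = TimeCourse(
            times=tc.times,
            biomass=-curves["biomass"] + 2 * np.mean(curves["biomass"]),
            metabolites={"DHA": -curves["DHA"] + 2 * np.mean(curves["DHA"])},
        )
        pearson, pooled = goodness_of_fit(flipped, fit)
        assert pearson["biomass"] == pytest.approx(-1.0, abs=1e-9)
        assert pearson["DHA"] == pytest.approx(-1.0, abs=1e-9)

    def test_constant_series_reported_undefined(self):
        params = KineticParameters(
            x0=0.0185, mu=0.15,
            metabolites=(MetaboliteParams(name="inert", m0=5.0, q=0.0, k=0.0),),
        )
        tc, _ = make_culture(params)
        fit = fit_timecourse(tc)
        assert fit.pearson_r["inert"] is None
        assert fit.pearson_r["biomass"] is not None

    def test_noisy_pooled_correlation_high(self, noisy_culture, wt_fit_config):
        tc, _ = noisy_culture
        fit = fit_timecourse(tc, wt_fit_config)
        assert fit.pooled_r > 0.99
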