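"""Abiotic decay fitting, derived times, branch yields, co-consumption."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhaflux import (
    ConversionYields,
    InputError,
    apply_yields,
    characteristic_times,
    coconsumption_fluxes,
    degraded_fraction,
    fit_degradation,
)
from dhaflux.degradation import DEFAULT_YIELDS
from dhaflux.synthetic import NoiseSpec, generate_abiotic


class TestFitDegradation:
    def test_noiseless_recovery_from_three_points(self):
        t = np.array([0.0, 24.0, 48.0])
        res = fit_degradation(t, 15 * np.exp(-0.0086 * t))
        assert res.k == pytest.approx(0.0086, rel=1e-6)
        assert res.m0 == pytest.approx(15.0, rel=1e-6)
        assert res.converged

    def test_constant_series_gives_zero_rate_unbounded_halflife(self):
        res = fit_degradation([0.0, 10.0, 20.0, 30.0], [5.0, 5.0, 5.0, 5.0])
        assert res.k == pytest.approx(0.0, abs=1e-12)
        assert res.clamped_at_zero
        assert math.isinf(res.half_life) and math.isinf(res.reciprocal_time)

    def test_increasing_series_clamped_at_zero_with_flag(self):
        res = fit_degradation([0.0, 10.0, 20.0], [5.0, 5.5, 6.0])
        assert res.k == 0.0
        assert res.clamped_at_zero

    def test_noisy_recovery_within_two_sd(self):
        tc = generate_abiotic(
            k=0.0086, interval=3.0, noise=NoiseSpec(relative=0.02), seed=1
        )
        res = fit_degradation(tc.times, tc.metabolites["DHA"])
        assert abs(res.k - 0.0086) < 2 * res.k_sd

    def test_estimator_nearly_unbiased_at_two_percent_noise(self):
        ks = []
        for seed in range(200):
            tc = generate_abiotic(k=0.0086, noise=NoiseSpec(relative=0.02), seed=seed)
            ks.append(fit_degradation(tc.times, tc.metabolites["DHA"]).k)
        bias = abs(np.mean(ks) - 0.0086) / 0.0086
        assert bias < 0.02

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError, match=">= 3"):
            fit_degradation([0.0, 1.0], [2.0, 1.0])

    def test_nonpositive_concentrations_rejected(self):
        with pytest.raises(InputError):
            fit_degradation([0.0, 1.0, 2.0], [2.0, 0.0, -1.0])


class TestDegradedFraction:
    @pytest.mark.parametrize(
        "k, t, expected",
        [
            (0.0086, 48.0, 0.3382),   # the low-salt condition after 48 h
            (0.0086, 39.0, 0.2850),
            (0.0, 123.0, 0.0),
        ],
    )
    def test_values(self, k, t, expected):
        assert degraded_fraction(k, t) == pytest.approx(expected, abs=5e-4)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InputError):
            degraded_fraction(-0.1, 1.0)
        with pytest.raises(InputError):
            degraded_fraction(0.1, -1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        # keep k*t small enough that 1 - exp(-k t) stays below 1.0 in floats
        k=st.floats(1e-4, 0.5),
        t=st.floats(0.01, 30.0),
        dk=st.floats(1e-4, 0.5),
        dt=st.floats(0.01, 10.0),
    )
    def test_strictly_increasing_and_bounded(self, k, t, dk, dt):
        f = degraded_fraction(k, t)
        assert 0.0 <= f < 1.0
        assert degraded_fraction(k + dk, t) > f
        assert degraded_fraction(k, t + dt) > f


class TestCharacteristicTimes:
    def test_low_salt_values(self):
        reciprocal, half = characteristic_times(0.0086)
        assert reciprocal == pytest.approx(116.3, abs=0.05)
        assert half == pytest.approx(np.log(2) / 0.0086, rel=1e-12)
        assert half == pytest.approx(80.6, abs=0.05)

    def test_ln2_rate_gives_unit_half_life(self):
        _, half = characteristic_times(np.log(2))
        assert half == pytest.approx(1.0, rel=1e-12)

    def test_reciprocal_always_exceeds_half_life(self):
        for k in (1e-4, 0.0086, 0.5, 3.0):
            reciprocal, half = characteristic_times(k)
            assert reciprocal > half

    def test_zero_rate_flagged_unbounded(self):
        reciprocal, half = characteristic_times(0.0)
        assert math.isinf(reciprocal) and math.isinf(half)


class TestYields:
    def test_default_yields_partition(self):
        out = apply_yields(10.0, DEFAULT_YIELDS)
        assert out["formate"] == pytest.approx(3.6)
        assert out["glycolate"] == pytest.approx(2.6)
        assert out["acetate"] == pytest.approx(0.13)

    def test_zero_amount_all_zero(self):
        assert all(v == 0.0 for v in apply_yields(0.0).values())

    def test_full_yield_closes_mass(self):
        out = apply_yields(5.0, ConversionYields({"p": 1.0}))
        assert out["p"] == pytest.approx(5.0)
        assert out["unidentified"] == pytest.approx(0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        amount=st.floats(0.0, 1e3),
        y1=st.floats(0.0, 0.5),
        y2=st.floats(0.0, 0.5),
    )
    def test_mole_conservation(self, amount, y1, y2):
        out = apply_yields(amount, ConversionYields({"a": y1, "b": y2}))
        assert sum(out.values()) == pytest.approx(amount, abs=1e-12 * max(amount, 1.0))

    def test_yields_exceeding_unity_rejected(self):
        with pytest.raises(InputError):
            ConversionYields({"a": 0.7, "b": 0.4})
        with pytest.raises(InputError):
            ConversionYields({"a": -0.1})


class TestCoconsumption:
    def test_zero_yield_zero_flux(self):
        out = coconsumption_fluxes(
            0.0086, ConversionYields({"formate": 0.0}), [15.0, 14.0], [0.02, 0.03]
        )
        assert out["formate"] == 0.0

    def test_doubling_biomass_halves_flux(self):
        y = ConversionYields({"formate": 0.36})
        m = np.array([15.0, 14.0, 13.0])
        q1 = coconsumption_fluxes(0.0086, y, m, np.array([0.02, 0.02, 0.02]))
        q2 = coconsumption_fluxes(0.0086, y, m, np.array([0.04, 0.04, 0.04]))
        assert q1["formate"] == pytest.approx(2 * q2["formate"], rel=1e-12)

    def test_constant_series_closed_form(self):
        out = coconsumption_fluxes(
            0.0086,
            ConversionYields({"formate": 0.36}),
            np.full(5, 15.0),
            np.full(5, 0.04),
        )
        assert out["formate"] == pytest.approx(0.36 * 0.0086 * 15.0 / 0.04, rel=1e-12)

    def test_quasi_steady_balance_keeps_product_flat(self):
        # with q_P balancing abiotic production, dP/dt = y k M - q_P X = 0
        y, k = 0.36, 0.0086
        m = np.full(10, 15.0)
        x = np.full(10, 0.04)
        q_p = coconsumption_fluxes(k, ConversionYields({"formate": y}), m, x)["formate"]
        dp_dt = y * k * m - q_p * x
        assert np.allclose(dp_dt, 0.0, atol=1e-12)

    def test_vanishing_biomass_rejected(self):
        with pytest.raises(InputError):
            coconsumption_fluxes(0.0086, DEFAULT_YIELDS, [15.0, 14.0], [0.02, 0.0])
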