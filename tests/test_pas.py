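"""Sampler calibration and water-concentration inference."""

import math

import numpy as np
import pytest

from deltarisk import pas, synth
from deltarisk._util import round_half_away


class TestCosolventRegression:
    def test_exact_line(self):
        pts = [
            pas.CosolventMeasurement(0.1, 5.0),
            pas.CosolventMeasurement(0.2, 4.0),
            pas.CosolventMeasurement(0.3, 3.0),
        ]
        fit = pas.fit_cosolvent_regression(pts)
        assert fit.intercept == pytest.approx(6.0, abs=1e-12)
        assert fit.slope == pytest.approx(-10.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_recovers_generating_intercept_noise_free(self):
        pts = synth.gen_cosolvent_series(5.86, -8.0, [0.05, 0.1, 0.15, 0.2, 0.25])
        fit = pas.fit_cosolvent_regression(pts)
        assert fit.intercept == pytest.approx(5.86, abs=1e-9)

    def test_noisy_fixtures_are_unbiased(self):
        """Mean recovered intercept over 200 noisy series within +/-0.02 of truth."""
        intercepts = []
        for seed in range(200):
            pts = synth.gen_cosolvent_series(
                5.86, -8.0, [0.05, 0.1, 0.15, 0.2, 0.25, 0.3], noise_sd=0.1, seed=seed
            )
            intercepts.append(pas.fit_cosolvent_regression(pts).intercept)
        assert np.mean(intercepts) == pytest.approx(5.86, abs=0.02)

    def test_insufficient_points(self):
        pts = [pas.CosolventMeasurement(0.1, 5.0), pas.CosolventMeasurement(0.2, 4.0)]
        with pytest.raises(pas.InsufficientDataError):
            pas.fit_cosolvent_regression(pts)

    def test_degenerate_identical_fractions(self):
        pts = [pas.CosolventMeasurement(0.1, v) for v in (5.0, 4.0, 3.0)]
        with pytest.raises(pas.InsufficientDataError):
            pas.fit_cosolvent_regression(pts)


class TestPrcKinetics:
    @pytest.mark.parametrize(
        "retained,days,expected",
        [(1.0, 5.0, 0.0), (math.exp(-1), 1.0, 1.0), (0.5, 3.5, math.log(2) / 3.5)],
    )
    def test_exchange_coefficient_closed_form(self, retained, days, expected):
        obs = pas.PrcObservation("PRC-1", retained, days)
        assert pas.prc_exchange_coefficient(obs) == pytest.approx(expected, abs=1e-12)

    def test_full_dissipation_unidentifiable(self):
        with pytest.raises(ValueError):
            pas.PrcObservation("PRC-1", 0.0, 3.5)

    def test_identity_scaling_when_prc_matches_analyte_kpw(self, sampler):
        sampler = sampler.with_analyte("PRC-1", sampler.log_kpw["deltamethrin"])
        obs = pas.PrcObservation("PRC-1", 0.5, 3.5)
        kin = pas.pool_prc_kinetics([obs], sampler, "deltamethrin")
        assert kin.ke == pytest.approx(pas.prc_exchange_coefficient(obs), rel=1e-12)

    def test_pooling_is_idempotent_for_identical_prcs(self, sampler):
        sampler = sampler.with_analyte("PRC-1", 5.0)
        obs = pas.PrcObservation("PRC-1", 0.4, 2.0)
        one = pas.pool_prc_kinetics([obs], sampler, "deltamethrin")
        two = pas.pool_prc_kinetics([obs, obs], sampler, "deltamethrin")
        assert two.ke == pytest.approx(one.ke, rel=1e-12)

    def test_recovers_generating_ke_noise_free(self, sampler):
        truth = 0.5
        obs = synth.gen_prc_dissipation(truth, [1.0, 2.0, 3.5], noise_sd=0.0)
        for o in obs:
            sampler = sampler.with_analyte(o.compound, sampler.log_kpw["deltamethrin"])
        kin = pas.pool_prc_kinetics(obs, sampler, "deltamethrin")
        assert kin.ke == pytest.approx(truth, abs=1e-9)

    def test_no_usable_prc_is_a_calibration_error(self, sampler):
        sampler = sampler.with_analyte("PRC-1", 5.0)
        obs = [pas.PrcObservation("PRC-1", 0.99, 3.5)]  # outside (0.05, 0.95)
        with pytest.raises(pas.CalibrationError):
            pas.pool_prc_kinetics(obs, sampler, "deltamethrin")

    def test_regime_classification(self, sampler):
        sampler = sampler.with_analyte("PRC-1", sampler.log_kpw["deltamethrin"])
        slow = pas.pool_prc_kinetics([pas.PrcObservation("PRC-1", 0.94, 1.0)], sampler, "deltamethrin")
        fast = pas.pool_prc_kinetics([pas.PrcObservation("PRC-1", 0.06, 0.5)], sampler, "deltamethrin")
        assert slow.regime == "kinetic"
        assert fast.regime in ("equilibrium", "intermediate")


class TestWaterConcentration:
    def test_zero_absorbed_gives_zero(self, sampler, field_kin):
        assert pas.water_concentration(0.0, sampler, field_kin, 3.5) == 0.0

    def test_equilibrium_limit(self, sampler):
        kin = pas.ExchangeKinetics(ke=100.0, rs=1.0)
        absorbed = sampler.kpw("deltamethrin") * sampler.mass * 100.0
        assert pas.water_concentration(absorbed, sampler, kin, 5.0) == pytest.approx(100.0, rel=1e-9)

    def test_round_trip_at_constant_concentration(self, sampler, field_kin):
        n = synth.gen_pas_uptake([(0, 250.0), (3.5, 250.0)], sampler, field_kin)
        cw = pas.water_concentration(n, sampler, field_kin, 3.5)
        assert cw == pytest.approx(250.0, rel=1e-3)

    @pytest.mark.parametrize("log_kpw", [3.0, 5.0, 7.0])
    @pytest.mark.parametrize("ket", [0.01, 0.5, 10.0])
    def test_round_trip_across_kpw_and_kinetic_depth(self, log_kpw, ket):
        sampler = pas.PolymerSampler(log_kpw={"x": log_kpw})
        t = 3.5
        ke = ket / t
        kin = pas.ExchangeKinetics(ke=ke, rs=ke * 10**log_kpw * sampler.mass)
        n = synth.gen_pas_uptake([(0, 42.0), (t, 42.0)], sampler, kin, analyte="x")
        cw = pas.water_concentration(n, sampler, kin, t, analyte="x")
        assert cw == pytest.approx(42.0, rel=1e-3)

    @pytest.mark.parametrize("ket", [0.005, 0.02, 0.1, 0.14])
    def test_kinetic_and_general_forms_agree_to_first_order(self, sampler, ket):
        """The gap between the general and linear-uptake forms is ~ke*t/2,
        so the simple 1/t scaling is accurate to ~1% only while ke*t < ~0.02
        (amply satisfied by the default field kinetics, ke*t ~ 1e-4)."""
        t = 3.5
        ke = ket / t
        rs = ke * sampler.kpw("deltamethrin") * sampler.mass
        kin = pas.ExchangeKinetics(ke=ke, rs=rs)
        absorbed = 12.0
        general = pas.water_concentration(absorbed, sampler, kin, t)
        kinetic = absorbed / (rs * t)
        rel_gap = abs(general - kinetic) / general
        assert rel_gap <= ket / 2 + 1e-9
        if ket <= 0.02:
            assert rel_gap < 0.01

    def test_zero_ke_falls_back_to_sampling_rate(self, sampler):
        kin = pas.ExchangeKinetics(ke=0.0, rs=0.2)
        assert pas.water_concentration(1.0, sampler, kin, 2.0) == pytest.approx(1.0 / 0.4)


class TestDurationScenarios:
    def test_rescaling_matches_reported_cells(self):
        assert pas.rescale_kinetic(364, 0.5, 2.0) == pytest.approx(91.0)
        assert pas.rescale_kinetic(364, 0.5, 1.0) == pytest.approx(182.0)

    def test_identity(self):
        assert pas.rescale_kinetic(57.0, 1.5, 1.5) == pytest.approx(57.0)

    def test_lowest_estimate_rounds_to_reported_value(self):
        c = pas.rescale_kinetic(74, 0.5, 3.5)
        assert c == pytest.approx(74 * 0.5 / 3.5)
        assert round_half_away(c) == 11

    def test_nonpositive_durations_rejected(self):
        with pytest.raises(ValueError):
            pas.rescale_kinetic(10.0, 0.0, 1.0)

    def _base(self, cw, station="B", band="3-5 m", dist=45.0):
        return pas.WaterConcentrationEstimate(
            cw=cw, assumed_duration=0.5, station=station, depth_band=band,
            distance_to_pen=dist,
        )

    def test_station_column_reproduces_reported_table(self):
        table = pas.scenario_table([self._base(143.0)], [1.0, 2.0, 3.5])
        assert list(table.rounded["B-3-5 m"]) == [72, 36, 20]

    def test_reference_duration_returns_base_unchanged(self):
        table = pas.scenario_table([self._base(143.0)], [0.5])
        assert table.raw.loc[0.5, "B-3-5 m"] == pytest.approx(143.0)

    def test_row_conservation(self):
        durations = [0.5, 1.0, 2.0, 3.5]
        table = pas.scenario_table([self._base(143.0), self._base(364.0, "E", dist=15.0)], durations)
        for col in table.raw:
            products = table.raw[col].to_numpy() * np.array(durations)
            np.testing.assert_allclose(products, products[0], rtol=1e-12)

    def test_empty_durations_rejected(self):
        with pytest.raises(ValueError):
            pas.scenario_table([self._base(143.0)], [])

    def test_mixed_reference_durations_rejected(self):
        other = pas.WaterConcentrationEstimate(cw=10, assumed_duration=1.0, station="C")
        with pytest.raises(ValueError):
            pas.scenario_table([self._base(143.0), other], [1.0])


class TestLodConversion:
    def test_polymer_lod_to_water_lod(self, sampler, field_kin):
        """0.04 ng/g polymer equals ~4 ng/L at 0.5 d, 0.6 ng/L at 3.5 d."""
        at_half_day = pas.lod_water_equivalent(0.04, sampler, field_kin, 0.5)
        assert at_half_day == pytest.approx(4.0, rel=1e-3)
        at_3p5 = pas.lod_water_equivalent(0.04, sampler, field_kin, 3.5)
        assert round_half_away(at_3p5, 1) == pytest.approx(0.6)

    def test_inverse_time_law(self, sampler, field_kin):
        one = pas.lod_water_equivalent(0.04, sampler, field_kin, 1.0)
        two = pas.lod_water_equivalent(0.04, sampler, field_kin, 2.0)
        assert two == pytest.approx(one / 2.0, rel=1e-4)

    def test_zero_lod(self, sampler, field_kin):
        assert pas.lod_water_equivalent(0.0, sampler, field_kin, 1.0) == 0.0

    def test_nonpositive_duration_rejected(self, sampler, field_kin):
        with pytest.raises(ValueError):
            pas.lod_water_equivalent(0.04, sampler, field_kin, 0.0)


class TestCensoring:
    def test_nothing_censored_above_lod(self):
        out = pas.censor([1.0, 2.0], 0.5)
        assert not any(m.censored for m in out)

    def test_everything_censored_below_lod(self):
        out = pas.censor([0.1, 0.2], 0.5)
        assert all(m.censored for m in out)
        assert str(out[0]) == "<0.5"

    def test_mixed_counts_and_order(self):
        out = pas.censor([0.03, 0.19, 0.01], 0.02)
        assert [m.censored for m in out] == [False, False, True]
        assert sum(m.censored for m in out) + sum(not m.censored for m in out) == 3
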