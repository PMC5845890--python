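"""Sensor forward/inverse models and the Nernst chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensortrace import sensors as S


class TestHillFractionBound:
    @pytest.mark.parametrize(
        "conc, expected",
        [
            (1.6, 0.5),  # half-saturation at kd
            (0.0, 0.0),
            (0.1, 8.053e-5),  # deep sub-kd regime of a cooperative sensor
        ],
    )
    def test_reference_points(self, conc, expected):
        assert S.hill_fraction_bound(conc, S.RCAMP1E) == pytest.approx(
            expected, rel=1e-3
        )

    def test_monotone_increasing_on_grid(self):
        grid = np.linspace(0, 20, 1000)
        f = S.hill_fraction_bound(grid, S.RCAMP1E)
        assert np.all(np.diff(f) > 0)
        assert np.all((f >= 0) & (f <= 1))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            S.hill_fraction_bound(-0.1, S.RCAMP1E)


class TestAtpRatioModel:
    def test_zero_atp_gives_rmin(self):
        assert S.ratio_from_atp(0.0, rmin=0.5) == pytest.approx(0.5)

    def test_half_dynamic_span_at_kd(self):
        # at [ATP] = Kd the ratio sits midway between Rmin and Rmax
        assert S.ratio_from_atp(3.3, rmin=0.5) == pytest.approx(0.825)

    def test_saturation_limit(self):
        r = S.ratio_from_atp(330.0, rmin=0.5)
        assert r == pytest.approx(0.5 * 2.3, rel=1e-3)
        assert r < 0.5 * 2.3

    def test_monotone_on_grid(self):
        grid = np.linspace(0, 50, 1000)
        r = S.ratio_from_atp(grid, rmin=1.0)
        assert np.all(np.diff(r) > 0)

    def test_midpoint_inversion(self):
        assert S.atp_from_ratio(1.65) == pytest.approx(3.3, abs=1e-12)

    def test_r_of_one_is_zero(self):
        assert S.atp_from_ratio(1.0) == 0.0

    def test_round_trip_identity(self):
        atp = np.linspace(0.0, 50.0, 1000)
        r = S.ratio_from_atp(atp, rmin=0.5)
        back = S.atp_from_ratio(r / 0.5)
        assert np.max(np.abs(back - atp)) < 1e-9

    def test_round_trip_with_alternative_hill_exponent(self):
        spec = S.SensorSpec("ATeam1.03", kd=3.3, hill_coefficient=2.1,
                            dynamic_range=2.3)
        atp = np.array([0.5, 2.0, 8.0])
        back = S.atp_from_ratio(S.ratio_from_atp(atp, spec), spec)
        assert np.max(np.abs(back - atp)) < 1e-9

    def test_sub_baseline_ratio_clips_to_zero(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="sensortrace.sensors"):
            assert S.atp_from_ratio(0.98) == 0.0
        assert any("clipping" in r.message for r in caplog.records)

    def test_saturated_ratio_raises(self):
        with pytest.raises(S.SaturationError):
            S.atp_from_ratio(2.3)


class TestFractionReduced:
    @pytest.mark.parametrize(
        "f, expected", [(1.0, 1.0), (0.4, 0.0), (0.7, 0.5)]
    )
    def test_endpoints_and_midpoint(self, f, expected):
        assert S.fraction_reduced(f, f_red=1.0, f_ox=0.4) == pytest.approx(expected)

    def test_degenerate_calibration(self):
        with pytest.raises(S.CalibrationError):
            S.fraction_reduced(0.5, 1.0, 1.0)

    @given(
        f=st.floats(-1e6, 1e6, allow_nan=False),
        f_red=st.floats(-1e3, 1e3),
        f_ox=st.floats(-1e3, 1e3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_always_within_unit_interval(self, f, f_red, f_ox):
        if f_red == f_ox:
            return
        out = S.fraction_reduced(f, f_red, f_ox)
        assert 0.0 <= out <= 1.0


class TestNernstChain:
    def test_dtt_ratio_reference_points(self):
        assert S.dtt_ratio_from_fraction(0.5, 0.070) == pytest.approx(0.070)
        assert S.dtt_ratio_from_fraction(1 / 1.070, 0.070) == pytest.approx(1.0)
        assert S.dtt_ratio_from_fraction(0.8, 0.070) == pytest.approx(0.28)

    def test_midpoint_potential_both_presets(self):
        e1 = S.nernst_sensor_midpoint(S.CONSTANTS, 0.070)
        e2 = S.nernst_sensor_midpoint(S.CONSTANTS_DOOLEY, 0.070)
        assert round(e1, 3) == -0.288
        assert round(e2, 3) == -0.295

    def test_midpoint_equals_e0_at_unit_keq(self):
        assert S.nernst_sensor_midpoint(S.CONSTANTS, 1.0) == pytest.approx(-0.323)

    def test_potential_equals_e0_at_equilibrium_fraction(self):
        # Keq·R/(1−R) = 1 exactly when R = 1/(1+Keq)
        r = 1.0 / (1.0 + 0.070)
        assert S.redox_potential(r) == pytest.approx(-0.323, abs=1e-12)

    def test_half_reduced_reduces_to_midpoint(self):
        assert S.redox_potential(0.5) == pytest.approx(
            S.nernst_sensor_midpoint(), abs=1e-12
        )

    def test_more_reduced_is_more_negative(self):
        assert S.redox_potential(0.9) < S.redox_potential(0.3)
        grid = np.linspace(0.01, 0.99, 1000)
        pots = np.array([S.redox_potential(r) for r in grid])
        assert np.all(np.diff(pots) < 0)

    def test_boundary_fraction_is_clamped(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="sensortrace.sensors"):
            out = S.redox_potential(1.0)
        assert math.isfinite(out)
        assert any("clamped" in r.message for r in caplog.records)


class TestPhAdjustment:
    def test_reference_ph_unchanged(self):
        assert S.ph_adjusted_e0(-0.288, 7.0) == -0.288

    def test_mitochondrial_ph(self):
        assert S.ph_adjusted_e0(-0.288, 7.98) == pytest.approx(-0.3469, abs=5e-5)

    def test_unit_ph_step(self):
        assert S.ph_adjusted_e0(-0.3, 8.0) - S.ph_adjusted_e0(-0.3, 7.0) == (
            pytest.approx(-0.0601)
        )


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kd=-1.0),
            dict(hill_coefficient=0.0),
            dict(dynamic_range=0.9),
            dict(keq=-0.1),
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            S.SensorSpec("bad", **kwargs)

    def test_constants_validation(self):
        with pytest.raises(ValueError):
            S.PhysConstants(temperature=-1.0)
        with pytest.raises(ValueError):
            S.PhysConstants(electrons=0)
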