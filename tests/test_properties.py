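"""Constitutive laws: mixing rules, viscosity law, conversions, Reynolds."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from implantflow import (FluidProperties, inlet_mass_fraction,
                         inlet_reynolds_number, reynolds_number)


@pytest.fixture(scope="module")
def props():
    return FluidProperties()


class TestMixtureDensity:
    @pytest.mark.parametrize("Y0,expected", [
        (0.0, 1025.0),                       # pure plasma
        (1.0, 1400.0),                       # pure fibrinogen
        (0.0029, 1 / (0.0029 / 1400 + 0.9971 / 1025)),  # ~1025.8
    ])
    def test_values(self, props, Y0, expected):
        assert props.mixture_density(Y0) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_rejected(self, props):
        with pytest.raises(ValueError):
            props.mixture_density(-0.1)
        with pytest.raises(ValueError):
            props.mixture_density(1.1)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_and_bounded(self, a, b):
        p = FluidProperties()
        ra, rb = p.mixture_density(a), p.mixture_density(b)
        assert 1025.0 - 1e-9 <= ra <= 1400.0 + 1e-9
        if a < b:
            assert ra <= rb


class TestPlasmaViscosity:
    @pytest.mark.parametrize("C,expected_mPas", [
        (0.0, 0.53),                          # intercept of the first branch
        (2.0, 0.19 * 4 + 1.03),               # quadratic branch: 1.79
    ])
    def test_values(self, props, C, expected_mPas):
        assert props.plasma_viscosity(C) == pytest.approx(expected_mPas * 1e-3,
                                                          rel=1e-12)

    def test_continuous_at_one(self, props):
        # both branches evaluate to 1.22 mPa.s at C = 1
        assert (0.37 * 1 + 0.85) == pytest.approx(0.19 * 1 + 1.03)
        lo = props.plasma_viscosity(1.0 - 1e-9)
        hi = props.plasma_viscosity(1.0)
        assert hi == pytest.approx(1.22e-3, rel=1e-9)
        assert abs(hi - lo) < 1e-9

    def test_small_documented_jump_at_040(self, props):
        lo = props.plasma_viscosity(0.40 - 1e-12)
        hi = props.plasma_viscosity(0.40)
        assert hi > lo                        # jump is upward...
        assert (hi - lo) / lo < 0.01          # ...and below 1%

    def test_monotone_nondecreasing(self, props):
        C = np.linspace(0.0, 5.0, 2001)
        mu = props.plasma_viscosity(C)
        assert (np.diff(mu) >= -1e-15).all()

    def test_negative_rejected(self, props):
        with pytest.raises(ValueError):
            props.plasma_viscosity(-0.1)


class TestConversions:
    def test_concentration_examples(self, props):
        assert props.concentration_from_mass_fraction(0.0, 1025.0) == 0.0
        C = props.concentration_from_mass_fraction(0.0029, 1025.8)
        assert C == pytest.approx(0.2975, abs=1e-3)

    @given(st.floats(0.0, 0.5), st.floats(900.0, 1500.0))
    def test_round_trip(self, Y0, rho):
        p = FluidProperties()
        C = p.concentration_from_mass_fraction(Y0, rho)
        assert p.mass_fraction_from_concentration(C, rho) == pytest.approx(
            Y0, abs=1e-12)

    @pytest.mark.parametrize("fib,rho,expected", [
        (3.0, 1024.0, 0.0029),    # human serum reference values
        (0.0, 1024.0, 0.0),
        (3.0, 1000.0, 0.0030),
    ])
    def test_inlet_mass_fraction(self, fib, rho, expected):
        assert inlet_mass_fraction(fib, rho) == pytest.approx(expected, abs=1e-12)

    def test_inlet_mass_fraction_zero_density(self):
        with pytest.raises(ValueError):
            inlet_mass_fraction(3.0, 0.0)


class TestCellBlend:
    def test_endpoints(self, props):
        assert props.cell_mixture_properties(1.0, 0.0) == pytest.approx(
            (1025.0, 0.00053), rel=1e-9)
        assert props.cell_mixture_properties(0.0, 0.0029) == pytest.approx(
            (1125.0, 0.0050), rel=1e-9)

    def test_inlet_blend_density(self, props):
        rho, _ = props.cell_mixture_properties(0.55, 0.0029)
        assert rho == pytest.approx(1070.4, abs=0.1)

    @given(st.floats(0.0, 1.0))
    def test_linear_in_alpha(self, alpha):
        p = FluidProperties()
        r0, m0 = p.cell_mixture_properties(0.0, 0.0029)
        r1, m1 = p.cell_mixture_properties(1.0, 0.0029)
        r, m = p.cell_mixture_properties(alpha, 0.0029)
        assert r == pytest.approx(alpha * r1 + (1 - alpha) * r0, rel=1e-12)
        assert m == pytest.approx(alpha * m1 + (1 - alpha) * m0, rel=1e-12)

    def test_out_of_range_alpha_rejected(self, props):
        with pytest.raises(ValueError):
            props.cell_mixture_properties(1.5, 0.0)


class TestReynolds:
    def test_inlet_value_rounds_to_six(self):
        # whole blood at 45% hematocrit, 0.01 m/s, 1.5 mm channel width
        assert round(inlet_reynolds_number()) == 6

    def test_zero_speed(self):
        assert reynolds_number(1000.0, 0.0, 0.0015, 0.001) == 0.0

    def test_hand_value(self):
        assert reynolds_number(1000.0, 0.01, 0.0015, 0.001) == pytest.approx(15.0)

    def test_nonpositive_viscosity_rejected(self):
        with pytest.raises(ValueError):
            reynolds_number(1000.0, 0.01, 0.0015, 0.0)


class TestValidation:
    def test_positive_constants_enforced(self):
        with pytest.raises(ValueError):
            FluidProperties(rho_plasma=-1.0)
        with pytest.raises(ValueError):
            FluidProperties(mu_rbc=0.0)
        with pytest.raises(ValueError):
            FluidProperties(sigma=-0.01)

    def test_viscosity_law_gap_rejected(self):
        with pytest.raises(ValueError):
            FluidProperties(viscosity_pieces=(
                (0.0, 0.4, (0.0, 1.16, 0.53)),
                (0.5, np.inf, (0.19, 0.0, 1.03)),   # gap 0.4-0.5
            ))
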