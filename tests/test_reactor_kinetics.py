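"""Reactor O2 mass balance, specific rates, quotients, steady-state check."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from photoacclim import reactor_kinetics as rk


@pytest.fixture
def reactor_gas():
    # kLa 0.83 min^-1, kH 1.08 mM atm^-1, O2-free sparge
    return rk.GasLiquidParams(kla=0.83, kla_unit="per_minute", kH=1.08,
                              pO2_in=0.0, O2_in=0.0)


class TestEquilibriumO2:
    def test_zero_pressure(self, reactor_gas):
        assert rk.equilibrium_O2(reactor_gas, 0.0) == 0.0

    def test_hyperoxic_sparge(self, reactor_gas):
        # pO2 0.78 atm dissolves ~840 uM at kH = 1.08 mM/atm
        assert rk.equilibrium_O2(reactor_gas, 0.78) == pytest.approx(842.4)

    def test_co2_level_sparge(self, reactor_gas):
        assert rk.equilibrium_O2(reactor_gas, 0.02) == pytest.approx(21.6)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    def test_linearity_in_pressure(self, a, b):
        gas = rk.GasLiquidParams(kla=49.8, kH=1.08)
        f = lambda p: rk.equilibrium_O2(gas, p)
        assert f(a) + f(b) - f(0) == pytest.approx(f(a + b), rel=1e-9)


class TestComputeQO2:
    def test_equilibrium_no_net_flux(self):
        gas = rk.GasLiquidParams(kla=50.0, kH=1.08, pO2_in=0.2, O2_in=216.0)
        rec = rk.SteadyStateRecord(Ii=100, D=0.1, mu=0.1, OD730=0.08,
                                   x=0.036, O2=216.0)
        assert rk.compute_qO2(rec, gas) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_value(self, reactor_gas):
        # (0.2*8 + 49.8*8) uM/h over 0.036 g/L = 11.1 mmol h^-1 g^-1
        rec = rk.SteadyStateRecord(Ii=100, D=0.2, mu=0.2, OD730=0.082,
                                   x=0.036, O2=8.0)
        assert rk.compute_qO2(rec, reactor_gas) == pytest.approx(11.111, rel=1e-3)

    def test_doubling_biomass_halves_rate(self, reactor_gas):
        r1 = rk.SteadyStateRecord(Ii=1, D=0.2, mu=0.2, OD730=0.08,
                                  x=0.036, O2=8.0)
        r2 = rk.SteadyStateRecord(Ii=1, D=0.2, mu=0.2, OD730=0.16,
                                  x=0.072, O2=8.0)
        assert rk.compute_qO2(r1, reactor_gas) == pytest.approx(
            2 * rk.compute_qO2(r2, reactor_gas))

    def test_kla_unit_tag_equivalence(self):
        per_min = rk.GasLiquidParams(kla=0.83, kla_unit="per_minute")
        per_hr = rk.GasLiquidParams(kla=49.8, kla_unit="per_hour")
        rec = rk.SteadyStateRecord(Ii=1, D=0.2, mu=0.2, OD730=0.08,
                                   x=0.036, O2=8.0)
        assert rk.compute_qO2(rec, per_min) == pytest.approx(
            rk.compute_qO2(rec, per_hr), rel=1e-12)

    def test_nonpositive_biomass_rejected(self, reactor_gas):
        rec = rk.SteadyStateRecord(Ii=1, D=0.2, mu=0.2, OD730=0.0,
                                   x=0.0, O2=8.0)
        with pytest.raises(ValueError):
            rk.compute_qO2(rec, reactor_gas)


class TestComputeQX:
    @pytest.mark.parametrize("mu, expected", [
        (0.0, 0.0),
        (0.20, 8.13),  # Cmmol h^-1 g^-1 at the maximal growth rate
        (0.07, 2.85),
    ])
    def test_carbon_basis_conversion(self, mu, expected):
        assert rk.compute_qX(mu) == pytest.approx(expected, abs=0.005)

    @settings(derandomize=True, max_examples=50)
    @given(mu=st.floats(1e-6, 1.0), scale=st.floats(1.1, 10.0))
    def test_linear_and_increasing(self, mu, scale):
        assert rk.compute_qX(mu * scale) == pytest.approx(
            scale * rk.compute_qX(mu), rel=1e-12)
        assert rk.compute_qX(mu * scale) > rk.compute_qX(mu)


def _ols_slope_oracle(x, y):
    """Closed-form OLS slope via the sigma formula."""
    x, y = np.asarray(x), np.asarray(y)
    return (np.sum(x * y) - len(x) * x.mean() * y.mean()) / \
        (np.sum(x * x) - len(x) * x.mean() ** 2)


class TestPhotosyntheticQuotient:
    def test_collinear_points_exact(self):
        q = np.array([1., 3., 5., 8.])
        fits = rk.photosynthetic_quotient(q, 1.3 * q, ["lim"] * 4)
        assert fits["lim"].Q == pytest.approx(1.3, rel=1e-12)

    def test_two_point_slope(self):
        fits = rk.photosynthetic_quotient([0., 10.], [0., 6.], ["s", "s"])
        assert fits["s"].Q == pytest.approx(0.6)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 12)
        y = 1.3 * x + rng.normal(0, 0.3, 12)
        fits = rk.photosynthetic_quotient(x, y, ["r"] * 12)
        assert fits["r"].Q == pytest.approx(_ols_slope_oracle(x, y), rel=1e-12)

    def test_monte_carlo_recovery(self):
        # true slope 1.3, noise sd 0.2, n=6 per seed, 500 seeds:
        # mean estimate within 3 standard errors of the truth
        x = np.linspace(1, 8, 6)
        est = []
        for s in range(500):
            rng = np.random.default_rng(s)
            y = 1.3 * x + rng.normal(0, 0.2, 6)
            est.append(rk.photosynthetic_quotient(x, y, ["r"] * 6)["r"].Q)
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 1.3) < 3 * se

    def test_degenerate_regimes_flagged(self):
        fits = rk.photosynthetic_quotient([1., 1., 2.], [1., 2., 3.],
                                          ["a", "a", "b"])
        assert not fits["a"].ok  # zero qO2 variance
        assert not fits["b"].ok  # single point

    def test_no_intercept_option(self):
        x = np.array([1., 2., 4.])
        y = 0.7 * x
        fits = rk.photosynthetic_quotient(x, y, ["r"] * 3,
                                          fit_intercept=False)
        assert fits["r"].Q == pytest.approx(0.7, rel=1e-12)
        assert fits["r"].intercept == 0.0


class TestDetectSteadyState:
    def test_constant_channels_steady(self):
        v = rk.detect_steady_state(
            {"OD730": [0.082] * 4, "pH": [7.5] * 4, "O2": [8.0] * 4},
            residence_times_elapsed=6)
        assert v.steady

    def test_large_od_step_rejected(self):
        v = rk.detect_steady_state({"OD730": [0.080, 0.090]},
                                   residence_times_elapsed=6)
        assert not v.steady
        assert v.channel_verdicts["OD730"] is False

    def test_boundary_three_percent_inclusive(self):
        # |delta|/pair-mean exactly 3.0% passes (inclusive threshold):
        # 197 -> 203 varies by 6/200 = 3% of the pair mean
        v = rk.detect_steady_state(
            {"O2": [197.0, 203.0], "pH": [7.5, 7.5]},
            residence_times_elapsed=5)
        assert v.max_variation["O2"] == pytest.approx(0.03, abs=1e-15)
        assert v.steady

    def test_too_few_residence_times(self):
        v = rk.detect_steady_state({"OD730": [0.082, 0.082]},
                                   residence_times_elapsed=4.9)
        assert not v.steady

    def test_empty_channel_indeterminate(self):
        v = rk.detect_steady_state({"OD730": [0.082, 0.082], "pH": []},
                                   residence_times_elapsed=6)
        assert v.channel_verdicts["pH"] is None
        assert not v.steady


def test_doubling_time_of_max_growth_rate():
    assert rk.doubling_time(0.20) == pytest.approx(np.log(2) / 0.20)
    assert rk.doubling_time(0.0) == np.inf
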