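"""Packing diagnostics, control order parameters, toy model, scans."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import multitrophic as mt
from multitrophic.errors import UndefinedControlError
from multitrophic.observables import DerivativeControl, PackingCounts

S1_TOY = dict(k1=5.0, m1=1.0, u1=2.0, eta_N=0.9, eta_X=0.9,
              D_R=1.0, D_N=5.0, D_X=5.0, c11=4.0, d11=4.0)


def toy_rhs(t, y, tp):
    R, N, X = y
    return [
        R * (tp["k1"] - tp["D_R"] * R - tp["c11"] * N),
        N * (tp["eta_N"] * tp["c11"] * R - tp["m1"] - tp["D_N"] * N - tp["d11"] * X),
        X * (tp["eta_X"] * tp["d11"] * N - tp["u1"] - tp["D_X"] * X),
    ]


def integrate_toy(tp, y0=(1.0, 1.0, 1.0), t_final=3000.0):
    sol = solve_ivp(toy_rhs, (0, t_final), y0, args=(tp,), method="LSODA",
                    rtol=1e-10, atol=1e-12)
    out = sol.y[:, -1]
    out[out < 1e-8] = 0.0
    return out


class TestFRatio:
    def test_arithmetic(self):
        assert mt.f_ratio(PackingCounts(4, 8, 10)) == pytest.approx(1.5)

    def test_saturated_middle_level(self):
        assert mt.f_ratio(PackingCounts(4, 14, 10)) == 0.0

    def test_filled_top_level_is_undefined(self):
        with pytest.raises(ZeroDivisionError, match="unfilled"):
            mt.f_ratio(PackingCounts(8, 8, 10))

    def test_cavity_counts_consistent_with_D_eff_R(self, reference_cavity):
        st = reference_cavity
        f = mt.f_ratio(PackingCounts.from_cavity(st))
        assert st.D_eff_R == pytest.approx(1 + 1 / f, abs=1e-8)
        assert f == pytest.approx(st.f, rel=1e-10)


class TestPackingForms:
    def test_agree_with_susceptibility_definitions(self, random_cavity_states):
        for st in random_cavity_states:
            D_X, D_N, D_R = mt.d_eff_from_packing(
                PackingCounts.from_cavity(st), st.params, st.phi_N
            )
            assert D_X == pytest.approx(st.D_eff_X, abs=1e-8)
            assert D_N == pytest.approx(st.D_eff_N, abs=1e-8)
            assert D_R == pytest.approx(st.D_eff_R, abs=1e-8)

    def test_linearity_in_predator_variance(self, reference_cavity):
        st = reference_cavity
        counts = PackingCounts.from_cavity(st)
        p = st.params
        p2 = dataclasses.replace(p, sigma_d=np.sqrt(2) * p.sigma_d)
        a = mt.d_eff_from_packing(counts, p, st.phi_N)
        b = mt.d_eff_from_packing(counts, p2, st.phi_N)
        assert b[0] == pytest.approx(2 * a[0], rel=1e-12)  # D_eff_X doubles
        assert b[1] == pytest.approx(a[1], rel=1e-12)      # D_eff_N unchanged

    def test_large_f_limit_is_bare_logistic(self):
        counts = PackingCounts(0.0, 1.0, 1e9)
        _, _, D_R = mt.d_eff_from_packing(counts, mt.ModelParams3(), 0.5)
        assert D_R == pytest.approx(1.0, abs=1e-6)


class TestOrderParameters:
    def test_biomass_limits(self, reference_cavity):
        st = reference_cavity
        assert mt.biomass_order_parameter(
            dataclasses.replace(st, mean_X=0.0)
        ) == 0.0
        assert mt.biomass_order_parameter(
            dataclasses.replace(st, mean_R=0.0)
        ) == 1.0
        with pytest.raises(UndefinedControlError):
            mt.biomass_order_parameter(
                dataclasses.replace(st, mean_X=0.0, mean_R=0.0)
            )

    def test_packing_from_counts_and_identity(self, reference_cavity):
        assert mt.packing_order_parameter(PackingCounts(4, 8, 10)) == 0.5
        st = reference_cavity
        p = st.params
        via_sus = (-p.eta_X * p.r1 * p.sigma_d**2 * st.chi) / (
            p.eta_N * p.sigma_c**2 * st.kappa - p.eta_X * p.r1 * p.sigma_d**2 * st.chi
        )
        assert mt.packing_order_parameter(st) == pytest.approx(via_sus, abs=1e-10)

    def test_empty_middle_level_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mt.packing_order_parameter(PackingCounts(0, 0, 5))

    def test_derivative_fractions_sum_to_one(self, reference_params, reference_cavity):
        d = mt.derivative_order_parameter(
            reference_params, seed=3, base_state=reference_cavity
        )
        assert isinstance(d, DerivativeControl)
        assert d.bottom_up + d.top_down == pytest.approx(1.0)
        assert 0.0 <= d.bottom_up <= 1.0
        assert d.dN_dk > 0  # more plant energy feeds herbivores

    def test_bottom_up_regime_when_predators_die_out(self):
        # high predator death rate: the top level barely survives and <N> is
        # controlled almost entirely by k
        p = mt.ModelParams3(k=2.0, u=5.0)
        st = mt.solve(p, seed=4)
        d = mt.derivative_order_parameter(p, seed=4, base_state=st)
        assert d.bottom_up > 0.9
        assert mt.packing_order_parameter(st) < 0.1

    def test_assembled_control_order_parameters(self, reference_cavity):
        cop = mt.control_order_parameters(reference_cavity, seed=3)
        assert cop.regime == ("top_down" if cop.packing_based > 0.5 else "bottom_up")
        assert cop.f == pytest.approx(reference_cavity.f)


class TestToyModel:
    def test_interior_matches_ode(self):
        R, N, X = mt.toy_model_steady_state(**S1_TOY)
        assert (R, N, X) == pytest.approx(tuple(integrate_toy(S1_TOY)), abs=1e-8)
        assert min(R, N, X) > 0

    def test_predator_death_limit_drops_top_level(self):
        tp = dict(S1_TOY, u1=1e9)
        R, N, X = mt.toy_model_steady_state(**tp)
        assert X == 0.0
        # surviving pair solves the two-level subsystem
        assert tp["k1"] - tp["D_R"] * R - tp["c11"] * N == pytest.approx(0, abs=1e-10)
        assert tp["eta_N"] * tp["c11"] * R - tp["m1"] - tp["D_N"] * N == pytest.approx(
            0, abs=1e-10
        )

    def test_no_consumption_leaves_logistic_plants(self):
        tp = dict(S1_TOY, c11=0.0)
        assert mt.toy_model_steady_state(**tp) == (5.0, 0.0, 0.0)

    @pytest.mark.parametrize("u1", [0.3, 1.0, 2.0, 4.0, 8.0, 20.0])
    def test_boundary_switches_track_ode(self, u1):
        tp = dict(S1_TOY, u1=u1)
        got = mt.toy_model_steady_state(**tp)
        want = integrate_toy(tp)
        assert got == pytest.approx(tuple(want), abs=1e-6)
        # returned state is a fixed point
        assert np.max(np.abs(toy_rhs(0.0, got, tp))) < 1e-8

    def test_toy_bottom_up_regime_derivative_fraction(self):
        # with the top level extinct, d N*/du = 0 exactly and control is pure
        # bottom-up; exact toy solutions serve as the oracle
        tp = dict(S1_TOY, u1=12.0)
        h = 1e-5
        dk = (mt.toy_model_steady_state(**dict(tp, k1=tp["k1"] + h))[1]
              - mt.toy_model_steady_state(**dict(tp, k1=tp["k1"] - h))[1]) / (2 * h)
        du = (mt.toy_model_steady_state(**dict(tp, u1=tp["u1"] + h))[1]
              - mt.toy_model_steady_state(**dict(tp, u1=tp["u1"] - h))[1]) / (2 * h)
        frac = abs(dk) / (abs(dk) + abs(du))
        assert frac > 0.999


class TestScans:
    def test_single_point_grid_equals_direct_solve(self, reference_params):
        df = mt.phase_scan(reference_params, {"k": [4.0]}, seed=2)
        st = mt.solve(reference_params, seed=2)
        assert df.shape[0] == 1 and df.loc[0, "status"] == "ok"
        assert df.loc[0, "mean_N"] == pytest.approx(st.mean_N, rel=1e-6)
        assert df.loc[0, "packing_order_parameter"] == pytest.approx(
            mt.packing_order_parameter(st), rel=1e-6
        )

    def test_scan_is_deterministic(self, reference_params):
        grid = {"k": [3.0, 4.0], "u": [1.0, 1.5]}
        a = mt.phase_scan(reference_params, grid, seed=5)
        b = mt.phase_scan(reference_params, grid, seed=5)
        assert a.equals(b)

    def test_unknown_scan_parameter_rejected(self, reference_params):
        with pytest.raises(ValueError, match="cannot scan"):
            mt.phase_scan(reference_params, {"M_X": [10, 20]})


def test_finite_size_cavity_columns_constant(reference_params):
    p = reference_params.with_ratios(0.9, 0.9)
    cfg = mt.IntegrationConfig()
    df = mt.finite_size_deviation(p, [8, 16], n_systems=4, config=cfg, seed=5)
    assert df["cavity_mean_N"].nunique() == 1
    assert df["cavity_phi_X"].nunique() == 1
    assert np.all(df["mean_squared_deviation"] > 0)
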