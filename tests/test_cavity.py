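"""The three-level cavity solver: effective parameters, susceptibilities, roots."""

import numpy as np
import pytest

import multitrophic as mt
from multitrophic.cavity import (
    effective_parameters,
    residuals,
    susceptibilities_from_deltas,
)
from multitrophic.errors import InfeasiblePackingError
from multitrophic.truncated_gaussian import w


def effective_parameters_oracle(moments, sus, p):
    """Independent re-derivation of the effective parameters (test oracle)."""
    mX, mN, mR, qX, qN, qR = moments
    chi, nu, kappa = sus
    g = (
        -p.u + p.eta_X * p.mu_d * mN,
        -p.m - p.r1 * p.mu_d * mX + p.eta_N * p.mu_c * mR,
        p.k - p.mu_c * p.r2 * mN,
    )
    sig = (
        np.sqrt(p.eta_X**2 * p.sigma_d**2 * qN + p.sigma_u**2),
        np.sqrt(p.eta_N**2 * p.sigma_c**2 * qR + p.sigma_d**2 * p.r1 * qX + p.sigma_m**2),
        np.sqrt(p.sigma_K**2 + p.sigma_c**2 * p.r2 * qN),
    )
    D = (
        -p.eta_X * p.sigma_d**2 * nu,
        p.eta_N * p.sigma_c**2 * kappa - p.eta_X * p.r1 * p.sigma_d**2 * chi,
        1.0 - p.eta_N * p.r2 * p.sigma_c**2 * nu,
    )
    return g, sig, D


def test_empty_ecosystem_limit():
    p = mt.ModelParams3()
    g, sig, D = effective_parameters(np.zeros(6), np.zeros(3), p)
    assert g == pytest.approx((-p.u, -p.m, p.k))
    assert sig == pytest.approx((p.sigma_u, p.sigma_m, p.sigma_K))
    assert D[0] == 0.0 and D[1] == 0.0 and D[2] == 1.0


def test_decoupled_top_level():
    p = mt.ModelParams3(eta_X=0.0)
    moments = np.array([0.3, 0.5, 2.0, 0.2, 0.6, 5.0])
    g, sig, D = effective_parameters(moments, (-0.5, -0.3, 0.8), p)
    assert D[0] == 0.0
    assert sig[0] == pytest.approx(p.sigma_u)


def test_effective_parameters_match_independent_recoding():
    rng = np.random.default_rng(8)
    p = mt.ModelParams3(k=3.1, u=1.4, m=0.8, eta_N=0.55, eta_X=0.85,
                        sigma_c=0.45, sigma_d=0.65)
    for _ in range(10):
        moments = rng.uniform(0.0, 5.0, 6)
        sus = (-rng.uniform(0, 2), -rng.uniform(0, 2), rng.uniform(0, 2))
        got = effective_parameters(moments, sus, p)
        want = effective_parameters_oracle(moments, sus, p)
        for a, b in zip(got, want):
            assert a == pytest.approx(b, abs=1e-14)


class TestSusceptibilities:
    def test_signs_in_physical_region(self):
        p = mt.ModelParams3()
        chi, nu, kappa = susceptibilities_from_deltas((-0.5, 0.2, 3.0), p)
        assert chi < 0 and nu < 0 and kappa > 0

    def test_matches_survivor_count_form(self):
        # identical values when re-expressed through M_L* = w0 * M_L
        p = mt.ModelParams3()
        deltas = (-0.4, 0.1, 2.5)
        chi, nu, kappa = susceptibilities_from_deltas(deltas, p)
        M = np.array([p.M_X, p.M_N, p.M_R])
        Ms = np.array([w(0, d) for d in deltas]) * M
        MXs, MNs, MRs = Ms
        chi2 = (
            -(p.eta_N * p.sigma_c**2) / (p.eta_X * p.sigma_d**2)
            * (MXs / p.M_X) * (p.M_N / p.M_R)
            * (MRs - MNs + MXs) / (MNs - MXs)
        )
        nu2 = -(p.M_R / (p.eta_N * p.M_N * p.sigma_c**2)) * (MNs - MXs) / (MRs - MNs + MXs)
        kappa2 = (MRs - MNs + MXs) / p.M_R
        assert chi == pytest.approx(chi2, abs=1e-12)
        assert nu == pytest.approx(nu2, abs=1e-12)
        assert kappa == pytest.approx(kappa2, abs=1e-12)

    def test_kappa_matches_packing_form(self):
        # kappa = phi_R / (1 + 1/f) with f built from the survival fractions
        p = mt.ModelParams3()
        deltas = (-0.6, 0.3, 2.0)
        _, _, kappa = susceptibilities_from_deltas(deltas, p)
        phis = [w(0, d) for d in deltas]
        f = (phis[2] - p.r2 * phis[1] + p.r1 * p.r2 * phis[0]) / (
            p.r2 * (phis[1] - p.r1 * phis[0])
        )
        assert kappa == pytest.approx(phis[2] / (1 + 1 / f), abs=1e-12)

    def test_vanishing_top_level_limit(self):
        # phi_X -> 0 (top level fully extinct): chi -> 0 from below
        p = mt.ModelParams3()
        chi, _, _ = susceptibilities_from_deltas((-40.0, 0.5, 3.0), p)
        assert chi <= 0 and abs(chi) < 1e-300

    def test_infeasible_region_raises_named_inequality(self):
        p = mt.ModelParams3().with_ratios(r1=5.0)
        with pytest.raises(InfeasiblePackingError, match="top level"):
            susceptibilities_from_deltas((2.0, -2.0, 2.0), p)


class TestResiduals:
    def test_zero_at_solution_and_sensitive_to_perturbation(self, reference_cavity):
        st = reference_cavity
        res = residuals(st.moments, st.params)
        assert np.linalg.norm(res) < 1e-10
        for i in range(6):
            x = st.moments.copy()
            x[i] *= 1.1
            assert abs(residuals(x, st.params)[i]) > 1e-3

    def test_simulation_moments_are_a_good_warm_start(self, reference_params,
                                                      reference_cavity):
        # pooled moments of a ~200-species-per-level simulation approximate the
        # fixed point and initialize the solver inside the physical basin
        p = reference_params.with_sizes(180, 202, 223)
        cfg = mt.IntegrationConfig(max_extensions=8)
        stats = mt.ensemble_statistics(p, 2, cfg, seed=9)
        po = stats.pooled
        x = np.array([po.mean_X, po.mean_N, po.mean_R,
                      po.second_moment_X, po.second_moment_N, po.second_moment_R])
        assert np.all(np.abs(x / reference_cavity.moments - 1) < 0.15)
        st = mt.solve(reference_params, init=x, seed=2)
        assert np.allclose(st.moments, reference_cavity.moments, rtol=1e-5)


class TestSolve:
    def test_fixed_point_structure(self, reference_cavity):
        st = reference_cavity
        assert st.residual_norm < 1e-6
        assert st.mean_X == pytest.approx(
            st.sigma_g_X / st.D_eff_X * w(1, st.delta_X), rel=1e-6
        )
        assert st.q_R == pytest.approx(
            (st.sigma_g_R / st.D_eff_R) ** 2 * w(2, st.delta_R), rel=1e-6
        )
        for lvl in "XNR":
            assert getattr(st, f"phi_{lvl}") == pytest.approx(
                w(0, getattr(st, f"delta_{lvl}")), abs=1e-12
            )

    def test_sign_conventions(self, reference_cavity):
        st = reference_cavity
        assert st.chi < 0 and st.nu < 0 and st.kappa > 0
        assert st.D_eff_X > 0 and st.D_eff_N > 0 and st.D_eff_R >= 1.0

    def test_unique_physical_branch_across_starts(self, reference_params):
        a = mt.solve(reference_params, seed=1)
        b = mt.solve(reference_params, seed=77)
        c = mt.solve(reference_params, init="multistart_random", seed=5)
        assert np.allclose(a.moments, b.moments, rtol=1e-5)
        assert np.allclose(a.moments, c.moments, rtol=1e-5)

    def test_exclusion_bounds_on_survival_fractions(self, random_cavity_states):
        for st in random_cavity_states:
            p = st.params
            assert p.r1 * st.phi_X <= st.phi_N + 1e-12
            assert p.r2 * st.phi_N <= st.phi_R + p.r1 * p.r2 * st.phi_X + 1e-12

    def test_zero_diversity_rejected(self):
        with pytest.raises(ValueError):
            mt.solve(mt.ModelParams3(sigma_c=0.0), seed=0)


def test_packing_identity_at_solutions(random_cavity_states):
    # D_N_top / (D_N_top + D_N_bottom) == r1 phi_X / phi_N at every solution
    for st in random_cavity_states:
        lhs = st.D_N_top / (st.D_N_top + st.D_N_bottom)
        assert lhs == pytest.approx(st.params.r1 * st.phi_X / st.phi_N, abs=1e-10)
        assert st.D_N_top + st.D_N_bottom == pytest.approx(st.D_eff_N, rel=1e-12)
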