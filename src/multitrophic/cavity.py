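"""Zero-temperature cavity solution of the three-level model.

In the large-pool limit (M_X, M_N, M_R -> infinity at fixed ratios
r1 = M_X/M_N, r2 = M_N/M_R) a typical species at each level has a rectified
Gaussian steady-state abundance

    B = max(0, (g_eff + sigma_g_eff * z) / D_eff),   z ~ N(0, 1),

with level-specific effective growth rates g_eff, growth-rate spreads
sigma_g_eff, and emergent competition coefficients D_eff.  The effective
parameters are functions of six pooled moments (the level means and second
moments of abundance, averaged over the full pool including extinct species)
and of three level-averaged susceptibilities

    chi = <dX/du>,  nu = <dN/dm>,  kappa = <dR/dK>,

which the theory lets us eliminate in closed form in terms of the survival
fractions phi_L = w0(Delta_L).  The result is a closed system of six
self-consistency equations in the six moments; this module evaluates its
residuals and solves it as a positivity-constrained nonlinear least-squares
problem (optimized in log-space so iterates stay positive).

Sign conventions: chi <= 0 and nu <= 0 (raising a death rate lowers
abundance), kappa >= 0; all three D_eff are positive at a physical solution
and D_eff_R >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .ensemble import ModelParams3
from .errors import ConvergenceError, InfeasiblePackingError
from .simulator import IntegrationConfig, ensemble_statistics
from .truncated_gaussian import w

__all__ = [
    "CavityState",
    "effective_parameters",
    "susceptibilities_from_deltas",
    "residuals",
    "solve",
]

_MOMENT_NAMES = ("mean_X", "mean_N", "mean_R", "q_X", "q_N", "q_R")


@dataclass(frozen=True)
class CavityState:
    """Solved cavity state: six moments plus every derived effective quantity."""

    mean_X: float
    mean_N: float
    mean_R: float
    q_X: float
    q_N: float
    q_R: float
    chi: float
    nu: float
    kappa: float
    g_eff_X: float
    g_eff_N: float
    g_eff_R: float
    sigma_g_X: float
    sigma_g_N: float
    sigma_g_R: float
    D_eff_X: float
    D_eff_N: float
    D_eff_R: float
    delta_X: float
    delta_N: float
    delta_R: float
    phi_X: float
    phi_N: float
    phi_R: float
    residual_norm: float
    params: ModelParams3 = field(repr=False, default=None)

    @property
    def moments(self) -> np.ndarray:
        return np.array(
            [self.mean_X, self.mean_N, self.mean_R, self.q_X, self.q_N, self.q_R]
        )

    @property
    def f(self) -> float:
        """Unfilled-niche ratio (middle over top level) from survival fractions."""
        p = self.params
        num = self.phi_R - p.r2 * self.phi_N + p.r1 * p.r2 * self.phi_X
        den = p.r2 * (self.phi_N - p.r1 * self.phi_X)
        return num / den

    @property
    def D_N_top(self) -> float:
        """Top-level (predation feedback) share of D_eff_N; positive."""
        p = self.params
        return -p.eta_X * p.r1 * p.sigma_d**2 * self.chi

    @property
    def D_N_bottom(self) -> float:
        """Bottom-level (resource feedback) share of D_eff_N; positive."""
        p = self.params
        return p.eta_N * p.sigma_c**2 * self.kappa

    def expected_counts(self) -> tuple[float, float, float]:
        """Expected surviving-species counts (phi_L * M_L), unrounded.

        Pool sizes are taken consistently with the ratios the state was solved
        at: M_R anchors the scale and M_N = r2*M_R, M_X = r1*M_N, so exact
        ratio overrides do not break packing identities.
        """
        p = self.params
        M_R = p.M_R
        M_N = p.r2 * M_R
        M_X = p.r1 * M_N
        return (self.phi_X * M_X, self.phi_N * M_N, self.phi_R * M_R)


def effective_parameters(moments, susceptibilities, params: ModelParams3):
    """Effective growth rates, spreads and competition coefficients.

    Parameters
    ----------
    moments : sequence of 6 floats
        (mean_X, mean_N, mean_R, q_X, q_N, q_R), second moments over the full
        pool.
    susceptibilities : sequence of 3 floats
        (chi, nu, kappa).
    params : ModelParams3

    Returns
    -------
    (g_effs, sigma_gs, D_effs) : three tuples ordered (X, N, R)
    """
    mean_X, mean_N, mean_R, q_X, q_N, q_R = moments
    chi, nu, kappa = susceptibilities
    p = params
    g_X = -p.u + p.eta_X * p.mu_d * mean_N
    g_N = -p.m - p.r1 * p.mu_d * mean_X + p.eta_N * p.mu_c * mean_R
    g_R = p.k - p.mu_c * p.r2 * mean_N
    sig_X = np.sqrt(p.eta_X**2 * p.sigma_d**2 * q_N + p.sigma_u**2)
    sig_N = np.sqrt(
        p.eta_N**2 * p.sigma_c**2 * q_R + p.sigma_d**2 * p.r1 * q_X + p.sigma_m**2
    )
    sig_R = np.sqrt(p.sigma_K**2 + p.sigma_c**2 * p.r2 * q_N)
    D_X = -p.eta_X * p.sigma_d**2 * nu
    D_N = p.eta_N * p.sigma_c**2 * kappa - p.eta_X * p.r1 * p.sigma_d**2 * chi
    D_R = 1.0 - p.eta_N * p.r2 * p.sigma_c**2 * nu
    return (g_X, g_N, g_R), (sig_X, sig_N, sig_R), (D_X, D_N, D_R)


def _packing_denominators(deltas, params: ModelParams3):
    w0_X, w0_N, w0_R = (w(0, d) for d in deltas)
    den_top = w0_N - params.r1 * w0_X
    den_mid = w0_R - params.r2 * w0_N + params.r1 * params.r2 * w0_X
    return (w0_X, w0_N, w0_R), den_top, den_mid


def susceptibilities_from_deltas(deltas, params: ModelParams3):
    """Closed-form (chi, nu, kappa) from the three rescaled growth rates.

    Valid only in the physical packing region
    ``w0(delta_N) - r1*w0(delta_X) > 0`` and
    ``w0(delta_R) - r2*w0(delta_N) + r1*r2*w0(delta_X) > 0``
    (the survival-fraction versions of the competitive-exclusion bounds);
    outside it raises :class:`InfeasiblePackingError`.
    """
    p = params
    (w0_X, _, _), den_top, den_mid = _packing_denominators(deltas, p)
    if den_top <= 0:
        raise InfeasiblePackingError(
            "exclusion bound violated at top level: "
            f"w0(delta_N) - r1*w0(delta_X) = {den_top:.3e} <= 0"
        )
    if den_mid <= 0:
        raise InfeasiblePackingError(
            "exclusion bound violated at middle level: "
            f"w0(delta_R) - r2*w0(delta_N) + r1*r2*w0(delta_X) = {den_mid:.3e} <= 0"
        )
    chi = -(p.eta_N * p.sigma_c**2) / (p.eta_X * p.sigma_d**2) * w0_X * den_mid / den_top
    nu = -den_top / (p.eta_N * p.sigma_c**2 * den_mid)
    kappa = den_mid
    return chi, nu, kappa


def _residuals_core(x, params: ModelParams3, penalize: bool):
    """Scaled self-consistency residuals at a (positive) moment vector.

    With ``penalize`` the exclusion denominators are floored at a tiny value
    and a large additive penalty proportional to the violation is returned
    instead of raising, which keeps the optimizer's objective finite and
    sloped back toward the physical region.
    """
    p = params
    g, sig, _ = effective_parameters(x, (0.0, 0.0, 0.0), p)
    deltas = tuple(gi / si for gi, si in zip(g, sig))
    penalty = 0.0
    if penalize:
        _, den_top, den_mid = _packing_denominators(deltas, p)
        if den_top <= 0 or den_mid <= 0:
            penalty = 1e3 * (1.0 + max(0.0, -den_top) + max(0.0, -den_mid))
            eps = 1e-10
            w0_X = w(0, deltas[0])
            den_top = max(den_top, eps)
            den_mid = max(den_mid, eps)
            chi = (
                -(p.eta_N * p.sigma_c**2)
                / (p.eta_X * p.sigma_d**2)
                * w0_X
                * den_mid
                / den_top
            )
            nu = -den_top / (p.eta_N * p.sigma_c**2 * den_mid)
            kappa = den_mid
            sus = (chi, nu, kappa)
        else:
            sus = susceptibilities_from_deltas(deltas, p)
    else:
        sus = susceptibilities_from_deltas(deltas, p)
    _, _, D = effective_parameters(x, sus, p)
    res = np.empty(6)
    for i in range(3):
        ratio = sig[i] / D[i]
        t_mean = ratio * w(1, deltas[i])
        t_q = ratio**2 * w(2, deltas[i])
        res[i] = (x[i] - t_mean) / max(1.0, abs(t_mean))
        res[3 + i] = (x[3 + i] - t_q) / max(1.0, abs(t_q))
    return res + penalty


def residuals(unknowns, params: ModelParams3):
    """Scaled residuals of the six self-consistency equations.

    ``unknowns`` is (mean_X, mean_N, mean_R, q_X, q_N, q_R), all nonnegative.
    Each residual is the gap between the input moment and its truncated-
    Gaussian prediction, divided by max(1, |prediction|) so that means and
    (much larger) second moments carry comparable weight.  Raises
    :class:`InfeasiblePackingError` outside the physical packing region.
    """
    x = np.asarray(unknowns, dtype=float)
    if x.shape != (6,):
        raise ValueError("unknowns must be a 6-vector")
    if np.any(x < 0):
        raise ValueError("moments must be nonnegative")
    return _residuals_core(x, params, penalize=False)


def _warm_start_from_simulation(params: ModelParams3, seed: int, size: int = 10):
    """Pooled moments of one small simulated system (the warm-start trick).

    A community of ~``size`` species per level is a rough but cheap
    approximation of the thermodynamic-limit statistics; its pooled moments
    bracket a good initialization range.
    """
    M_X = size
    M_N = max(1, round(M_X / params.r1))
    M_R = max(1, round(M_N / params.r2))
    small = params.with_sizes(M_X, M_N, M_R)
    cfg = IntegrationConfig(t_final=200.0, steady_state_residual_tol=1e-4)
    stats = ensemble_statistics(small, n_systems=2, config=cfg, seed=seed)
    v = stats.pooled
    x = np.array(
        [v.mean_X, v.mean_N, v.mean_R,
         v.second_moment_X, v.second_moment_N, v.second_moment_R]
    )
    return np.maximum(x, 1e-3)


def _state_from_moments(x, params: ModelParams3, residual_norm: float) -> CavityState:
    g, sig, _ = effective_parameters(x, (0.0, 0.0, 0.0), params)
    deltas = tuple(gi / si for gi, si in zip(g, sig))
    sus = susceptibilities_from_deltas(deltas, params)
    _, _, D = effective_parameters(x, sus, params)
    phis = tuple(w(0, d) for d in deltas)
    return CavityState(
        mean_X=float(x[0]), mean_N=float(x[1]), mean_R=float(x[2]),
        q_X=float(x[3]), q_N=float(x[4]), q_R=float(x[5]),
        chi=float(sus[0]), nu=float(sus[1]), kappa=float(sus[2]),
        g_eff_X=float(g[0]), g_eff_N=float(g[1]), g_eff_R=float(g[2]),
        sigma_g_X=float(sig[0]), sigma_g_N=float(sig[1]), sigma_g_R=float(sig[2]),
        D_eff_X=float(D[0]), D_eff_N=float(D[1]), D_eff_R=float(D[2]),
        delta_X=float(deltas[0]), delta_N=float(deltas[1]), delta_R=float(deltas[2]),
        phi_X=float(phis[0]), phi_N=float(phis[1]), phi_R=float(phis[2]),
        residual_norm=float(residual_norm),
        params=params,
    )


def solve(
    params: ModelParams3,
    init="warm_start_simulation",
    seed: int = 0,
    n_starts: int = 12,
    accept_tol: float = 1e-6,
    max_nfev: int = 2000,
) -> CavityState:
    """Solve the six cavity self-consistency equations.

    The root-finding problem is recast as minimizing the sum of squared
    scaled residuals over strictly positive moments; positivity is enforced
    by optimizing in log-space.  A solution is accepted when the residual
    norm drops below ``accept_tol``.

    Parameters
    ----------
    init : "warm_start_simulation" | "multistart_random" | array_like
        Initialization strategy.  The default simulates a tiny (10 species
        per level) community and samples starts between half and the full
        value of each pooled statistic; ``"multistart_random"`` samples
        starts log-uniformly in [0.05, 5]; an explicit 6-vector is used the
        same way as the warm-start statistics (starts in [v/2, v]).
    seed : int
        Seeds both the warm-start simulation and start sampling.

    Raises
    ------
    ConvergenceError
        If no start reaches ``accept_tol``; carries the best residual norm.
    """
    if params.sigma_c <= 0 or params.sigma_d <= 0:
        raise ValueError(
            "the cavity solution requires sigma_c > 0 and sigma_d > 0 "
            "(zero trait diversity makes the mean-field closure degenerate)"
        )
    rng = np.random.default_rng(seed)

    if isinstance(init, str) and init == "warm_start_simulation":
        anchor = _warm_start_from_simulation(params, seed=int(rng.integers(2**31)))
        sample_start = lambda: rng.uniform(0.5, 1.0, size=6) * anchor
    elif isinstance(init, str) and init == "multistart_random":
        sample_start = lambda: np.exp(rng.uniform(np.log(0.05), np.log(5.0), size=6))
    elif isinstance(init, str):
        raise ValueError(f"unknown init strategy {init!r}")
    else:
        anchor = np.maximum(np.asarray(init, dtype=float), 1e-8)
        if anchor.shape != (6,):
            raise ValueError("explicit init must be a 6-vector of moments")
        sample_start = lambda: rng.uniform(0.5, 1.0, size=6) * anchor

    def fun(y):
        # cap the log-moments so stray optimizer steps cannot overflow exp
        return _residuals_core(np.exp(np.clip(y, -60.0, 60.0)), params, penalize=True)

    best_norm = np.inf
    best_x = None
    for start_idx in range(n_starts):
        x0 = sample_start()
        try:
            sol = least_squares(
                fun, np.log(x0), method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=max_nfev,
            )
        except (FloatingPointError, OverflowError):  # pragma: no cover
            continue
        x = np.exp(sol.x)
        try:
            norm = float(np.linalg.norm(residuals(x, params)))
        except InfeasiblePackingError:
            continue
        if norm < best_norm:
            best_norm, best_x = norm, x
        if norm < accept_tol:
            return _state_from_moments(x, params, norm)
    raise ConvergenceError(
        f"cavity solver failed: best residual norm {best_norm:.3e} "
        f"after {n_starts} starts (accept_tol={accept_tol:.1e})",
        best_residual=best_norm,
        best_start=best_x,
    )
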