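"""ODE integration of three-level communities to steady state.

The dynamics are generalized Lotka-Volterra with a trophic ladder structure:

    dX_a/dt = X_a * (eta_X * sum_j d_aj N_j - u_a)
    dN_i/dt = N_i * (eta_N * sum_Q c_iQ R_Q - m_i - sum_b d_bi X_b)
    dR_P/dt = R_P * (K_P - R_P - sum_j c_jP N_j)

With symmetric (reciprocal) interactions these dynamics converge to a unique
globally stable fixed point from any positive initial condition, so
"integrate long enough and check the per-capita residual" is a sound
steady-state detector.  Species whose final abundance falls below an explicit
extinction threshold are counted extinct and set to exactly zero at readout.

Pooled moments are taken over the FULL species pool including extinct species
as zeros, matching the averages the cavity theory is written in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .ensemble import CommunityInstance, ModelParams3, child_seeds, sample_community
from .errors import EmptyStatisticsError, IntegrationError

__all__ = [
    "IntegrationConfig",
    "SteadyStateSummary",
    "EnsembleStatistics",
    "rhs",
    "integrate_to_steady_state",
    "ensemble_statistics",
]


@dataclass(frozen=True)
class IntegrationConfig:
    """Settings for steady-state integration.

    ``t_final`` is one integration chunk; if the per-capita residual test
    fails the horizon is extended (doubling chunks) up to ``max_extensions``
    times before the run is flagged non-converged.  Initial abundances are
    uniform on [init_low, init_high].  The extinction threshold is applied at
    readout only, never during integration.
    """

    t_final: float = 200.0
    max_step: float = np.inf
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    extinction_threshold: float = 1e-6
    init_low: float = 1.0
    init_high: float = 2.0
    steady_state_residual_tol: float = 1e-5
    max_extensions: int = 6
    method: str = "LSODA"

    def __post_init__(self):
        if self.t_final <= 0:
            raise ValueError("t_final must be > 0")
        if not 0 < self.init_low < self.init_high:
            raise ValueError("need 0 < init_low < init_high")
        if self.extinction_threshold <= 0:
            raise ValueError("extinction_threshold must be > 0")


@dataclass(frozen=True)
class SteadyStateSummary:
    """Steady-state readout for one community."""

    X_star: np.ndarray
    N_star: np.ndarray
    R_star: np.ndarray
    survivors_X: int
    survivors_N: int
    survivors_R: int
    mean_X: float
    mean_N: float
    mean_R: float
    second_moment_X: float
    second_moment_N: float
    second_moment_R: float
    converged: bool
    residual: float
    t_end: float

    @property
    def survival_fractions(self) -> tuple[float, float, float]:
        """(phi_X, phi_N, phi_R) = survivors / pool size."""
        return (
            self.survivors_X / max(len(self.X_star), 1),
            self.survivors_N / max(len(self.N_star), 1),
            self.survivors_R / max(len(self.R_star), 1),
        )


@dataclass(frozen=True)
class EnsembleStatistics:
    """Pooled steady-state statistics over an ensemble of communities."""

    pooled: SteadyStateSummary  # abundances concatenated over systems
    per_system: tuple
    n_converged: int
    n_systems: int
    abundances_X: np.ndarray  # pooled, incl. zeros, for histograms
    abundances_N: np.ndarray
    abundances_R: np.ndarray

    def standard_errors(self):
        """SEs (over systems) of the per-system level means and survival fractions.

        Returns a dict with keys mean_X/N/R and phi_X/N/R.
        """
        conv = [s for s in self.per_system if s.converged]
        n = max(len(conv), 1)
        out = {}
        for lvl in "XNR":
            means = np.array([getattr(s, f"mean_{lvl}") for s in conv])
            phis = np.array(
                [s.survival_fractions["XNR".index(lvl)] for s in conv]
            )
            out[f"mean_{lvl}"] = float(means.std(ddof=1) / np.sqrt(n)) if n > 1 else np.inf
            out[f"phi_{lvl}"] = float(phis.std(ddof=1) / np.sqrt(n)) if n > 1 else np.inf
            out[f"q_{lvl}"] = (
                float(
                    np.array([getattr(s, f"second_moment_{lvl}") for s in conv]).std(ddof=1)
                    / np.sqrt(n)
                )
                if n > 1
                else np.inf
            )
        return out


def _split(state: np.ndarray, sizes) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    M_X, M_N, M_R = sizes
    return state[:M_X], state[M_X : M_X + M_N], state[M_X + M_N :]


def per_capita_rates(state, instance: CommunityInstance, params: ModelParams3):
    """Per-capita growth rates (g such that dB/dt = B*g) at a state.

    The state is clipped at zero before evaluating interactions, so tiny
    negative excursions from the integrator cannot feed back into the
    dynamics.
    """
    sizes = instance.sizes
    if state.shape != (sum(sizes),):
        raise ValueError(
            f"state has shape {state.shape}, expected ({sum(sizes)},) "
            f"for sizes M_X={sizes[0]}, M_N={sizes[1]}, M_R={sizes[2]}"
        )
    s = np.maximum(state, 0.0)
    X, N, R = _split(s, sizes)
    gX = params.eta_X * (instance.d @ N) - instance.u_vec
    gN = params.eta_N * (instance.c @ R) - instance.m_vec - instance.d.T @ X
    gR = instance.K - R - instance.c.T @ N
    return np.concatenate([gX, gN, gR])


def rhs(state, instance: CommunityInstance, params: ModelParams3):
    """Right-hand side of the three-level dynamics; zero abundance => zero rate."""
    s = np.maximum(np.asarray(state, dtype=float), 0.0)
    return s * per_capita_rates(s, instance, params)


def integrate_to_steady_state(
    instance: CommunityInstance,
    params: ModelParams3,
    config: IntegrationConfig | None = None,
    seed: int = 0,
    init_state: np.ndarray | None = None,
) -> SteadyStateSummary:
    """Integrate one community until the per-capita residual test passes.

    ``converged`` is True iff, at the final time, every species with
    abundance above the extinction threshold has |per-capita growth rate|
    below ``steady_state_residual_tol``.  Non-convergence is reported in the
    flag, not raised; integrator failures raise :class:`IntegrationError`.
    """
    config = config or IntegrationConfig()
    sizes = instance.sizes
    n = sum(sizes)
    if init_state is None:
        rng = np.random.default_rng(seed)
        y = rng.uniform(config.init_low, config.init_high, size=n)
    else:
        y = np.asarray(init_state, dtype=float).copy()
        if y.shape != (n,):
            raise ValueError(f"init_state must have shape ({n},)")

    def fun(t, state):
        return rhs(state, instance, params)

    t_end = 0.0
    converged = False
    residual = np.inf
    horizon = config.t_final
    for _ in range(config.max_extensions + 1):
        sol = solve_ivp(
            fun,
            (t_end, t_end + horizon),
            y,
            method=config.method,
            rtol=config.rel_tol,
            atol=config.abs_tol,
            max_step=config.max_step,
        )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise IntegrationError(
                f"integrator failed at t={sol.t[-1]:.3g}: {sol.message}",
                partial_state=sol.y[:, -1] if sol.y.size else None,
            )
        y = sol.y[:, -1]
        t_end = sol.t[-1]
        alive = np.maximum(y, 0.0) >= config.extinction_threshold
        g = per_capita_rates(y, instance, params)
        residual = float(np.max(np.abs(g[alive]))) if alive.any() else 0.0
        if residual < config.steady_state_residual_tol:
            converged = True
            break
        horizon *= 2.0

    final = np.maximum(y, 0.0)
    final[final < config.extinction_threshold] = 0.0
    X, N, R = _split(final, sizes)

    def _mean(a, power=1):
        return float((a**power).mean()) if a.size else 0.0

    return SteadyStateSummary(
        X_star=X,
        N_star=N,
        R_star=R,
        survivors_X=int(np.count_nonzero(X)),
        survivors_N=int(np.count_nonzero(N)),
        survivors_R=int(np.count_nonzero(R)),
        mean_X=_mean(X),
        mean_N=_mean(N),
        mean_R=_mean(R),
        second_moment_X=_mean(X, 2),
        second_moment_N=_mean(N, 2),
        second_moment_R=_mean(R, 2),
        converged=converged,
        residual=residual,
        t_end=float(t_end),
    )


def ensemble_statistics(
    params: ModelParams3,
    n_systems: int,
    config: IntegrationConfig | None = None,
    seed: int = 0,
) -> EnsembleStatistics:
    """Integrate an ensemble and pool steady-state statistics.

    Pooled moments average over all species of all converged systems
    (extinct species contribute zeros).  Raises
    :class:`EmptyStatisticsError` if no system converged.
    """
    config = config or IntegrationConfig()
    seeds = child_seeds(seed, 2 * n_systems).reshape(n_systems, 2)
    summaries = []
    for sample_seed, init_seed in seeds:
        inst = sample_community(params, int(sample_seed))
        summaries.append(
            integrate_to_steady_state(inst, params, config, seed=int(init_seed))
        )
    converged = [s for s in summaries if s.converged]
    if not converged:
        raise EmptyStatisticsError(
            f"none of the {n_systems} systems reached steady state"
        )
    Xs = np.concatenate([s.X_star for s in converged])
    Ns = np.concatenate([s.N_star for s in converged])
    Rs = np.concatenate([s.R_star for s in converged])
    pooled = SteadyStateSummary(
        X_star=Xs,
        N_star=Ns,
        R_star=Rs,
        survivors_X=int(np.count_nonzero(Xs)),
        survivors_N=int(np.count_nonzero(Ns)),
        survivors_R=int(np.count_nonzero(Rs)),
        mean_X=float(Xs.mean()),
        mean_N=float(Ns.mean()),
        mean_R=float(Rs.mean()),
        second_moment_X=float((Xs**2).mean()),
        second_moment_N=float((Ns**2).mean()),
        second_moment_R=float((Rs**2).mean()),
        converged=len(converged) == n_systems,
        residual=float(max(s.residual for s in converged)),
        t_end=float(max(s.t_end for s in converged)),
    )
    return EnsembleStatistics(
        pooled=pooled,
        per_system=tuple(summaries),
        n_converged=len(converged),
        n_systems=n_systems,
        abundances_X=Xs,
        abundances_N=Ns,
        abundances_R=Rs,
    )
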