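"""Cavity solver and simulator for food chains with an arbitrary number of levels.

Levels are indexed 0 (bottom, primary producers) through L-1 (top).  Each
level i carries a bare intra-level competition coefficient D[i], a conversion
efficiency eta[i], growth/death-rate statistics (g_mean[i], g_sd[i]), and,
for i >= 1, a preference matrix A[i] (shape M[i] x M[i-1]) through which it
consumes level i-1.  Preference entries are i.i.d. with mean mu[i]/M[i-1]
and standard deviation sigma[i]/sqrt(M[i-1]) — the same prey-pool scaling as
the three-level model, to which this module reduces exactly when L = 3,
D = (1, 0, 0) and matched statistics are used.

Per-capita dynamics of species mu on level i:

    g[i]_mu - D[i]*B_mu + eta[i] * (A[i] @ B_{i-1})_mu - (A[i+1].T @ B_{i+1})_mu

with all out-of-range level quantities equal to zero.

The cavity closure gives each level a rectified-Gaussian abundance law and a
set of 3L self-consistency equations in the per-level means <B_i>, second
moments q_i and susceptibilities chi_i = <dB_i/dg_i>.  Note chi_i here is a
derivative with respect to the *growth* rate and is therefore nonnegative;
the three-level module differentiates with respect to death rates for its
top two levels, so the reduction maps chi_i -> (kappa, -nu, -chi).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy.integrate import solve_ivp

from .ensemble import ModelParams3
from .errors import (
    ConvergenceError,
    IntegrationError,
    UndefinedControlError,
    UndefinedLevelError,
)
from .truncated_gaussian import w

__all__ = [
    "NLevelParams",
    "NLevelCommunity",
    "NLevelState",
    "from_three_level",
    "sample_nlevel_community",
    "rhs_n",
    "integrate_nlevel",
    "residuals_n",
    "solve_n",
    "order_parameter_level",
]


@dataclass(frozen=True)
class NLevelParams:
    """Per-level statistics of a random L-level food chain.

    All tuples have length L (bottom level first).  ``mu[0]``, ``sigma[0]``
    and ``eta[0]`` are boundary placeholders and must be zero: the bottom
    level consumes nothing.
    """

    M: tuple
    g_mean: tuple
    g_sd: tuple
    D: tuple
    mu: tuple
    sigma: tuple
    eta: tuple

    def __post_init__(self):
        L = len(self.M)
        if L < 2:
            raise ValueError("need at least 2 levels")
        for name in ("g_mean", "g_sd", "D", "mu", "sigma", "eta"):
            if len(getattr(self, name)) != L:
                raise ValueError(f"{name} must have length {L}")
        # sizes may be non-integral: the cavity equations only see the ratios
        # M[i+1]/M[i]; sampling a finite community rounds them
        if any(m < 1 for m in self.M):
            raise ValueError("all level sizes must be >= 1")
        if self.mu[0] != 0 or self.sigma[0] != 0:
            raise ValueError("mu[0] and sigma[0] must be 0 (bottom level consumes nothing)")
        if any(s < 0 for s in self.sigma) or any(s < 0 for s in self.g_sd):
            raise ValueError("spreads must be >= 0")
        if any(not 0 <= e <= 1 for e in self.eta[1:]):
            raise ValueError("efficiencies must lie in [0, 1]")

    @property
    def n_levels(self) -> int:
        return len(self.M)

    def r_up(self, i: int) -> float:
        """Pool-size ratio M[i+1]/M[i]; zero above the top level."""
        return self.M[i + 1] / self.M[i] if i + 1 < self.n_levels else 0.0


def from_three_level(p3: ModelParams3) -> NLevelParams:
    """Embed a three-level parameter set as L = 3 chain parameters.

    Plants get bare self-competition D = 1 (their logistic term); consumers
    get D = 0.  Growth-rate means are (k, -m, -u): the sign flip encodes
    death rates as negative growth.  Level sizes are chosen to reproduce the
    *effective* ratios r1, r2 (which honor exact-ratio overrides), anchored at
    the plant pool size, so the reduction is exact even when the ratios are
    not integer-size quotients.
    """
    M_R = float(p3.M_R)
    M_N = p3.r2 * M_R
    M_X = p3.r1 * M_N
    return NLevelParams(
        M=(M_R, M_N, M_X),
        g_mean=(p3.k, -p3.m, -p3.u),
        g_sd=(p3.sigma_K, p3.sigma_m, p3.sigma_u),
        D=(1.0, 0.0, 0.0),
        mu=(0.0, p3.mu_c, p3.mu_d),
        sigma=(0.0, p3.sigma_c, p3.sigma_d),
        eta=(0.0, p3.eta_N, p3.eta_X),
    )


@dataclass(frozen=True)
class NLevelCommunity:
    """One sampled chain: preference matrices A (A[0] is None) and growth vectors."""

    A: tuple
    g: tuple
    seed: int = 0

    @property
    def sizes(self) -> tuple:
        return tuple(len(gi) for gi in self.g)


def sample_nlevel_community(params: NLevelParams, seed: int) -> NLevelCommunity:
    rng = np.random.default_rng(seed)
    L = params.n_levels
    sizes = [max(1, round(m)) for m in params.M]  # non-integral sizes round
    A = [None]
    for i in range(1, L):
        mean = params.mu[i] / sizes[i - 1]
        sd = params.sigma[i] / np.sqrt(sizes[i - 1])
        shape = (sizes[i], sizes[i - 1])
        A.append(rng.normal(mean, sd, size=shape) if sd > 0 else np.full(shape, mean))
    g = tuple(
        rng.normal(params.g_mean[i], params.g_sd[i], size=sizes[i])
        if params.g_sd[i] > 0
        else np.full(sizes[i], float(params.g_mean[i]))
        for i in range(L)
    )
    return NLevelCommunity(A=tuple(A), g=g, seed=int(seed))


def _split_levels(state, sizes):
    out, k = [], 0
    for m in sizes:
        out.append(state[k : k + m])
        k += m
    return out


def rhs_n(state, community: NLevelCommunity, params: NLevelParams):
    """Right-hand side of the L-level dynamics; zero abundance => zero rate."""
    sizes = community.sizes
    state = np.asarray(state, dtype=float)
    if state.shape != (sum(sizes),):
        raise ValueError(f"state must have shape ({sum(sizes)},), got {state.shape}")
    s = np.maximum(state, 0.0)
    B = _split_levels(s, sizes)
    L = params.n_levels
    rates = []
    for i in range(L):
        g = community.g[i] - params.D[i] * B[i]
        if i >= 1:
            g = g + params.eta[i] * (community.A[i] @ B[i - 1])
        if i + 1 < L:
            g = g - community.A[i + 1].T @ B[i + 1]
        rates.append(B[i] * g)
    return np.concatenate(rates)


def integrate_nlevel(
    community: NLevelCommunity,
    params: NLevelParams,
    seed: int = 0,
    t_final: float = 200.0,
    max_extensions: int = 6,
    residual_tol: float = 1e-5,
    extinction_threshold: float = 1e-6,
    init_range: tuple = (1.0, 2.0),
):
    """Integrate one chain to steady state; returns per-level pooled statistics.

    Returns a dict with per-level arrays ``mean``, ``q`` (second moment over
    the full pool), ``phi`` (survival fraction), the final abundances, and a
    ``converged`` flag based on the per-capita residual of surviving species.
    """
    sizes = community.sizes
    rng = np.random.default_rng(seed)
    y = rng.uniform(*init_range, size=sum(sizes))

    def fun(t, state):
        return rhs_n(state, community, params)

    def percap(state):
        s = np.maximum(state, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            full = rhs_n(s, community, params)
        g = np.where(s > 0, full / np.where(s > 0, s, 1.0), 0.0)
        return g

    t_end, horizon, converged, residual = 0.0, t_final, False, np.inf
    for _ in range(max_extensions + 1):
        sol = solve_ivp(fun, (t_end, t_end + horizon), y, method="LSODA",
                        rtol=1e-8, atol=1e-10)
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise IntegrationError(
                f"n-level integrator failed at t={sol.t[-1]:.3g}: {sol.message}",
                partial_state=sol.y[:, -1] if sol.y.size else None,
            )
        y, t_end = sol.y[:, -1], sol.t[-1]
        alive = np.maximum(y, 0.0) >= extinction_threshold
        g = percap(y)
        residual = float(np.max(np.abs(g[alive]))) if alive.any() else 0.0
        if residual < residual_tol:
            converged = True
            break
        horizon *= 2.0

    final = np.maximum(y, 0.0)
    final[final < extinction_threshold] = 0.0
    B = _split_levels(final, sizes)
    return {
        "mean": np.array([b.mean() for b in B]),
        "q": np.array([(b**2).mean() for b in B]),
        "phi": np.array([np.count_nonzero(b) / len(b) for b in B]),
        "abundances": B,
        "converged": converged,
        "residual": residual,
    }


@dataclass(frozen=True)
class NLevelState:
    """Solved L-level cavity state (per-level arrays, bottom level first)."""

    mean_B: np.ndarray
    q: np.ndarray
    chi: np.ndarray  # <dB_i/dg_i>, nonnegative
    g_eff: np.ndarray
    sigma_g_eff: np.ndarray
    D_eff: np.ndarray
    delta: np.ndarray
    phi: np.ndarray
    residual_norm: float
    params: NLevelParams = field(repr=False, default=None)


def _effective_n(mean, q, chi, params: NLevelParams):
    L = params.n_levels
    g_eff = np.empty(L)
    sig2 = np.empty(L)
    D_eff = np.empty(L)
    for i in range(L):
        r_up = params.r_up(i)
        up_mean = mean[i + 1] if i + 1 < L else 0.0
        up_q = q[i + 1] if i + 1 < L else 0.0
        up_chi = chi[i + 1] if i + 1 < L else 0.0
        up_sigma = params.sigma[i + 1] if i + 1 < L else 0.0
        up_mu = params.mu[i + 1] if i + 1 < L else 0.0
        up_eta = params.eta[i + 1] if i + 1 < L else 0.0
        down_mean = mean[i - 1] if i >= 1 else 0.0
        down_q = q[i - 1] if i >= 1 else 0.0
        down_chi = chi[i - 1] if i >= 1 else 0.0
        g_eff[i] = (
            params.g_mean[i]
            + params.eta[i] * params.mu[i] * down_mean
            - r_up * up_mu * up_mean
        )
        sig2[i] = (
            (params.eta[i] * params.sigma[i]) ** 2 * down_q
            + r_up * up_sigma**2 * up_q
            + params.g_sd[i] ** 2
        )
        D_eff[i] = (
            params.D[i]
            + params.eta[i] * params.sigma[i] ** 2 * down_chi
            + up_eta * r_up * up_sigma**2 * up_chi
        )
    return g_eff, np.sqrt(sig2), D_eff


def residuals_n(unknowns, params: NLevelParams, _penalize: bool = False):
    """Scaled residuals of the 3L self-consistency equations.

    ``unknowns`` concatenates (mean_B, q, chi), each of length L, all
    nonnegative.  Residuals are scaled by max(1, |prediction|) per equation.
    """
    L = params.n_levels
    x = np.asarray(unknowns, dtype=float)
    if x.shape != (3 * L,):
        raise ValueError(f"unknowns must have shape ({3 * L},)")
    mean, q, chi = x[:L], x[L : 2 * L], x[2 * L :]
    g_eff, sig, D_eff = _effective_n(mean, q, chi, params)
    penalty = 0.0
    tiny = 1e-12
    if np.any(D_eff <= tiny) or np.any(sig <= tiny):
        if not _penalize:
            raise ConvergenceError(
                "degenerate effective parameters (D_eff or sigma_g_eff ~ 0); "
                "the truncated-Gaussian law is undefined there"
            )
        penalty = 1e3 * (1.0 + np.sum(np.maximum(0.0, tiny - D_eff))
                         + np.sum(np.maximum(0.0, tiny - sig)))
        D_eff = np.maximum(D_eff, tiny)
        sig = np.maximum(sig, tiny)
    delta = g_eff / sig
    res = np.empty(3 * L)
    for i in range(L):
        ratio = sig[i] / D_eff[i]
        t_mean = ratio * w(1, delta[i])
        t_q = ratio**2 * w(2, delta[i])
        t_chi = w(0, delta[i]) / D_eff[i]
        res[i] = (mean[i] - t_mean) / max(1.0, abs(t_mean))
        res[L + i] = (q[i] - t_q) / max(1.0, abs(t_q))
        res[2 * L + i] = (chi[i] - t_chi) / max(1.0, abs(t_chi))
    return res + penalty


def _state_from_unknowns(x, params: NLevelParams, norm: float) -> NLevelState:
    L = params.n_levels
    mean, q, chi = x[:L], x[L : 2 * L], x[2 * L :]
    g_eff, sig, D_eff = _effective_n(mean, q, chi, params)
    delta = g_eff / sig
    return NLevelState(
        mean_B=mean.copy(), q=q.copy(), chi=chi.copy(),
        g_eff=g_eff, sigma_g_eff=sig, D_eff=D_eff, delta=delta,
        phi=np.array([w(0, d) for d in delta]),
        residual_norm=float(norm), params=params,
    )


def _warm_start_n(params: NLevelParams, seed: int, target_size: int = 12):
    """Anchor unknowns from one small simulated chain (warm-start trick).

    Sizes are scaled down to ~``target_size`` species on the smallest level;
    the simulated pooled means/second moments anchor (mean, q), and the
    susceptibilities are anchored by iterating chi_i = phi_i / D_eff_i(chi)
    with the simulated survival fractions held fixed.
    """
    L = params.n_levels
    factor = target_size / min(params.M)
    sizes = tuple(max(3, round(m * min(factor, 1.0))) for m in params.M)
    small = NLevelParams(
        M=sizes, g_mean=params.g_mean, g_sd=params.g_sd, D=params.D,
        mu=params.mu, sigma=params.sigma, eta=params.eta,
    )
    comm = sample_nlevel_community(small, seed)
    res = integrate_nlevel(comm, small, seed=seed + 1)
    mean = np.maximum(res["mean"], 1e-3)
    q = np.maximum(res["q"], 1e-3)
    phi = np.maximum(res["phi"], 1e-3)
    # chi anchor: damped fixed-point iteration of chi = phi / D_eff(chi); the
    # undamped map alternates and can diverge, so average with the previous
    # iterate and clip the result to a sane bracket
    chi = phi / (np.asarray(params.D) + 0.5)
    for _ in range(200):
        _, _, D_eff = _effective_n(mean, q, chi, params)
        chi_new = 0.5 * (chi + phi / np.maximum(D_eff, 1e-6))
        chi_new = np.clip(chi_new, 1e-4, 50.0)
        if np.max(np.abs(chi_new - chi)) < 1e-12:
            chi = chi_new
            break
        chi = chi_new
    return np.concatenate([mean, q, np.clip(chi, 1e-3, 20.0)])


def solve_n(
    params: NLevelParams,
    init="warm_start_simulation",
    seed: int = 0,
    n_starts: int = 20,
    accept_tol: float = 1e-6,
    max_nfev: int = 4000,
    plausibility_factor: float = 100.0,
) -> NLevelState:
    """Solve the 3L-equation cavity system by positivity-constrained least squares.

    ``init`` is ``"warm_start_simulation"`` (default: anchor the unknowns on a
    small simulated chain and sample starts between half and the full anchor),
    ``"multistart_random"`` (log-uniform starts in [0.05, 2]), or an explicit
    3L-vector anchor used like the warm-start statistics.

    Besides the physical root, the self-consistency system can admit spurious
    roots: a "noise blow-up" branch in which the second moments of adjacent
    levels sustain each other at enormous values, and off-branch solutions of
    the bilinear susceptibility subsystem (chi_i * D_eff_i(chi) = w0_i).
    Two safeguards select the physical branch: accepted roots must stay
    within ``plausibility_factor`` times the anchor's largest level mean (for
    random multistart, within ``plausibility_factor`` absolute), and among
    all accepted roots found across the starts the one closest to the anchor
    in log-space (means and second moments) is returned — the anchor being a
    direct small-community simulation of the same ensemble.
    """
    from scipy.optimize import least_squares

    L = params.n_levels
    rng = np.random.default_rng(seed)
    anchor = None
    if isinstance(init, str) and init == "warm_start_simulation":
        anchor = _warm_start_n(params, seed=int(rng.integers(2**31)))
        mean_scale = float(np.max(anchor[:L]))
        sample_start = lambda: rng.uniform(0.5, 1.0, size=3 * L) * anchor
    elif isinstance(init, str) and init == "multistart_random":
        mean_scale = 1.0
        sample_start = lambda: np.exp(
            rng.uniform(np.log(0.05), np.log(2.0), size=3 * L)
        )
    elif isinstance(init, str):
        raise ValueError(f"unknown init strategy {init!r}")
    else:
        anchor = np.maximum(np.asarray(init, dtype=float), 1e-8)
        if anchor.shape != (3 * L,):
            raise ValueError(f"explicit init must have shape ({3 * L},)")
        mean_scale = float(np.max(anchor[:L]))
        sample_start = lambda: rng.uniform(0.5, 1.0, size=3 * L) * anchor
    mean_cap = plausibility_factor * (1.0 + mean_scale)

    def fun(y):
        # cap the log-unknowns so stray optimizer steps cannot overflow exp
        return residuals_n(np.exp(np.clip(y, -60.0, 60.0)), params, _penalize=True)

    def anchor_distance(x):
        if anchor is None:
            return float(np.linalg.norm(np.log(np.maximum(x[: 2 * L], 1e-12))))
        return float(
            np.linalg.norm(
                np.log(np.maximum(x[: 2 * L], 1e-12))
                - np.log(np.maximum(anchor[: 2 * L], 1e-12))
            )
        )

    best_norm, best_x = np.inf, None
    accepted = []
    for _ in range(n_starts):
        sol = least_squares(
            fun, np.log(sample_start()), method="lm",
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_nfev,
        )
        x = np.exp(sol.x)
        norm = float(np.linalg.norm(residuals_n(x, params, _penalize=True)))
        if np.max(x[:L]) > mean_cap:
            continue  # unphysical blow-up branch
        if norm < best_norm:
            best_norm, best_x = norm, x
        if norm < accept_tol:
            accepted.append((anchor_distance(x), norm, x))
    if accepted:
        _, norm, x = min(accepted, key=lambda t: t[0])
        return _state_from_unknowns(x, params, norm)
    raise ConvergenceError(
        f"n-level cavity solver failed: best residual norm {best_norm:.3e} "
        f"after {n_starts} starts",
        best_residual=best_norm,
        best_start=best_x,
    )


def order_parameter_level(state: NLevelState, params: NLevelParams, i: int) -> float:
    """Top-down share of the emergent competition on interior level ``i``.

    Returns eta[i+1]*r_up*sigma[i+1]^2*chi[i+1] over the sum of that term and
    eta[i]*sigma[i]^2*chi[i-1]; both contributions are nonnegative.  Defined
    only for interior levels (0 < i < L-1).
    """
    L = params.n_levels
    if not 0 < i < L - 1:
        raise UndefinedLevelError(
            f"order parameter is defined for interior levels only; "
            f"got i={i} with {L} levels"
        )
    top = params.eta[i + 1] * params.r_up(i) * params.sigma[i + 1] ** 2 * state.chi[i + 1]
    bottom = params.eta[i] * params.sigma[i] ** 2 * state.chi[i - 1]
    if top + bottom == 0:
        raise UndefinedControlError(
            f"both feedback contributions vanish at level {i}"
        )
    return float(top / (top + bottom))
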