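"""Species-packing diagnostics, control order parameters, toy model and scans.

Three complementary measures of whether a community is limited from above
(top-down control) or from below (bottom-up control):

* packing-based  — M_X*/M_N*, the fraction of realized herbivore-level niches
  filled by surviving carnivores; equals the top-level share of the emergent
  competition D_eff_N.  Above 0.5 the community is classed top-down.
* biomass-based  — r1*mu_d*<X> / (r1*mu_d*<X> + eta_N*mu_c*<R>), the predation
  share of the herbivores' effective growth rate.
* derivative-based — |d<N>/dk| / (|d<N>/dk| + |d<N>/du|), the bottom-up share
  of the herbivore biomass response to nudging the plant carrying capacity k
  versus the carnivore death rate u (its complement is the top-down share).

The module also evaluates the packing (f-ratio) closed forms of the emergent
competition coefficients, the exact single-species-per-level toy model, grid
scans of the cavity solution, and the finite-size convergence study.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cavity import CavityState, solve
from .ensemble import ModelParams3
from .errors import ConvergenceError, UndefinedControlError
from .simulator import IntegrationConfig, SteadyStateSummary, ensemble_statistics

__all__ = [
    "PackingCounts",
    "ControlOrderParameters",
    "DerivativeControl",
    "f_ratio",
    "d_eff_from_packing",
    "biomass_order_parameter",
    "packing_order_parameter",
    "derivative_order_parameter",
    "control_order_parameters",
    "toy_model_steady_state",
    "phase_scan",
    "finite_size_deviation",
]


@dataclass(frozen=True)
class PackingCounts:
    """Surviving-species counts per level.

    From a simulation these are integers; from a cavity solution they are
    expected counts phi_L * M_L and need not be integral.
    """

    M_X_star: float
    M_N_star: float
    M_R_star: float
    source: str = "simulation"

    def __post_init__(self):
        if self.source not in ("simulation", "cavity"):
            raise ValueError("source must be 'simulation' or 'cavity'")
        if min(self.M_X_star, self.M_N_star, self.M_R_star) < 0:
            raise ValueError("survivor counts must be nonnegative")

    @classmethod
    def from_summary(cls, summary: SteadyStateSummary) -> "PackingCounts":
        return cls(summary.survivors_X, summary.survivors_N, summary.survivors_R,
                   source="simulation")

    @classmethod
    def from_cavity(cls, state: CavityState) -> "PackingCounts":
        mx, mn, mr = state.expected_counts()
        return cls(mx, mn, mr, source="cavity")

    def exclusion_satisfied(self) -> bool:
        """Competitive-exclusion bounds M_X* <= M_N* and M_N* <= M_R* + M_X*."""
        return (self.M_X_star <= self.M_N_star
                and self.M_N_star <= self.M_R_star + self.M_X_star)


def f_ratio(counts: PackingCounts) -> float:
    """Unfilled-niche ratio f = (M_R* + M_X* - M_N*) / (M_N* - M_X*).

    The numerator counts unfilled realized niches in the middle level, the
    denominator those in the top level.  Undefined when M_N* = M_X*: every
    realized top-level niche is filled and no herbivore niche is free for an
    invading carnivore.
    """
    den = counts.M_N_star - counts.M_X_star
    if den == 0:
        raise ZeroDivisionError(
            "f-ratio undefined: M_N* = M_X*, no unfilled realized niches in "
            "the top level"
        )
    return (counts.M_R_star + counts.M_X_star - counts.M_N_star) / den


def d_eff_from_packing(counts: PackingCounts, params: ModelParams3, phi_N: float):
    """Emergent competition coefficients from species-packing counts alone.

    D_eff_X = eta_X*sigma_d^2 / (eta_N*sigma_c^2 * r2 * f),
    D_eff_N = eta_N*phi_N*sigma_c^2 * r2 * f,
    D_eff_R = 1 + 1/f.

    These closed forms agree with the susceptibility-based definitions at any
    solved cavity state.
    """
    f = f_ratio(counts)
    if f <= 0:
        raise ValueError(f"packing forms require f > 0, got f={f:.4g}")
    p = params
    D_X = (p.eta_X * p.sigma_d**2) / (p.eta_N * p.sigma_c**2 * p.r2 * f)
    D_N = p.eta_N * phi_N * p.sigma_c**2 * p.r2 * f
    D_R = 1.0 + 1.0 / f
    return D_X, D_N, D_R


def biomass_order_parameter(state: CavityState, params: ModelParams3 | None = None) -> float:
    """Predation share of the herbivore effective growth rate, in [0, 1].

    |g_N_top| / (|g_N_top| + g_N_bottom) with g_N_top = -r1*mu_d*<X> and
    g_N_bottom = eta_N*mu_c*<R>.
    """
    p = params or state.params
    top = p.r1 * p.mu_d * state.mean_X
    bottom = p.eta_N * p.mu_c * state.mean_R
    if top + bottom == 0:
        raise UndefinedControlError("both growth-rate contributions vanish")
    return top / (top + bottom)


def packing_order_parameter(source) -> float:
    """Fraction of realized top-level niches that are filled, M_X*/M_N*.

    Accepts either :class:`PackingCounts` (ratio of counts) or a solved
    :class:`CavityState` (r1*phi_X/phi_N); for cavity-sourced counts the two
    routes agree.
    """
    if isinstance(source, CavityState):
        if source.phi_N == 0:
            raise ZeroDivisionError("empty middle level: phi_N = 0")
        return source.params.r1 * source.phi_X / source.phi_N
    counts = source
    if counts.M_N_star == 0:
        raise ZeroDivisionError("empty middle level: M_N* = 0")
    return counts.M_X_star / counts.M_N_star


@dataclass(frozen=True)
class DerivativeControl:
    """Central-difference response of <N> to the boundary parameters k and u."""

    bottom_up: float  # |dN/dk| / (|dN/dk| + |dN/du|)
    top_down: float   # complement
    dN_dk: float
    dN_du: float


def derivative_order_parameter(
    params: ModelParams3,
    h_rel: float = 0.01,
    seed: int = 0,
    base_state: CavityState | None = None,
    **solve_kw,
) -> DerivativeControl:
    """Derivative-based control measure from four cavity solves.

    Estimates d<N>/dk and d<N>/du by central differences at relative step
    ``h_rel`` and returns the bottom-up fraction
    |d<N>/dk| / (|d<N>/dk| + |d<N>/du|) together with its top-down
    complement.  Stencil solves are warm-started from the base solution.
    Solver failures at a stencil point propagate, annotated with the point.
    """
    base = base_state or solve(params, seed=seed, **solve_kw)
    init = base.moments

    def solve_at(**changes):
        try:
            return solve(replace(params, **changes), init=init, seed=seed, **solve_kw)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"stencil solve failed at {changes}: {err}",
                best_residual=err.best_residual,
                best_start=err.best_start,
            ) from err

    h_k = h_rel * max(abs(params.k), 1e-3)
    h_u = h_rel * max(abs(params.u), 1e-3)
    dN_dk = (solve_at(k=params.k + h_k).mean_N - solve_at(k=params.k - h_k).mean_N) / (2 * h_k)
    dN_du = (solve_at(u=params.u + h_u).mean_N - solve_at(u=params.u - h_u).mean_N) / (2 * h_u)
    total = abs(dN_dk) + abs(dN_du)
    if total == 0:
        raise UndefinedControlError("herbivore biomass insensitive to both k and u")
    bu = abs(dN_dk) / total
    return DerivativeControl(bottom_up=bu, top_down=1.0 - bu,
                             dN_dk=dN_dk, dN_du=dN_du)


@dataclass(frozen=True)
class ControlOrderParameters:
    """The three top-down/bottom-up measures for one community.

    ``derivative_based`` is the *bottom-up* fraction (the printed convention);
    its top-down counterpart is 1 - derivative_based.  ``regime`` classifies
    by the packing measure against the 0.5 threshold.
    """

    biomass_based: float
    packing_based: float
    derivative_based: float
    f: float
    regime: str


def control_order_parameters(
    state: CavityState,
    h_rel: float = 0.01,
    seed: int = 0,
    **solve_kw,
) -> ControlOrderParameters:
    """Assemble all three order parameters at a solved cavity state."""
    packing = packing_order_parameter(state)
    deriv = derivative_order_parameter(
        state.params, h_rel=h_rel, seed=seed, base_state=state, **solve_kw
    )
    return ControlOrderParameters(
        biomass_based=biomass_order_parameter(state),
        packing_based=packing,
        derivative_based=deriv.bottom_up,
        f=state.f,
        regime="top_down" if packing > 0.5 else "bottom_up",
    )


def toy_model_steady_state(
    k1: float, m1: float, u1: float,
    eta_N: float, eta_X: float,
    D_R: float, D_N: float, D_X: float,
    c11: float, d11: float,
) -> tuple[float, float, float]:
    """Exact steady state of the one-species-per-level chain.

    Dynamics:
        dR/dt = R*(k1 - D_R*R - c11*N)
        dN/dt = N*(eta_N*c11*R - m1 - D_N*N - d11*X)
        dX/dt = X*(eta_X*d11*N - u1 - D_X*X)

    Case analysis mirrors invasion logic: try the full interior equilibrium,
    then drop the carnivore, then the herbivore, then everything.  A boundary
    case is accepted when its member abundances are positive and no excluded
    species has a positive invasion growth rate; if round-off leaves no case
    fully stable, the first merely feasible case in the same order is used.

    Returns (R*, N*, X*), nonnegative, a fixed point of the dynamics.
    """
    candidates = []

    # interior: linear 3x3 system in (R, N, X)
    A = np.array([
        [D_R, c11, 0.0],
        [eta_N * c11, -D_N, -d11],
        [0.0, eta_X * d11, -D_X],
    ])
    b = np.array([k1, m1, u1])
    try:
        R, N, X = np.linalg.solve(A, b)
        candidates.append(((R, N, X), ()))  # no excluded species
    except np.linalg.LinAlgError:
        pass

    # carnivore extinct: 2x2 in (R, N)
    A2 = np.array([[D_R, c11], [eta_N * c11, -D_N]])
    try:
        R, N = np.linalg.solve(A2, np.array([k1, m1]))
        invasion_X = eta_X * d11 * N - u1
        candidates.append(((R, N, 0.0), (invasion_X,)))
    except np.linalg.LinAlgError:
        pass

    # consumers extinct: logistic plant
    if D_R > 0:
        R = k1 / D_R
        invasion_N = eta_N * c11 * R - m1
        candidates.append(((R, 0.0, 0.0), (invasion_N,)))

    # empty system
    candidates.append(((0.0, 0.0, 0.0), (k1,)))

    tol = 1e-12

    def feasible(state):
        # member abundances (set by the linear solve) must be positive;
        # excluded species are exactly 0.0 by construction
        return all(v > tol or v == 0.0 for v in state)

    for state, invasions in candidates:
        if feasible(state) and all(inv <= tol for inv in invasions):
            return tuple(float(v) for v in state)
    # round-off corner: fall back to the first feasible case in the same
    # precedence order, ignoring invasibility
    for state, _ in candidates:
        if feasible(state):
            return tuple(float(v) for v in state)
    return (0.0, 0.0, 0.0)


_SCANNABLE = {"k", "u", "m", "mu_c", "mu_d", "sigma_c", "sigma_d",
              "eta_N", "eta_X", "r1", "r2"}


def _params_at_point(params: ModelParams3, point: dict) -> ModelParams3:
    direct = {k: v for k, v in point.items() if k not in ("r1", "r2")}
    p = replace(params, **direct) if direct else params
    if "r1" in point or "r2" in point:
        p = p.with_ratios(point.get("r1"), point.get("r2"))
    return p


def _cavity_row(state: CavityState) -> dict:
    row = {
        name: getattr(state, name)
        for name in (
            "mean_X", "mean_N", "mean_R", "q_X", "q_N", "q_R",
            "chi", "nu", "kappa",
            "g_eff_X", "g_eff_N", "g_eff_R",
            "sigma_g_X", "sigma_g_N", "sigma_g_R",
            "D_eff_X", "D_eff_N", "D_eff_R",
            "delta_X", "delta_N", "delta_R",
            "phi_X", "phi_N", "phi_R",
            "residual_norm",
        )
    }
    row["f"] = state.f
    row["D_N_top"] = state.D_N_top
    row["D_N_bottom"] = state.D_N_bottom
    row["packing_order_parameter"] = packing_order_parameter(state)
    row["biomass_order_parameter"] = biomass_order_parameter(state)
    return row


def phase_scan(
    params: ModelParams3,
    grid: dict,
    seed: int = 0,
    include_derivative: bool = False,
    h_rel: float = 0.01,
    **solve_kw,
) -> pd.DataFrame:
    """Cavity solution over a cartesian parameter grid, long format.

    ``grid`` maps parameter names (any of k, u, m, mu_c, mu_d, sigma_c,
    sigma_d, eta_N, eta_X, r1, r2) to value arrays.  Consecutive points are
    warm-started from the previous solution, so 1-D scans are cheap.  Solver
    failures are recorded in the ``status`` column, not raised.  Deterministic
    given the seed.
    """
    unknown = set(grid) - _SCANNABLE
    if unknown:
        raise ValueError(f"cannot scan over {sorted(unknown)}; "
                         f"allowed: {sorted(_SCANNABLE)}")
    names = list(grid)
    rows = []
    prev_moments = None
    for values in itertools.product(*(np.atleast_1d(grid[n]) for n in names)):
        point = dict(zip(names, (float(v) for v in values)))
        p = _params_at_point(params, point)
        row = dict(point)
        state = None
        for init in ([prev_moments] if prev_moments is not None else []) + [
            "warm_start_simulation", "multistart_random",
        ]:
            try:
                state = solve(p, init=init, seed=seed, **solve_kw)
                break
            except ConvergenceError:
                continue
        if state is None:
            row["status"] = "failed"
        else:
            row.update(_cavity_row(state))
            row["status"] = "ok"
            prev_moments = state.moments
            if include_derivative:
                try:
                    d = derivative_order_parameter(
                        p, h_rel=h_rel, seed=seed, base_state=state, **solve_kw
                    )
                    row["derivative_bottom_up"] = d.bottom_up
                    row["derivative_top_down"] = d.top_down
                except (ConvergenceError, UndefinedControlError):
                    row["status"] = "derivative_failed"
        rows.append(row)
    return pd.DataFrame(rows)


def finite_size_deviation(
    params: ModelParams3,
    sizes,
    n_systems: int,
    config: IntegrationConfig | None = None,
    seed: int = 0,
    cavity_state: CavityState | None = None,
) -> pd.DataFrame:
    """Mean squared deviation of single-system statistics from the cavity solution.

    For each carnivore pool size M_X in ``sizes``, herbivore and plant pools
    are set to match the reference ratios r1 and r2, ``n_systems`` communities
    are integrated, and the squared deviation of each system's
    (mean_X, mean_N, mean_R, phi_X, phi_N, phi_R) from the (size-independent)
    cavity prediction is averaged over systems and components.
    """
    r1, r2 = params.r1, params.r2
    base = params.with_ratios(r1, r2)
    state = cavity_state or solve(base, seed=seed)
    target = np.array([
        state.mean_X, state.mean_N, state.mean_R,
        state.phi_X, state.phi_N, state.phi_R,
    ])
    rows = []
    for j, M_X in enumerate(sizes):
        M_N = max(1, round(M_X / r1))
        M_R = max(1, round(M_N / r2))
        p = params.with_sizes(int(M_X), M_N, M_R)
        stats = ensemble_statistics(p, n_systems, config=config, seed=seed + j)
        devs = []
        for s in stats.per_system:
            if not s.converged:
                continue
            v = np.array([s.mean_X, s.mean_N, s.mean_R, *s.survival_fractions])
            devs.append(np.mean((v - target) ** 2))
        rows.append({
            "M_X": int(M_X), "M_N": M_N, "M_R": M_R,
            "n_converged": stats.n_converged,
            "mean_squared_deviation": float(np.mean(devs)),
            "cavity_mean_X": state.mean_X,
            "cavity_mean_N": state.mean_N,
            "cavity_mean_R": state.mean_R,
            "cavity_phi_X": state.phi_X,
            "cavity_phi_N": state.phi_N,
            "cavity_phi_R": state.phi_R,
        })
    return pd.DataFrame(rows)
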