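"""Random three-level community ensembles.

A community couples three trophic levels: plants (primary producers) R_P with
carrying capacities K_P, herbivores N_i with death rates m_i feeding on plants
through the preference matrix c (M_N x M_R), and carnivores X_alpha with death
rates u_alpha feeding on herbivores through d (M_X x M_N).  Preference entries
are i.i.d. with mean mu/M_prey and standard deviation sigma/sqrt(M_prey),
where M_prey is the prey pool size, so that the level-summed interaction
strength stays O(1) as pool sizes grow.

Two sampling dialects are provided with identical first two moments:

* ``gaussian`` — entries are Gaussian and may be negative; this is the
  statistics the cavity theory assumes exactly.
* ``uniform`` — entries are uniform on [mean - sqrt(3)*s, mean + sqrt(3)*s];
  feasible (strictly positive) only when mean > sqrt(3)*s, e.g. when the
  preference means are large relative to their spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .errors import InfeasibleDialectError

__all__ = ["ModelParams3", "CommunityInstance", "sample_community", "generate_ensemble"]


@dataclass(frozen=True)
class ModelParams3:
    """Scalar statistics defining a random three-level ecosystem ensemble.

    Defaults are a well-studied reference condition: pools of 50 carnivores,
    56 herbivores and 62 plants with k = 4, m = u = 1, sigma_c = sigma_d = 0.5,
    mu_c = mu_d = 1, eta_X = 0.8, eta_N = 0.6 and 0.1 spread on the
    growth/death parameters.
    """

    M_X: int = 50
    M_N: int = 56
    M_R: int = 62
    mu_c: float = 1.0
    mu_d: float = 1.0
    sigma_c: float = 0.5
    sigma_d: float = 0.5
    k: float = 4.0
    sigma_K: float = 0.1
    m: float = 1.0
    sigma_m: float = 0.1
    u: float = 1.0
    sigma_u: float = 0.1
    eta_N: float = 0.6
    eta_X: float = 0.8
    preference_dialect: str = "gaussian"
    # Exact pool-size ratios for thermodynamic-limit work (cavity solutions,
    # parameter scans).  When set they override the integer-size ratios, so a
    # scan in r1 is not staircased by rounding M_X to an integer.  Sampling of
    # finite communities always uses the integer sizes.
    r1_override: float | None = None
    r2_override: float | None = None

    def __post_init__(self):
        for name in ("M_X", "M_N", "M_R"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("sigma_c", "sigma_d", "sigma_K", "sigma_m", "sigma_u"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("eta_N", "eta_X"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.preference_dialect not in ("gaussian", "uniform"):
            raise ValueError(
                f"preference_dialect must be 'gaussian' or 'uniform', "
                f"got {self.preference_dialect!r}"
            )
        for name in ("r1_override", "r2_override"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when set")

    @property
    def r1(self) -> float:
        """Pool-size ratio M_X / M_N (carnivores per herbivore niche)."""
        return self.r1_override if self.r1_override is not None else self.M_X / self.M_N

    @property
    def r2(self) -> float:
        """Pool-size ratio M_N / M_R (herbivores per plant niche)."""
        return self.r2_override if self.r2_override is not None else self.M_N / self.M_R

    def with_sizes(self, M_X: int, M_N: int, M_R: int) -> "ModelParams3":
        """Return a copy with different pool sizes (and no ratio overrides)."""
        return replace(self, M_X=M_X, M_N=M_N, M_R=M_R,
                       r1_override=None, r2_override=None)

    def with_ratios(self, r1: float | None = None, r2: float | None = None) -> "ModelParams3":
        """Return a copy with exact ratio overrides (sizes left untouched)."""
        kw = {}
        if r1 is not None:
            kw["r1_override"] = float(r1)
        if r2 is not None:
            kw["r2_override"] = float(r2)
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams3":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelParams3 keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class CommunityInstance:
    """One sampled realization of a three-level community."""

    c: np.ndarray  # (M_N, M_R) herbivore->plant preferences
    d: np.ndarray  # (M_X, M_N) carnivore->herbivore preferences
    K: np.ndarray  # (M_R,) plant carrying capacities
    m_vec: np.ndarray  # (M_N,) herbivore death rates
    u_vec: np.ndarray  # (M_X,) carnivore death rates
    seed: int = 0

    def __post_init__(self):
        M_N, M_R = self.c.shape
        M_X = self.d.shape[0]
        if self.d.shape != (M_X, M_N):
            raise ValueError(
                f"d has shape {self.d.shape}, expected ({M_X}, {M_N}) to match c"
            )
        if self.K.shape != (M_R,) or self.m_vec.shape != (M_N,) or self.u_vec.shape != (M_X,):
            raise ValueError("K, m_vec, u_vec shapes inconsistent with c, d")

    @property
    def sizes(self) -> tuple[int, int, int]:
        """(M_X, M_N, M_R)."""
        return self.d.shape[0], self.c.shape[0], self.c.shape[1]


def _sample_matrix(rng, shape, mean, sd, dialect):
    if dialect == "gaussian":
        return rng.normal(mean, sd, size=shape) if sd > 0 else np.full(shape, mean)
    half = np.sqrt(3.0) * sd
    if mean - half < 0:
        raise InfeasibleDialectError(
            f"uniform dialect infeasible: mean {mean:.4g} < sqrt(3)*sd {half:.4g}; "
            "entries would not be strictly positive"
        )
    return rng.uniform(mean - half, mean + half, size=shape)


def sample_community(params: ModelParams3, seed: int) -> CommunityInstance:
    """Draw one community with the prescribed entry statistics.

    Preference entries: d ~ (mu_d/M_N, sigma_d/sqrt(M_N)), c ~ (mu_c/M_R,
    sigma_c/sqrt(M_R)); K, m, u are always Gaussian with the stated
    means and standard deviations.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    dialect = params.preference_dialect
    d = _sample_matrix(
        rng, (params.M_X, params.M_N),
        params.mu_d / params.M_N, params.sigma_d / np.sqrt(params.M_N), dialect,
    )
    c = _sample_matrix(
        rng, (params.M_N, params.M_R),
        params.mu_c / params.M_R, params.sigma_c / np.sqrt(params.M_R), dialect,
    )
    K = rng.normal(params.k, params.sigma_K, size=params.M_R)
    m_vec = rng.normal(params.m, params.sigma_m, size=params.M_N)
    u_vec = rng.normal(params.u, params.sigma_u, size=params.M_X)
    return CommunityInstance(c=c, d=d, K=K, m_vec=m_vec, u_vec=u_vec, seed=int(seed))


def child_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-system sub-seeds derived from a master seed.

    Uses numpy's SeedSequence splitting so streams for different systems are
    statistically independent; the same master seed always yields the same
    sub-seeds.
    """
    return np.random.SeedSequence(master_seed).generate_state(n)


def generate_ensemble(params: ModelParams3, n_systems: int, seed: int):
    """Sample ``n_systems`` independent communities from one master seed."""
    if n_systems < 1:
        raise ValueError("n_systems must be >= 1")
    seeds = child_seeds(seed, n_systems)
    return [sample_community(params, int(s)) for s in seeds]
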