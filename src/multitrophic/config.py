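"""Run configuration: schema, loading, serialization and dispatch.

A run is described by a small YAML (or JSON — valid YAML) document::

    command: cavity            # simulate | cavity | nlevel | scan | toy | finite-size
    seed: 1
    output_dir: runs/demo
    params:                    # ModelParams3 fields
      M_X: 50
      M_N: 56
      M_R: 62
      k: 4.0
      ...
    integration:               # IntegrationConfig fields (simulate / finite-size)
      t_final: 200.0
    solver:                    # cavity/nlevel solver options
      n_starts: 12
      accept_tol: 1.0e-6
    grid:                      # scan only
      k: [1, 2, 3]
      u: [1, 2]
    n_systems: 50              # simulate / finite-size
    sizes: [10, 20, 50]        # finite-size
    toy: {k1: 5.0, m1: 1.0, ...}
    nlevel_params: {...}       # nlevel only; NLevelParams fields

Every run writes the fully resolved configuration (defaults expanded) next to
its outputs, plus a log recording the config hash, seed, library versions and
wall time.  Identical config + seed produces identical data payloads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .cavity import solve
from .ensemble import ModelParams3
from .errors import ConfigError
from .nlevel import NLevelParams, solve_n
from .observables import finite_size_deviation, phase_scan, toy_model_steady_state
from .simulator import IntegrationConfig, ensemble_statistics

__all__ = ["RunConfig", "load_config", "run", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_COMMANDS = ("simulate", "cavity", "nlevel", "scan", "toy", "finite-size")
_TOP_KEYS = {
    "command", "seed", "output_dir", "params", "nlevel_params", "integration",
    "solver", "grid", "n_systems", "sizes", "toy", "include_derivative",
    "schema_version",
}
_TOY_DEFAULTS = dict(k1=5.0, m1=1.0, u1=2.0, eta_N=0.9, eta_X=0.9,
                     D_R=1.0, D_N=5.0, D_X=5.0, c11=4.0, d11=4.0)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved description of one run."""

    command: str
    seed: int = 0
    output_dir: str = "."
    params: ModelParams3 = field(default_factory=ModelParams3)
    nlevel_params: NLevelParams | None = None
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    solver: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    n_systems: int = 50
    sizes: tuple = (10, 20, 50)
    toy: dict = field(default_factory=lambda: dict(_TOY_DEFAULTS))
    include_derivative: bool = False

    def __post_init__(self):
        if self.command not in _COMMANDS:
            raise ConfigError(
                f"unknown command {self.command!r}; expected one of {_COMMANDS}",
                keys=("command",),
            )

    def resolved_dict(self) -> dict:
        """Plain-python dict with every default expanded (round-trips losslessly)."""
        d = {
            "schema_version": SCHEMA_VERSION,
            "command": self.command,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "params": dataclasses.asdict(self.params),
            "integration": dataclasses.asdict(self.integration),
            "solver": dict(self.solver),
            "grid": {k: list(map(float, np.atleast_1d(v))) for k, v in self.grid.items()},
            "n_systems": self.n_systems,
            "sizes": list(self.sizes),
            "toy": dict(self.toy),
            "include_derivative": self.include_derivative,
        }
        if self.nlevel_params is not None:
            d["nlevel_params"] = dataclasses.asdict(self.nlevel_params)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific content: the resolved config minus output paths."""
        d = self.resolved_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _check_keys(d: dict, allowed, context: str):
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown {context} keys: {sorted(unknown)}", keys=sorted(unknown)
        )


def config_from_dict(raw: dict, command: str | None = None) -> RunConfig:
    """Build a RunConfig from a plain dict, validating every key."""
    if not isinstance(raw, dict):
        raise ConfigError("config document must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    cmd = command or raw.get("command")
    if cmd is None:
        raise ConfigError("config must specify a command", keys=("command",))

    params_dict = dict(raw.get("params", {}))
    _check_keys(params_dict, {f.name for f in dataclasses.fields(ModelParams3)},
                "params")
    params = ModelParams3(**params_dict)

    integ_dict = dict(raw.get("integration", {}))
    _check_keys(integ_dict, {f.name for f in dataclasses.fields(IntegrationConfig)},
                "integration")
    integration = IntegrationConfig(**integ_dict)

    nlevel_params = None
    if "nlevel_params" in raw:
        nl = dict(raw["nlevel_params"])
        _check_keys(nl, {f.name for f in dataclasses.fields(NLevelParams)},
                    "nlevel_params")
        nlevel_params = NLevelParams(**{k: tuple(v) for k, v in nl.items()})

    toy = dict(_TOY_DEFAULTS)
    toy_raw = dict(raw.get("toy", {}))
    _check_keys(toy_raw, _TOY_DEFAULTS, "toy")
    toy.update(toy_raw)

    return RunConfig(
        command=cmd,
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", ".")),
        params=params,
        nlevel_params=nlevel_params,
        integration=integration,
        solver=dict(raw.get("solver", {})),
        grid=dict(raw.get("grid", {})),
        n_systems=int(raw.get("n_systems", 50)),
        sizes=tuple(raw.get("sizes", (10, 20, 50))),
        toy=toy,
        include_derivative=bool(raw.get("include_derivative", False)),
    )


def load_config(path, command: str | None = None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw or {}, command=command)


def _atomic_write(path: Path, text: str):
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def _write_json(path: Path, payload: dict):
    payload = {"schema_version": SCHEMA_VERSION, **payload}
    _atomic_write(path, json.dumps(payload, indent=2, default=_json_default) + "\n")


def _state_payload(state) -> dict:
    d = dataclasses.asdict(state)
    d.pop("params", None)
    return d


def run(config: RunConfig) -> dict:
    """Execute a run; writes artifacts into ``config.output_dir``.

    Returns a manifest dict listing the artifact paths.  All randomness flows
    from ``config.seed``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    cfg_hash = config.config_hash()
    _atomic_write(out / "config.resolved.yaml",
                  yaml.safe_dump(config.resolved_dict(), sort_keys=True))

    artifacts = {"config": str(out / "config.resolved.yaml")}
    cmd, seed = config.command, config.seed

    if cmd == "simulate":
        stats = ensemble_statistics(config.params, config.n_systems,
                                    config=config.integration, seed=seed)
        rows = []
        for sys_idx, s in enumerate(stats.per_system):
            for level, arr in (("X", s.X_star), ("N", s.N_star), ("R", s.R_star)):
                for sp, ab in enumerate(arr):
                    rows.append((sys_idx, level, sp, float(ab), bool(ab > 0)))
        import pandas as pd

        df = pd.DataFrame(rows, columns=["system", "level", "species",
                                         "abundance", "survived"])
        df.to_csv(out / "abundances.csv", index=False)
        pooled = stats.pooled
        _write_json(out / "summary.json", {
            "config_hash": cfg_hash,
            "n_systems": stats.n_systems,
            "n_converged": stats.n_converged,
            "pooled": {
                "mean_X": pooled.mean_X, "mean_N": pooled.mean_N,
                "mean_R": pooled.mean_R,
                "q_X": pooled.second_moment_X, "q_N": pooled.second_moment_N,
                "q_R": pooled.second_moment_R,
                "phi_X": pooled.survival_fractions[0],
                "phi_N": pooled.survival_fractions[1],
                "phi_R": pooled.survival_fractions[2],
            },
            "standard_errors": stats.standard_errors(),
        })
        artifacts["abundances"] = str(out / "abundances.csv")
        artifacts["summary"] = str(out / "summary.json")

    elif cmd == "cavity":
        state = solve(config.params, seed=seed, **config.solver)
        _write_json(out / "cavity.json", {
            "config_hash": cfg_hash,
            "state": _state_payload(state),
            "f": state.f,
            "packing_order_parameter": state.params.r1 * state.phi_X / state.phi_N,
        })
        artifacts["cavity"] = str(out / "cavity.json")

    elif cmd == "nlevel":
        if config.nlevel_params is None:
            raise ConfigError("nlevel command requires nlevel_params",
                              keys=("nlevel_params",))
        state = solve_n(config.nlevel_params, seed=seed, **config.solver)
        _write_json(out / "nlevel.json",
                    {"config_hash": cfg_hash, "state": _state_payload(state)})
        artifacts["nlevel"] = str(out / "nlevel.json")

    elif cmd == "scan":
        df = phase_scan(config.params, config.grid, seed=seed,
                        include_derivative=config.include_derivative,
                        **config.solver)
        header = (f"# schema_version={SCHEMA_VERSION} config_hash={cfg_hash} "
                  f"seed={seed} version={_pkg_version}\n")
        _atomic_write(out / "scan.csv", header + df.to_csv(index=False))
        artifacts["scan"] = str(out / "scan.csv")

    elif cmd == "toy":
        R, N, X = toy_model_steady_state(**config.toy)
        _write_json(out / "toy.json", {
            "config_hash": cfg_hash,
            "R_star": R, "N_star": N, "X_star": X,
        })
        artifacts["toy"] = str(out / "toy.json")

    elif cmd == "finite-size":
        df = finite_size_deviation(config.params, config.sizes, config.n_systems,
                                   config=config.integration, seed=seed)
        header = (f"# schema_version={SCHEMA_VERSION} config_hash={cfg_hash} "
                  f"seed={seed} version={_pkg_version}\n")
        _atomic_write(out / "finite_size.csv", header + df.to_csv(index=False))
        artifacts["finite_size"] = str(out / "finite_size.csv")

    _write_json(out / "run_log.json", {
        "config_hash": cfg_hash,
        "command": cmd,
        "seed": seed,
        "versions": {"multitrophic": _pkg_version, "numpy": np.__version__},
        "wall_time_s": time.perf_counter() - t0,
    })
    artifacts["log"] = str(out / "run_log.json")
    return artifacts
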