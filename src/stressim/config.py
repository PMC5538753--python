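"""Run configuration: YAML/JSON loading, validation, and fixture generation.

A :class:`RunConfig` bundles everything a command-line run needs — model
parameters, the scenario (regime / stress diversity / strategy / seed),
the grid of cycle lengths, numerical tolerances, and the output
directory — and round-trips losslessly through YAML.  Unknown keys are
rejected so that typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .params import ModelParameters

__all__ = ["ConfigError", "RunConfig", "load_config", "generate_fixtures", "FIXTURE_NAMES"]


class ConfigError(ValueError):
    """Invalid or malformed run configuration; message lists all failures."""


_PARAM_KEYS = {"s", "sigma", "mu_M", "mu_R", "nu_R", "tau_S", "tau_NS"}
_SCENARIO_KEYS = {"regime", "chi", "seed", "n_iterations", "n_last"}
_GRID_KEYS = {"taus", "tau_over_tau_c_min", "tau_over_tau_c_max", "n_points"}
_TOL_KEYS = {"convergence", "extinction", "rtol", "atol"}
_TOP_KEYS = {"parameters", "scenario", "grid", "tolerances", "max_cycles", "output_dir"}

_REGIMES = {"R", "NR", "cyclic", "randomized", "treatment"}


def _check_keys(mapping: dict, allowed: set[str], section: str, errors: list[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        errors.append(f"unknown key(s) in {section}: {sorted(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one simulation or sweep run."""

    parameters: ModelParameters
    regime: str = "NR"
    chi: int = 1
    seed: int = 0
    n_iterations: int = 10_000
    n_last: int = 1_000
    taus: tuple[float, ...] | None = None
    tau_over_tau_c_min: float = 0.02
    tau_over_tau_c_max: float = 1.5
    n_points: int = 20
    convergence_tol: float = 1e-9
    extinction_tol: float = 1e-10
    rtol: float = 1e-10
    atol: float = 1e-12
    max_cycles: int = 10_000
    output_dir: str = "stressim_out"

    def tau_grid(self) -> np.ndarray:
        """Resolved grid of cycle lengths (explicit taus win over the range spec)."""
        if self.taus is not None:
            return np.asarray(self.taus, dtype=float)
        from .analytic import critical_cycle_length

        tau_c = critical_cycle_length(self.parameters)
        return np.geomspace(
            self.tau_over_tau_c_min * tau_c, self.tau_over_tau_c_max * tau_c, self.n_points
        )

    def to_dict(self) -> dict:
        p = self.parameters
        out: dict = {
            "parameters": {
                "s": p.s, "sigma": p.sigma, "mu_M": p.mu_M,
                "mu_R": p.mu_R, "nu_R": p.nu_R, "tau_S": p.tau_S, "tau_NS": p.tau_NS,
            },
            "scenario": {
                "regime": self.regime, "chi": self.chi, "seed": self.seed,
                "n_iterations": self.n_iterations, "n_last": self.n_last,
            },
            "grid": (
                {"taus": list(self.taus)}
                if self.taus is not None
                else {
                    "tau_over_tau_c_min": self.tau_over_tau_c_min,
                    "tau_over_tau_c_max": self.tau_over_tau_c_max,
                    "n_points": self.n_points,
                }
            ),
            "tolerances": {
                "convergence": self.convergence_tol, "extinction": self.extinction_tol,
                "rtol": self.rtol, "atol": self.atol,
            },
            "max_cycles": self.max_cycles,
            "output_dir": self.output_dir,
        }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        errors: list[str] = []
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
        _check_keys(data, _TOP_KEYS, "top level", errors)

        raw_params = data.get("parameters")
        params = None
        if not isinstance(raw_params, dict):
            errors.append("missing or non-mapping 'parameters' section")
        else:
            _check_keys(raw_params, _PARAM_KEYS, "parameters", errors)
            missing = {"s", "sigma", "mu_M", "mu_R", "nu_R"} - set(raw_params)
            if missing:
                errors.append(f"missing parameter(s): {sorted(missing)}")
            if not errors:
                try:
                    params = ModelParameters(**raw_params)
                except (TypeError, ValueError) as exc:
                    errors.append(str(exc))

        kwargs: dict = {}
        scenario = data.get("scenario", {})
        if not isinstance(scenario, dict):
            errors.append("'scenario' must be a mapping")
        else:
            _check_keys(scenario, _SCENARIO_KEYS, "scenario", errors)
            regime = scenario.get("regime", "NR")
            if regime not in _REGIMES:
                errors.append(f"regime must be one of {sorted(_REGIMES)}, got {regime!r}")
            kwargs["regime"] = regime
            for key, attr in (("chi", "chi"), ("seed", "seed"),
                              ("n_iterations", "n_iterations"), ("n_last", "n_last")):
                if key in scenario:
                    value = scenario[key]
                    if not isinstance(value, int) or value < 0:
                        errors.append(f"scenario.{key} must be a non-negative integer")
                    else:
                        kwargs[attr] = value
            if kwargs.get("chi", 1) < 1:
                errors.append("scenario.chi must be >= 1")

        grid = data.get("grid", {})
        if not isinstance(grid, dict):
            errors.append("'grid' must be a mapping")
        else:
            _check_keys(grid, _GRID_KEYS, "grid", errors)
            if "taus" in grid:
                taus = grid["taus"]
                if not isinstance(taus, (list, tuple)) or not taus or any(
                    not isinstance(t, (int, float)) or t <= 0 for t in taus
                ):
                    errors.append("grid.taus must be a non-empty list of positive numbers")
                else:
                    kwargs["taus"] = tuple(float(t) for t in taus)
            for key, attr in (
                ("tau_over_tau_c_min", "tau_over_tau_c_min"),
                ("tau_over_tau_c_max", "tau_over_tau_c_max"),
            ):
                if key in grid:
                    value = grid[key]
                    if not isinstance(value, (int, float)) or value <= 0:
                        errors.append(f"grid.{key} must be a positive number")
                    else:
                        kwargs[attr] = float(value)
            if "n_points" in grid:
                if not isinstance(grid["n_points"], int) or grid["n_points"] < 1:
                    errors.append("grid.n_points must be a positive integer")
                else:
                    kwargs["n_points"] = grid["n_points"]

        tols = data.get("tolerances", {})
        if not isinstance(tols, dict):
            errors.append("'tolerances' must be a mapping")
        else:
            _check_keys(tols, _TOL_KEYS, "tolerances", errors)
            for key, attr in (("convergence", "convergence_tol"), ("extinction", "extinction_tol"),
                              ("rtol", "rtol"), ("atol", "atol")):
                if key in tols:
                    value = tols[key]
                    if not isinstance(value, (int, float)) or value <= 0:
                        errors.append(f"tolerances.{key} must be a positive number")
                    else:
                        kwargs[attr] = float(value)

        if "max_cycles" in data:
            if not isinstance(data["max_cycles"], int) or data["max_cycles"] < 1:
                errors.append("max_cycles must be a positive integer")
            else:
                kwargs["max_cycles"] = data["max_cycles"]
        if "output_dir" in data:
            if not isinstance(data["output_dir"], str):
                errors.append("output_dir must be a string")
            else:
                kwargs["output_dir"] = data["output_dir"]

        if errors or params is None:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
        return cls(parameters=params, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    Emits a hierarchy warning if the rates violate s >> (mu_M, mu_R) >> nu_R.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    config = RunConfig.from_dict(data)
    config.parameters.check_hierarchy()
    return config


def _dump(config_dict: dict) -> str:
    return yaml.safe_dump(config_dict, sort_keys=True, default_flow_style=False)


#: Canonical configurations written by :func:`generate_fixtures`.
FIXTURE_NAMES = ("single_stress.yaml", "treatment.yaml", "smoke.yaml")


def generate_fixtures(output_dir: str | Path) -> list[Path]:
    """Write the canonical parameter-set configs plus a fast smoke-test config.

    ``single_stress.yaml`` carries the single-stress cycling benchmark
    (s=1, sigma=100, mu_M=1e-3, mu_R=1e-2, nu_R=1e-4, tau_S=10);
    ``treatment.yaml`` the multi-drug comparison set (s=0.5, mu_R=5e-3);
    ``smoke.yaml`` a coarse, capped variant for end-to-end smoke runs.
    Regeneration is idempotent (byte-identical files).
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    single = RunConfig(
        parameters=ModelParameters(s=1.0, sigma=100.0, mu_M=1e-3, mu_R=1e-2,
                                   nu_R=1e-4, tau_S=10.0, tau_NS=90.0),
        regime="NR",
    )
    treatment = RunConfig(
        parameters=ModelParameters(s=0.5, sigma=100.0, mu_M=1e-3, mu_R=5e-3,
                                   nu_R=1e-4, tau_S=10.0, tau_NS=90.0),
        regime="treatment",
        chi=4,
        taus=(600.0, 800.0, 1000.0, 1100.0, 1200.0, 1400.0),
    )
    smoke = RunConfig(
        parameters=ModelParameters(s=1.0, sigma=100.0, mu_M=1e-3, mu_R=1e-2,
                                   nu_R=1e-4, tau_S=10.0, tau_NS=90.0),
        regime="NR",
        n_points=4,
        tau_over_tau_c_min=0.1,
        tau_over_tau_c_max=1.2,
        max_cycles=500,
        n_iterations=200,
        n_last=50,
    )

    written = []
    for name, config in zip(FIXTURE_NAMES, (single, treatment, smoke)):
        path = output_dir / name
        path.write_text(_dump(config.to_dict()))
        written.append(path)
    return written


def write_manifest(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    """Write the fully resolved configuration (plus provenance extras) as JSON."""
    from . import __version__

    manifest = {"stressim_version": __version__, "config": config.to_dict()}
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
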