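"""Structured run configuration: strict YAML loading and object construction.

A run config has blocks ``model``, ``response``, ``grid``, ``perturbation``,
``solver`` plus top-level ``mode`` and ``output_dir``.  Unknown keys are
rejected so that typos fail loudly, and every command writes the resolved
config beside its outputs for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .geometry import BipolarGrid, make_grid
from .model import ModelParameters, ResponseFunction
from .diagnostics import PerturbationSpec

__all__ = ["RunConfig", "load_config", "resolved_config_dict"]

_MODEL_KEYS = {"D_L", "D_M", "mu", "k_L", "k_M", "k_N", "L0"}
_RESPONSE_KEYS = {
    "identity": set(),
    "logistic": {"offset", "amplitude", "steepness", "center"},
    "pinned": {"L_star", "value", "slope"},
}
_GRID_KEYS = {"d", "tau_ext", "tau_int", "m", "n"}
_PERTURBATION_KEYS = {
    "amplitude", "pattern", "k_tau", "k_sigma", "center", "width", "seed", "species_mask",
}
_SOLVER_KEYS = {"t_end", "n_outputs", "rtol", "atol", "method", "divergence"}
_TOP_KEYS = {"mode", "output_dir", "model", "response", "grid", "perturbation", "solver"}

_SOLVER_DEFAULTS = {
    "t_end": 10.0,
    "n_outputs": 33,
    "rtol": 1e-8,
    "atol": 1e-10,
    "method": "BDF",
    "divergence": "faithful",
}


def _require_keys(block: Mapping[str, Any], allowed: set, required: set, name: str) -> None:
    if not isinstance(block, Mapping):
        raise ConfigurationError(f"config block {name!r} must be a mapping")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(f"unknown keys in {name!r}: {sorted(unknown)}")
    missing = required - set(block)
    if missing:
        raise ConfigurationError(f"missing keys in {name!r}: {sorted(missing)}")


@dataclass
class RunConfig:
    params: ModelParameters
    grid_spec: dict
    perturbation: PerturbationSpec
    solver: dict
    mode: str
    output_dir: Path
    raw: dict = field(repr=False, default_factory=dict)

    def make_grid(self) -> BipolarGrid:
        g = self.grid_spec
        return make_grid(g["tau_ext"], g["tau_int"], g["m"], g["n"], g["d"])


def _build_response(block: Mapping[str, Any]) -> ResponseFunction:
    family = block.get("family")
    if family not in _RESPONSE_KEYS:
        raise ConfigurationError(
            f"response.family must be one of {sorted(_RESPONSE_KEYS)}, got {family!r}"
        )
    _require_keys(
        {k: v for k, v in block.items() if k != "family"},
        _RESPONSE_KEYS[family], _RESPONSE_KEYS[family] if family == "pinned" else set(),
        f"response({family})",
    )
    if family == "identity":
        return ResponseFunction.identity()
    if family == "logistic":
        return ResponseFunction.logistic(
            offset=float(block.get("offset", 0.0)),
            amplitude=float(block.get("amplitude", 1.0)),
            steepness=float(block.get("steepness", 1.0)),
            center=float(block.get("center", 0.0)),
        )
    return ResponseFunction.pinned(
        L_star=float(block["L_star"]), value=float(block["value"]), slope=float(block["slope"])
    )


def load_config(path: str | Path) -> RunConfig:
    """Load, validate and materialize a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    _require_keys(raw, _TOP_KEYS, {"mode", "output_dir", "model", "response", "grid"}, "top level")

    mode = raw["mode"]
    if mode not in ("nonlinear", "linearized"):
        raise ConfigurationError(f"mode must be 'nonlinear' or 'linearized', got {mode!r}")

    _require_keys(raw["model"], _MODEL_KEYS, _MODEL_KEYS, "model")
    try:
        params = ModelParameters(
            response=_build_response(raw["response"]),
            **{k: float(raw["model"][k]) for k in _MODEL_KEYS},
        )
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc

    _require_keys(raw["grid"], _GRID_KEYS, _GRID_KEYS, "grid")
    grid_spec = {
        "d": float(raw["grid"]["d"]),
        "tau_ext": float(raw["grid"]["tau_ext"]),
        "tau_int": float(raw["grid"]["tau_int"]),
        "m": int(raw["grid"]["m"]),
        "n": int(raw["grid"]["n"]),
    }

    pert_block = dict(raw.get("perturbation", {"amplitude": 0.01}))
    _require_keys(pert_block, _PERTURBATION_KEYS, {"amplitude"}, "perturbation")
    mask = pert_block.pop("species_mask", [True, True, True])
    if len(mask) != 3:
        raise ConfigurationError("species_mask needs exactly three booleans")
    perturbation = PerturbationSpec(species_mask=tuple(bool(v) for v in mask), **pert_block)

    solver = dict(_SOLVER_DEFAULTS)
    solver_block = raw.get("solver", {})
    _require_keys(solver_block, _SOLVER_KEYS, set(), "solver")
    solver.update(solver_block)

    return RunConfig(
        params=params,
        grid_spec=grid_spec,
        perturbation=perturbation,
        solver=solver,
        mode=mode,
        output_dir=Path(raw["output_dir"]),
        raw=raw,
    )


def resolved_config_dict(cfg: RunConfig) -> dict:
    """Fully resolved configuration (defaults applied) for provenance output."""
    rf = cfg.params.response
    return {
        "mode": cfg.mode,
        "output_dir": str(cfg.output_dir),
        "model": {
            k: getattr(cfg.params, k) for k in sorted(_MODEL_KEYS)
        },
        "response": {"family": rf.family, **{k: float(v) for k, v in rf.parameters.items()}},
        "grid": dict(cfg.grid_spec),
        "perturbation": {
            "amplitude": cfg.perturbation.amplitude,
            "pattern": cfg.perturbation.pattern,
            "k_tau": cfg.perturbation.k_tau,
            "k_sigma": cfg.perturbation.k_sigma,
            "center": cfg.perturbation.center,
            "width": cfg.perturbation.width,
            "seed": cfg.perturbation.seed,
            "species_mask": list(cfg.perturbation.species_mask),
        },
        "solver": dict(cfg.solver),
    }
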