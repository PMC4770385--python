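"""YAML run configuration: validation and construction of typed parameters.

A config file has named blocks, each validated against the corresponding
parameter type before any computation runs; unknown keys anywhere are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any

import yaml

from .models import (
    BlamDimensionalParams,
    BlamDimensionlessParams,
    SimplifiedParams,
    SwarmbotState,
    TransportParams,
    TwoCompartmentSimplifiedParams,
)
from .simulate import SPECIES, DosingSchedule
from .synthetic import NoiseModel

__all__ = ["RunConfig", "ConfigError", "load_config"]

KNOWN_BLOCKS = {
    "model",
    "params",
    "base_params",
    "transport",
    "schedule",
    "simulation",
    "steady_state",
    "heatmap",
    "synthetic",
    "fitting",
    "seed",
    "outdir",
}


class ConfigError(ValueError):
    """A config file failed validation."""


def _build(cls, block: dict, where: str):
    """Instantiate a parameter dataclass from a mapping, rejecting unknown keys."""
    if block is None:
        block = {}
    if not isinstance(block, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(block).__name__}")
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)} (allowed: {sorted(allowed)})")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


@dataclass
class RunConfig:
    """Fully validated run configuration."""

    model: str = "simplified"
    params: Any = None
    transport: TransportParams | None = None
    schedule: DosingSchedule | None = None
    simulation: dict = field(default_factory=dict)
    steady_state: dict = field(default_factory=dict)
    heatmap: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)
    fitting: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "results"
    raw: dict = field(default_factory=dict)

    def initial_state(self):
        init = self.simulation.get("initial_state")
        if init is None:
            raise ConfigError("simulation.initial_state is required for simulate")
        if self.model == "swarmbot":
            if isinstance(init, dict):
                return _build(SwarmbotState, init, "simulation.initial_state")
            return SwarmbotState.from_array(init)
        expected = len(SPECIES[self.model])
        init = [init] if isinstance(init, (int, float)) else list(init)
        if len(init) != expected:
            raise ConfigError(
                f"simulation.initial_state: model {self.model!r} needs {expected} "
                f"components, got {len(init)}"
            )
        return init

    def sim_params(self):
        """Parameter object(s) in the form `simulate` expects."""
        if self.model == "swarmbot":
            return (self.params, self.transport or TransportParams())
        return self.params


_PARAM_TYPES = {
    "simplified": SimplifiedParams,
    "two_compartment_simplified": TwoCompartmentSimplifiedParams,
    "blam": BlamDimensionlessParams,
    "blam_dimensional": BlamDimensionalParams,
    "swarmbot": BlamDimensionlessParams,
}

_SIMULATION_KEYS = {"initial_state", "horizon", "n_samples", "rtol", "atol", "method"}
_STEADY_KEYS = {"k_values", "search_interval"}
_HEATMAP_KEYS = {"i_a_values", "i_s_values", "horizon", "grow_threshold",
                 "persist_threshold", "initial_state", "rtol", "atol"}
_SYNTHETIC_KEYS = {"sampling_interval", "noise", "gain", "antibiotic_levels",
                   "nutrient_levels", "replicates", "horizon"}
_FITTING_KEYS = {"free_params", "bounds", "start", "n_starts", "compartment"}


def _check_keys(block: dict, allowed: set, where: str) -> dict:
    block = block or {}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)} (allowed: {sorted(allowed)})")
    return dict(block)


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML config file (or an already-parsed mapping)."""
    if (path is None) == (data is None):
        raise ValueError("pass exactly one of path or data")
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("top level of the config must be a mapping")
    unknown = set(data) - KNOWN_BLOCKS
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)} (allowed: {sorted(KNOWN_BLOCKS)})")

    model = data.get("model", "simplified")
    if model not in _PARAM_TYPES:
        raise ConfigError(f"model must be one of {sorted(_PARAM_TYPES)}, got {model!r}")

    params_block = data.get("params") or {}
    if model == "two_compartment_simplified":
        base = _build(SimplifiedParams, data.get("base_params") or params_block.pop("base", {}) or {}, "base_params")
        params = _build(
            TwoCompartmentSimplifiedParams,
            {**params_block, "base": base},
            "params",
        )
    else:
        params = _build(_PARAM_TYPES[model], params_block, "params")

    transport = None
    if "transport" in data or model == "swarmbot":
        transport = _build(TransportParams, data.get("transport") or {}, "transport")

    schedule = None
    if "schedule" in data:
        schedule = _build(DosingSchedule, data["schedule"], "schedule")

    synthetic = _check_keys(data.get("synthetic"), _SYNTHETIC_KEYS, "synthetic")
    if "noise" in synthetic:
        synthetic["noise"] = _build(NoiseModel, synthetic["noise"], "synthetic.noise")

    cfg = RunConfig(
        model=model,
        params=params,
        transport=transport,
        schedule=schedule,
        simulation=_check_keys(data.get("simulation"), _SIMULATION_KEYS, "simulation"),
        steady_state=_check_keys(data.get("steady_state"), _STEADY_KEYS, "steady_state"),
        heatmap=_check_keys(data.get("heatmap"), _HEATMAP_KEYS, "heatmap"),
        synthetic=synthetic,
        fitting=_check_keys(data.get("fitting"), _FITTING_KEYS, "fitting"),
        seed=int(data.get("seed", 0)),
        outdir=str(data.get("outdir", "results")),
        raw=data,
    )
    return cfg
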