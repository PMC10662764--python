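"""Run configuration: defaults, YAML loading, strict validation.

The default blocks carry the reference parameter values of the particle
model (sigma=0.05, A_p=1, n=4, T_delay=5, beta=8, h=0.25, s=5), the neural
field (see :class:`ringdrift.neural_field.NeuralFieldParams`), the task
protocol, and the fitting pipeline, plus scale factors (n_sim, n_boot,
k_sets, n_rep) that trade accuracy for runtime.
"""

from __future__ import annotations

import copy
from dataclasses import asdict
from pathlib import Path

import yaml

from .neural_field import NeuralFieldParams

__all__ = ["RunConfig", "DEFAULTS", "load_config", "merge_config"]


def _field_defaults() -> dict:
    d = asdict(NeuralFieldParams())
    d.pop("seed")
    return d


DEFAULTS = {
    "seed": 0,
    "out_dir": "runs",
    "environment": {
        "prior_form": "exp_cosine",
        "amplitude": 1.0,
        "modes": 4,
        "offset_deg": 0.0,
        "n_short": 100,
        "n_long": 100,
        "p_biased": 0.5,
        "arc_width_deg": 20.0,
    },
    "particle": {
        "sigma": 0.05,
        "A_p": 1.0,
        "n": 4,
        "T_delay": 5.0,
        "dt": 0.01,
        "beta": 8.0,
        "h": 0.25,
        "s": 5.0,
    },
    "field": _field_defaults(),
    "generator": {
        "model": "StaticHet",
        "params": {"sigma": 0.05, "A_p": 1.0, "n": 4},
        "n_subjects": 1,
    },
    "fitting": {
        "k_sets": 100,
        "n_rep": 100,
        "models": "all",
        "population_offset_deg": 0.0,
    },
    "scale": {
        "n_sim": 100_000,
        "n_boot": 1000,
    },
}


class RunConfig(dict):
    """Validated configuration; behaves like a nested dict."""


def merge_config(overrides: dict, defaults: dict = DEFAULTS, path: str = "") -> dict:
    """Recursive merge with strict schema: unknown keys are errors."""
    merged = copy.deepcopy(defaults)
    for key, value in (overrides or {}).items():
        where = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ValueError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and key != "params":
            if not isinstance(value, dict):
                raise ValueError(f"config key {where} must be a mapping")
            merged[key] = merge_config(value, defaults[key], path=where)
        else:
            merged[key] = value
    return merged


def load_config(path=None) -> RunConfig:
    """Load a YAML config, applying defaults for absent fields."""
    if path is None:
        return RunConfig(copy.deepcopy(DEFAULTS))
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"config root in {path} must be a mapping")
    return RunConfig(merge_config(data))
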