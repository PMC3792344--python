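"""Flat YAML run-configuration files.

A config is a flat mapping of scalar keys; unknown keys are rejected so a
typo cannot silently fall back to a default.  Example::

    condition: static_gradient
    n_replicates: 24
    n_mcs: 500000
    seed_base: 0
    box: [80, 10, 10]
    N: 80
    steepness: 1.0
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .experiments import ExperimentSpec

__all__ = ["load_experiment_spec", "save_experiment_spec"]

_FIELDS = {f.name for f in fields(ExperimentSpec)}


def load_experiment_spec(path) -> ExperimentSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    unknown = set(data) - _FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "box" in data:
        data["box"] = tuple(data["box"])
    return ExperimentSpec(**data)


def save_experiment_spec(spec: ExperimentSpec, path) -> None:
    d = spec.config_dict()
    d["box"] = list(d["box"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
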