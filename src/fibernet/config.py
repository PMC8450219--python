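"""YAML run configuration with schema and unit validation.

A config file is organized in sections mirroring the model layers::

    schema_version: 1
    seed: 7
    network:
      concentration: "1.5 mg/ml"
      box_edge: "60 um"
    cells:
      density: "0.5e6 cells/ml"
      radius: "15 um"
    crosslinks:
      k_on: "0.01 1/s"
      k_off0: "1e-4 1/s"
    protocol:
      dt: "0.5 s"
      horizon: "240 s"

Quantities may be plain numbers (interpreted in the canonical unit) or
``"value unit"`` strings; a wrong unit string is a load-time error, as
is any unknown key.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .bonds import CrosslinkKinetics
from .cells import CatchSlipParams, CellParams
from .mechanics import BeamProperties
from .protocols import SimulationConfig

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised on schema violations, unknown keys, or unit mismatches."""


#: section -> field -> (canonical unit, aliases)
_SCHEMA: dict[str, dict[str, str]] = {
    "network": {
        "concentration": "mg/ml",
        "box_edge": "um",
        "fiber_diameter": "um",
        "fiber_modulus": "Pa",
        "elements_per_segment": "",
    },
    "cells": {
        "density": "cells/ml",
        "radius": "um",
        "shell_halfwidth": "um",
        "k_on": "1/s",
        "k_sf": "pN/um",
        "contraction_rate": "um/s",
        "max_adhesions": "",
    },
    "catch_slip": {
        "a1": "1/s", "b1": "pN", "c1": "pN",
        "a2": "1/s", "b2": "pN", "c2": "pN", "F_min": "pN",
    },
    "crosslinks": {
        "k_on": "1/s",
        "k_off0": "1/s",
        "delta_x": "um",
        "d_min": "um",
        "d_max": "um",
    },
    "protocol": {
        "dt": "s",
        "horizon": "s",
        "removal_time": "s",
        "record_every": "",
        "mechanics_tol": "pN",
    },
}


def _parse_quantity(section: str, key: str, value, unit: str) -> float:
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.split(None, 1)
        try:
            num = float(parts[0])
        except ValueError as e:
            raise ConfigError(f"{section}.{key}: cannot parse number from {value!r}") from e
        if len(parts) == 2:
            given = parts[1].strip().replace("μm", "um").replace("µm", "um")
            if unit == "":
                raise ConfigError(f"{section}.{key}: dimensionless, got unit {given!r}")
            if given != unit:
                raise ConfigError(f"{section}.{key}: expected unit {unit!r}, got {given!r}")
        return num
    raise ConfigError(f"{section}.{key}: expected number or 'value unit' string")


def load_config(path) -> tuple[SimulationConfig, dict]:
    """Load and validate a YAML run configuration.

    Returns the :class:`SimulationConfig` plus a dict of protocol extras
    (currently ``removal_time``).
    """
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"invalid YAML: {e}") from e
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    doc = dict(doc)
    version = doc.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"schema_version must be {SCHEMA_VERSION}, got {version!r}")
    seed = doc.pop("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")

    values: dict[str, dict[str, float]] = {}
    for section, entries in doc.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown section {section!r}")
        if not isinstance(entries, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        values[section] = {}
        for key, raw in entries.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown key {section}.{key}")
            values[section][key] = _parse_quantity(section, key, raw, _SCHEMA[section][key])

    cfg = SimulationConfig(seed=seed)
    net = values.get("network", {})
    if "concentration" in net:
        cfg = replace(cfg, concentration=net["concentration"])
    if "box_edge" in net:
        cfg = replace(cfg, box_edge=net["box_edge"])
    if "elements_per_segment" in net:
        cfg = replace(cfg, elements_per_segment=int(net["elements_per_segment"]))
    beam = BeamProperties(
        youngs_modulus=net.get("fiber_modulus", BeamProperties().youngs_modulus),
        diameter=net.get("fiber_diameter", BeamProperties().diameter),
    )
    cfg = replace(cfg, beam=beam)

    cs = values.get("catch_slip", {})
    catch = CatchSlipParams(**{k: cs[k] for k in cs}) if cs else CatchSlipParams()
    cell_map = {
        "density": None, "radius": "radius", "shell_halfwidth": "shell_halfwidth",
        "k_on": "k_on_cf", "k_sf": "k_sf", "contraction_rate": "contraction_rate",
        "max_adhesions": "max_adhesions",
    }
    cells = values.get("cells", {})
    kwargs = {}
    for key, attr in cell_map.items():
        if key in cells and attr is not None:
            kwargs[attr] = int(cells[key]) if attr == "max_adhesions" else cells[key]
    cfg = replace(cfg, cell=CellParams(catch_slip=catch, **kwargs))
    if "density" in cells:
        cfg = replace(cfg, cell_density=cells["density"])

    if "crosslinks" in values:
        cl = values["crosslinks"]
        cfg = replace(cfg, crosslinks=CrosslinkKinetics(**{k: cl[k] for k in cl}))

    proto = values.get("protocol", {})
    for key, attr in (("dt", "dt"), ("horizon", "horizon"), ("mechanics_tol", "mechanics_tol")):
        if key in proto:
            cfg = replace(cfg, **{attr: proto[key]})
    if "record_every" in proto:
        cfg = replace(cfg, record_every=int(proto["record_every"]))
    extras = {"removal_time": proto.get("removal_time")}
    return cfg, extras
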