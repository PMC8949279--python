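"""Declarative run configuration (YAML).

One file describes a whole run: a ``mesh`` section (generator + parameters
or a file path), ``materials`` keyed by element tag, a ``scenario`` section
and optional ``solver`` overrides.  All quantities are SI.  Serialisation
round-trips exactly (materials are plain dataclasses).
"""

from __future__ import annotations

from pathlib import Path

import yaml

from . import mesh as meshmod
from .impact import ImpactScenario
from .materials import material_from_dict
from .spacetime import SolverConfig

__all__ = ["load_config", "save_config", "build_mesh", "build_scenario",
           "build_materials", "build_solver_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def build_mesh(cfg: dict) -> meshmod.Mesh:
    section = cfg.get("mesh", {})
    kind = section.get("kind", "file")
    if kind == "bar":
        return meshmod.generate_bar_mesh(
            section["length"], section["width"], section["height"],
            tuple(section.get("divisions", (10, 2, 2))),
        )
    if kind == "ellipsoid":
        return meshmod.generate_ellipsoid_mesh(
            tuple(section.get("semi_axes", (0.09, 0.07, 0.08))),
            int(section.get("target_element_count", 21384)),
            float(section.get("frontal_layer_thickness", 0.0)),
        )
    if kind == "file":
        return meshmod.read_mesh(section["path"], section.get("format"))
    raise ValueError(f"unknown mesh kind {kind!r}")


def build_materials(cfg: dict) -> dict[int, object]:
    section = cfg.get("materials", {})
    if not section:
        raise ValueError("config has no materials section")
    return {int(tag): material_from_dict(d) for tag, d in section.items()}


def build_scenario(cfg: dict, mesh=None) -> ImpactScenario:
    section = dict(cfg.get("scenario", {}))
    if section.pop("head_on", False) and mesh is not None:
        return ImpactScenario.head_on(mesh, **{
            k: (tuple(v) if isinstance(v, list) else v) for k, v in section.items()
        })
    for key in ("direction", "plane_point", "plane_normal", "gravity"):
        if key in section and isinstance(section[key], list):
            section[key] = tuple(section[key])
    return ImpactScenario(**section)


def build_solver_config(cfg: dict) -> SolverConfig:
    return SolverConfig(**cfg.get("solver", {}))
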