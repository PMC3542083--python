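"""YAML run configuration.

All physical quantities are SI: metres, seconds, Pa s, kg m^-3,
mol m^-3, m^2 s^-1.  A config file has an optional ``mode`` plus blocks
named after the parameter groups::

    mode: grow            # grow | flow | transport | morph | synth | sweep
    output: runs/demo
    domain:   {extents: [0.6, 0.6, 0.4], pitch: 0.0125}
    fluid:    {velocity: 0.05, dynamic_viscosity: 5.0e-2,
               fluid_density: 1.0e+3}
    transport: {diffusion_coefficient: 1.0e-3, boundary_concentration: 1.0}
    growth:   {L_max: 1.0e-3, K: 1.0, n: 1.2, surface_diffusion: 3.0e-4,
               steps: 40, target_edge: 4.0e-3}
    colony:   {initial_diameter: 0.06}
    fixtures: {n_branches: 8, seed: 1, pitch: 0.001}

Validation happens while building the parameter dataclasses, before any
compute; unknown keys raise with the offending field name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fixtures import FixtureSpec
from .flow import DEFAULT_BC, FluidParams, SimulationDomain
from .growth import GrowthConfig, GrowthParams
from .transport import TransportParams

_FLUID_KEYS = {"velocity": "inlet_speed", "dynamic_viscosity": "viscosity",
               "fluid_density": "density", "tolerance": "tol",
               "max_iterations": "max_iters"}
_TRANSPORT_KEYS = {"diffusion_coefficient": "diffusivity",
                   "boundary_concentration": "boundary_conc",
                   "sampling_distance": "sampling_distance",
                   "tolerance": "tol"}
_GROWTH_KEYS = {"L_max": "l_max", "K": "k", "n": "n",
                "surface_diffusion": "d_s", "tau_s": "tau_s",
                "steps": "steps", "target_edge": "target_edge"}


class ConfigError(ValueError):
    pass


def _mapped(block: dict, mapping: dict, where: str) -> dict:
    out = {}
    for key, val in (block or {}).items():
        if key not in mapping:
            raise ConfigError(f"unknown field '{key}' in block '{where}' "
                              f"(expected one of {sorted(mapping)})")
        out[mapping[key]] = val
    return out


@dataclass
class RunConfig:
    """A fully validated experiment configuration."""

    mode: str = "grow"
    output: str = "runs/out"
    growth_config: GrowthConfig = field(default_factory=GrowthConfig)
    fixture_spec: FixtureSpec = field(default_factory=FixtureSpec)
    morph: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)


def build_config(doc: dict) -> RunConfig:
    doc = dict(doc or {})
    mode = doc.get("mode", "grow")
    if mode not in ("grow", "flow", "transport", "morph", "synth", "sweep"):
        raise ConfigError(f"unknown mode '{mode}'")

    dom_block = dict(doc.get("domain") or {})
    bc = dict(DEFAULT_BC)
    bc.update(dom_block.pop("bc", {}))
    try:
        domain = SimulationDomain(
            extents=tuple(dom_block.pop("extents", (0.6, 0.6, 0.4))),
            pitch=float(dom_block.pop("pitch", 0.0125)), bc=bc)
    except ValueError as exc:
        raise ConfigError(f"domain: {exc}") from exc
    if dom_block:
        raise ConfigError(f"unknown field(s) in block 'domain': "
                          f"{sorted(dom_block)}")

    try:
        fluid = FluidParams(**_mapped(doc.get("fluid"), _FLUID_KEYS, "fluid"))
        transport = TransportParams(**_mapped(doc.get("transport"),
                                              _TRANSPORT_KEYS, "transport"))
        growth = GrowthParams(**_mapped(doc.get("growth"), _GROWTH_KEYS,
                                        "growth"))
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    colony = dict(doc.get("colony") or {})
    run = dict(doc.get("run") or {})
    gc = GrowthConfig(
        domain=domain, fluid=fluid, transport=transport, growth=growth,
        initial_diameter=float(colony.pop("initial_diameter", 0.06)),
        center_height=colony.pop("center_height", None),
        flow_enabled=bool(run.pop("flow_enabled", True)),
        flow_update_interval=int(run.pop("flow_update_interval", 1)),
        self_intersection_interval=int(
            run.pop("self_intersection_interval", 0)),
        response=run.pop("response", "hill"),
    )
    if colony:
        raise ConfigError(f"unknown field(s) in block 'colony': "
                          f"{sorted(colony)}")
    if run:
        raise ConfigError(f"unknown field(s) in block 'run': {sorted(run)}")

    fx = dict(doc.get("fixtures") or {})
    try:
        spec = FixtureSpec(**fx)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"fixtures: {exc}") from exc

    return RunConfig(mode=mode, output=str(doc.get("output", "runs/out")),
                     growth_config=gc, fixture_spec=spec,
                     morph=dict(doc.get("morph") or {}), raw=doc)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return build_config(doc)


def desk_scale_config(diffusivity: float = 1.0e-3,
                      steps: int = 40,
                      flow_enabled: bool = True) -> GrowthConfig:
    """The desk-scale study conditions used by the trend experiments.

    A 0.24 x 0.24 x 0.18 m channel at 7.5 mm pitch around the 6 cm seed
    colony, 4 mm mesh edges, flow refreshed every 5 steps (the interface
    advances at most 0.5 mm per step, well under one voxel).
    """
    return GrowthConfig(
        domain=SimulationDomain(extents=(0.24, 0.24, 0.18), pitch=0.0075),
        fluid=FluidParams(),
        transport=TransportParams(diffusivity=diffusivity),
        growth=GrowthParams(steps=steps, target_edge=4.0e-3),
        flow_enabled=flow_enabled,
        flow_update_interval=5,
    )
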