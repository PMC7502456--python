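"""Configuration files: YAML in bench units (mm, kPa), SI internally.

The file schema mirrors the `SimulationConfig` structure; every length
is given in millimetres and every modulus in kilopascals, converted once
at load.  The cohesive calibration constraints (delta_max < delta_c < b)
are checked at load time with the violated inequality named.
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml

from .cohesive import calibrate_cohesive_law
from .driver import SimulationConfig
from .fe_solid import Material
from .geometry import DomainSpec, NeedleSpec
from .units import kpa, mm, to_kpa, to_mm

DEFAULT_FRICTION = 0.3


class ConfigError(ValueError):
    """Schema or constraint violation in a configuration file."""


def load_config(path) -> SimulationConfig:
    """Load and validate a simulation configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        nd = raw["needle"]
        dm = raw["domain"]
        sb = raw["substrate"]
        cz = raw["cohesive"]
    except KeyError as k:
        raise ConfigError(f"{path}: missing section {k}") from k

    needle = NeedleSpec(
        b=mm(float(nd["b_mm"])),
        alpha=math.radians(0.5 * float(nd["total_bevel_deg"])),
        c=mm(float(nd.get("c_mm", 0.0))),
        rho_tip=mm(float(nd["rho_tip_mm"])),
        E=kpa(float(nd["E_kpa"])),
        nu=float(nd.get("nu", 0.475)),
        length=mm(float(nd.get("length_mm", 120.0))))
    domain = DomainSpec(
        half_width=mm(float(dm["half_width_mm"])),
        height=mm(float(dm["height_mm"])),
        inner_half_width=mm(float(dm["inner_half_width_mm"])),
        inner_depth=mm(float(dm["inner_depth_mm"])),
        h_tip=mm(float(dm["h_tip_mm"])),
        h_inner=mm(float(dm["h_inner_mm"])),
        h_outer=mm(float(dm["h_outer_mm"])),
        ring_sectors=int(dm.get("ring_sectors", 16)),
        ring_radius_factor=float(dm.get("ring_radius_factor", 2.0)),
        notch_depth_factor=float(dm.get("notch_depth_factor", 6.0)))
    substrate = Material(E=kpa(float(sb["E_kpa"])),
                         nu=float(sb.get("nu", 0.475)))

    G_c = float(cz["G_c"])
    sigma_max = float(cz["sigma_max_pa"])
    try:
        calibrate_cohesive_law(G_c, sigma_max, needle.rho_tip, needle.b)
    except ValueError as err:
        raise ConfigError(f"{path}: cohesive calibration: {err}") from err

    friction = raw.get("friction")
    if friction is None:
        friction = DEFAULT_FRICTION
        import logging
        logging.getLogger("needlefem").info(
            "friction coefficient not given; using default f = %.2f",
            DEFAULT_FRICTION)

    run = raw.get("run", {})
    kwargs = dict(needle=needle, domain=domain, substrate=substrate,
                  G_c=G_c, sigma_max=sigma_max, friction=float(friction),
                  target_depth=mm(float(run.get("target_depth_mm", 20.0))),
                  seed=int(run.get("seed", 0)))
    for key in ("n_seed_symmetric", "weak_factor", "standoff_factor",
                "admissible_range_deg", "step_coarse", "step_fine",
                "penalty_factor", "max_iterations", "constitutive_model"):
        if key in run:
            kwargs[key] = run[key]
    return SimulationConfig(**kwargs)


def dump_config(cfg: SimulationConfig, path) -> None:
    """Write a configuration file (bench units) for `load_config`."""
    nd, dm = cfg.needle, cfg.domain
    data = {
        "needle": {
            "b_mm": to_mm(nd.b),
            "total_bevel_deg": math.degrees(2 * nd.alpha),
            "c_mm": to_mm(nd.c),
            "rho_tip_mm": to_mm(nd.rho_tip),
            "E_kpa": to_kpa(nd.E),
            "nu": nd.nu,
            "length_mm": to_mm(nd.length),
        },
        "domain": {
            "half_width_mm": to_mm(dm.half_width),
            "height_mm": to_mm(dm.height),
            "inner_half_width_mm": to_mm(dm.inner_half_width),
            "inner_depth_mm": to_mm(dm.inner_depth),
            "h_tip_mm": to_mm(dm.h_tip),
            "h_inner_mm": to_mm(dm.h_inner),
            "h_outer_mm": to_mm(dm.h_outer),
            "ring_sectors": dm.ring_sectors,
            "ring_radius_factor": dm.ring_radius_factor,
            "notch_depth_factor": dm.notch_depth_factor,
        },
        "substrate": {"E_kpa": to_kpa(cfg.substrate.E),
                      "nu": cfg.substrate.nu},
        "cohesive": {"G_c": cfg.G_c, "sigma_max_pa": cfg.sigma_max},
        "friction": cfg.friction,
        "run": {
            "target_depth_mm": to_mm(cfg.target_depth),
            "seed": cfg.seed,
            "n_seed_symmetric": cfg.n_seed_symmetric,
            "weak_factor": cfg.weak_factor,
            "standoff_factor": cfg.standoff_factor,
            "admissible_range_deg": cfg.admissible_range_deg,
            "step_coarse": cfg.step_coarse,
            "step_fine": cfg.step_fine,
            "penalty_factor": cfg.penalty_factor,
            "max_iterations": cfg.max_iterations,
            "constitutive_model": cfg.constitutive_model,
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
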