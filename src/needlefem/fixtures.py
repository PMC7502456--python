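"""Self-contained presets and synthetic oracles.

Everything needed to exercise the simulator — configurations at the
standard gelatine-phantom scale, scaled-down variants that run quickly,
and synthetic trajectories with known curvature — is generated here
programmatically; no external data is required anywhere in the package.

Preset families
---------------
- ``symmetric`` / ``pbn-c22`` / ``pbn-c32`` / ``pbn-c47``: the standard
  bench-scale configurations (235 x 245 mm gelatine block, 8 mm needle,
  h_tip = rho_tip / 2).  These are hours-scale runs.
- ``coarse-*``: domain shrunk 4x and h_tip doubled.
- ``micro-*``: the desk-scale study used by the test-suite and the
  acceptance script: same needle tip geometry and material constants,
  an 80 x 60 mm block, shallow target depth.
- ``unit-patch`` / ``cantilever`` / ``friction-block`` / ``czm-strip``:
  parameter bundles for the elementary verification problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .driver import SimulationConfig
from .fe_solid import Material
from .geometry import DomainSpec, NeedleSpec
from .postprocess import PenetrationPath

PRESET_NAMES = ("symmetric", "pbn-c22", "pbn-c32", "pbn-c47",
                "coarse-symmetric", "coarse-pbn",
                "micro-symmetric", "micro-pbn",
                "unit-patch", "cantilever", "friction-block", "czm-strip")

# standard gelatine-phantom constants
E_GEL = 14.8e3
NU = 0.475
G_C = 1.1
SIGMA_MAX = 550.0
FRICTION = 0.3
B = 8e-3
ALPHA = math.radians(10.0)
RHO_TIP = 0.5e-3
E_NEEDLE_STD = 16 * E_GEL          # stiffness ratio 16 unless overridden


@dataclass(frozen=True)
class ElementaryPreset:
    """Parameter bundle for one of the elementary verification problems."""

    name: str
    params: dict


def _needle(c: float, E: float = E_NEEDLE_STD, length: float = 0.12) -> NeedleSpec:
    return NeedleSpec(b=B, alpha=ALPHA, c=c, rho_tip=RHO_TIP, E=E, nu=NU,
                      length=length)


def make_preset(name: str, **overrides):
    """Build a named configuration.

    Simulation presets return a `SimulationConfig`; the elementary
    verification presets return an `ElementaryPreset` parameter bundle.
    Keyword overrides replace `SimulationConfig` fields.
    """
    if name == "symmetric" or name == "pbn-c22" or name == "pbn-c32" \
            or name == "pbn-c47":
        c = {"symmetric": 0.0, "pbn-c22": 22e-3, "pbn-c32": 32e-3,
             "pbn-c47": 47e-3}[name]
        domain = DomainSpec(half_width=0.1175, height=0.245,
                            inner_half_width=0.035, inner_depth=0.13,
                            h_tip=0.5 * RHO_TIP, h_inner=2.5e-3,
                            h_outer=0.02, notch_depth_factor=6.0)
        cfg = dict(needle=_needle(c), domain=domain,
                   substrate=Material(E_GEL, NU), G_c=G_C,
                   sigma_max=SIGMA_MAX, friction=FRICTION,
                   target_depth=max(0.06, 2 * c + 0.016),
                   standoff_factor=0.5)
    elif name in ("coarse-symmetric", "coarse-pbn"):
        c = 0.0 if name == "coarse-symmetric" else 22e-3
        domain = DomainSpec(half_width=0.1175 / 4, height=0.245 / 4,
                            inner_half_width=0.016, inner_depth=0.05,
                            h_tip=RHO_TIP, h_inner=2.5e-3, h_outer=8e-3,
                            notch_depth_factor=6.0)
        cfg = dict(needle=_needle(c, length=0.07), domain=domain,
                   substrate=Material(E_GEL, NU), G_c=G_C,
                   sigma_max=SIGMA_MAX, friction=FRICTION,
                   target_depth=0.04, standoff_factor=0.5)
    elif name in ("micro-symmetric", "micro-pbn"):
        c = 0.0 if name == "micro-symmetric" else 6e-3
        domain = DomainSpec(half_width=0.04, height=0.06,
                            inner_half_width=0.012, inner_depth=0.03,
                            h_tip=0.5 * RHO_TIP, h_inner=2e-3, h_outer=6e-3,
                            notch_depth_factor=6.0)
        cfg = dict(needle=_needle(c, length=0.03), domain=domain,
                   substrate=Material(E_GEL, NU), G_c=G_C,
                   sigma_max=SIGMA_MAX, friction=FRICTION,
                   target_depth=8e-3 if c == 0 else 13e-3,
                   step_coarse=0.5, step_fine=0.1, penalty_factor=10.0,
                   standoff_factor=0.5)
    elif name == "unit-patch":
        return ElementaryPreset(name, dict(E=E_GEL, nu=NU, size=1.0,
                                           nx=5, ny=5))
    elif name == "cantilever":
        return ElementaryPreset(name, dict(E=1e6, nu=0.0, length=0.1,
                                           thickness=0.004, load=1e-4,
                                           nx=200, ny=10))
    elif name == "friction-block":
        return ElementaryPreset(name, dict(E=10e3, nu=0.3, size=0.02,
                                           friction=FRICTION, press=4e-4))
    elif name == "czm-strip":
        return ElementaryPreset(name, dict(G_c=G_C, sigma_max=SIGMA_MAX,
                                           rho_tip=RHO_TIP, b=B,
                                           length=1e-3))
    else:
        raise ValueError(f"unknown preset name: {name!r}")
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def synthetic_path(kind: str, params: dict | None = None,
                   seed: int | None = None) -> PenetrationPath:
    """Deterministic synthetic tip trajectories for the trajectory metrics.

    kinds
    -----
    - ``line``: straight vertical insertion.
    - ``arc``: circular arc of radius ``R`` (m), bending toward +x.
    - ``two-arc``: two arcs of radii ``R1``, ``R2`` joined tangentially at
      half depth.
    - ``noisy-arc``: ``arc`` plus isotropic Gaussian noise ``sigma`` (m).

    params defaults: R=0.25, R1=0.25, R2=0.1, depth=0.04, n=81, sigma=1e-5.
    """
    p = dict(R=0.25, R1=0.25, R2=0.1, depth=0.04, n=81, sigma=1e-5)
    if params:
        p.update(params)
    n = int(p["n"])
    depth = float(p["depth"])
    s = np.linspace(0.0, depth, n)        # arclength ~ imposed displacement
    if kind == "line":
        tip = np.column_stack([np.zeros(n), -s])
    elif kind in ("arc", "noisy-arc"):
        tip = _arc_from(np.array([0.0, 0.0]), np.array([0.0, -1.0]),
                        float(p["R"]), s)
        if kind == "noisy-arc":
            rng = np.random.default_rng(seed)
            tip = tip + rng.normal(0.0, float(p["sigma"]), size=tip.shape)
    elif kind == "two-arc":
        s1 = s[s <= depth / 2]
        s2 = s[s > depth / 2] - depth / 2
        first = _arc_from(np.array([0.0, 0.0]), np.array([0.0, -1.0]),
                          float(p["R1"]), s1)
        # tangent at the junction of arc 1
        phi = s1[-1] / float(p["R1"])
        tang = np.array([math.sin(phi), -math.cos(phi)])
        second = _arc_from(first[-1], tang, float(p["R2"]), s2)
        tip = np.vstack([first, second])
    else:
        raise ValueError(f"unknown synthetic path kind: {kind!r}")
    return PenetrationPath(D_e=s, tip=tip)


def _arc_from(start: np.ndarray, tangent: np.ndarray, R: float,
              s: np.ndarray) -> np.ndarray:
    """Arc of radius R from `start` with initial unit `tangent`, centre on
    the CCW side of the tangent (a downward start curves toward +x)."""
    centre = start + R * np.array([-tangent[1], tangent[0]])
    a0 = math.atan2(start[1] - centre[1], start[0] - centre[0])
    ang = a0 + s / R
    return centre + R * np.column_stack([np.cos(ang), np.sin(ang)])
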