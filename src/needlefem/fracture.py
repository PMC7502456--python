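"""Crack propagation and kinking criteria.

Two decisions drive the adaptive insertion algorithm:

*When* does the crack advance?  A crack-tip-opening-displacement (CTOD)
criterion: the normal separation of the crack faces, probed at a
characteristic arclength L_bar behind the equivalent crack tip, reaches
the peak-traction opening delta_max of the cohesive law.  The probe
distance is tied to the needle geometry,

    L_bar = rho_tip / tan(alpha),

and, for a law calibrated with delta_max = 2 rho_tip, coincides with the
additional compliance length of the elastic cohesive branch:

    L_bar = delta_max / (2 tan a) = sigma_max / (2 K tan a) = L_add.

*Where* does it go?  The minimum strain energy density (MSED) criterion:
strain energy densities sampled on a radial ring of elements around the
tip (in the deformed configuration) are interpolated over an admissible
angular range, and the crack kinks toward the interior minimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .cohesive import CohesiveLaw
from .geometry import point_at_arclength, polyline_lengths, rot90, unit


def characteristic_distance(rho_tip: float, alpha: float,
                            law: CohesiveLaw | None = None) -> float:
    """CTOD probe distance L_bar = rho_tip / tan(alpha).

    If a calibrated law (delta_max = 2 rho_tip) is supplied, the
    equivalent expressions delta_max / (2 tan a) and
    sigma_max / (2 K tan a) are asserted to agree to machine precision.
    """
    if not 0 < alpha < math.pi / 2:
        raise ValueError("bevel half-angle alpha must lie in (0, pi/2)")
    if rho_tip <= 0:
        raise ValueError("rho_tip must be positive")
    L = rho_tip / math.tan(alpha)
    if law is not None:
        alt1 = law.delta_max / (2.0 * math.tan(alpha))
        alt2 = law.sigma_max / (2.0 * law.K * math.tan(alpha))
        if not (math.isclose(L, alt1, rel_tol=1e-12)
                and math.isclose(L, alt2, rel_tol=1e-12)):
            raise ValueError(
                "law is not calibrated with delta_max = 2 rho_tip: "
                f"L_bar expressions disagree ({L} vs {alt1} vs {alt2})")
    return L


def ctod_at_distance(path_nodes: np.ndarray, openings: np.ndarray,
                     L_bar: float) -> float | None:
    """Normal crack-face opening at arclength L_bar behind the tip.

    Parameters
    ----------
    path_nodes : (N, 2) crack path coordinates from entry to tip
    openings : (N,) normal opening delta_n = (u+ - u-) . n at each path
        node (the tip itself carries 0 by construction); nodes without a
        duplicated pair (e.g. the entry node) may carry NaN and are
        bridged by interpolation of their neighbours.
    L_bar : probe arclength behind the tip (m)

    Returns
    -------
    The linearly interpolated opening, or None when the path is shorter
    than L_bar (criterion not yet evaluable).
    """
    pts = np.asarray(path_nodes, dtype=float)
    w = np.asarray(openings, dtype=float)
    seg = polyline_lengths(pts)
    total = float(seg.sum())
    if total < L_bar:
        return None
    s_probe = total - L_bar
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    good = ~np.isnan(w)
    if good.sum() < 2:
        return None
    return float(np.interp(s_probe, cum[good], w[good]))


def propagation_check(delta_n: float | None, law: CohesiveLaw) -> bool:
    """Crack advances when the probed CTOD reaches the critical opening
    delta_max (>= absorbs load-step discreteness)."""
    if delta_n is None:
        return False
    return delta_n >= law.delta_max


@dataclass(frozen=True)
class AdmissibleRange:
    """Symmetric angular window +-theta_lim (rad) about the current tip
    direction within which the crack may kink.  The default 75 deg stays
    below the pure-shear MSED kink limit (~80 deg for nu near 0.5)."""

    theta_lim: float = math.radians(75.0)

    def __post_init__(self) -> None:
        if not 0 < self.theta_lim < math.pi / 2 + 0.35:
            raise ValueError("theta_lim out of the sensible (0, ~110 deg) range")


def msed_kink_angle(angles: np.ndarray, sed: np.ndarray,
                    admissible: AdmissibleRange = AdmissibleRange(),
                    grid_step: float = math.radians(0.01)) -> float:
    """Kink angle theta_c minimising the interpolated strain energy density.

    Ring samples (angle relative to the current tip direction, SED value)
    are interpolated with a periodic cubic spline over the full circle,
    then minimised on a fine grid restricted to the admissible range; an
    interior minimum is required by the second-order condition, a
    boundary minimum is accepted with a warning.  A flat distribution
    ties toward straight continuation, theta_c = 0.

    Returns theta_c in radians, positive toward +x-side kinks.
    """
    th = np.asarray(angles, dtype=float)
    us = np.asarray(sed, dtype=float)
    if th.size < 5:
        raise ValueError("need at least 5 ring samples to interpolate the SED")
    if np.any(us < -1e-12 * max(1.0, float(np.max(np.abs(us))))):
        raise ValueError("strain energy density samples must be non-negative")
    if float(np.ptp(us)) <= 1e-12 * max(1.0, float(np.max(np.abs(us)))):
        warnings.warn("flat SED distribution: tie broken toward straight "
                      "continuation (theta_c = 0)", stacklevel=2)
        return 0.0
    # periodic spline over sorted angles in (-pi, pi]
    order = np.argsort(th)
    th_s = th[order]
    us_s = us[order]
    th_ext = np.concatenate([th_s, [th_s[0] + 2 * math.pi]])
    us_ext = np.concatenate([us_s, [us_s[0]]])
    spline = CubicSpline(th_ext, us_ext, bc_type="periodic")

    lim = admissible.theta_lim
    n = max(int(math.ceil(2 * lim / grid_step)), 11)
    grid = np.linspace(-lim, lim, n + 1)
    vals = spline(grid)
    k = int(np.argmin(vals))
    theta_c = float(grid[k])
    if k in (0, n):
        warnings.warn(
            f"SED minimum at the admissible-range boundary ({math.degrees(theta_c):.1f} deg)",
            stacklevel=2)
        return theta_c
    # one Newton polish on the spline derivative for sub-grid accuracy
    d1 = spline.derivative(1)
    d2 = spline.derivative(2)
    for _ in range(3):
        g = float(d1(theta_c))
        h = float(d2(theta_c))
        if h <= 0:
            break
        step = g / h
        if abs(step) > grid_step:
            break
        theta_c -= step
    return float(np.clip(theta_c, -lim, lim))


def ring_sed_samples(tip_def: np.ndarray, tip_dir_def: np.ndarray,
                     centroids_def: np.ndarray, sed: np.ndarray):
    """Convert deformed ring-element centroids + SED values into
    (angle-relative-to-tip-direction, SED) samples.

    Angles are the CCW signed angle from tip_dir to the centroid ray, so
    that rotate(tip_dir, theta_c) is the kinked direction; for a downward
    tip direction, positive angles lie on the +x side.
    """
    d = unit(np.asarray(tip_dir_def, dtype=float))
    rel = np.asarray(centroids_def, dtype=float) - np.asarray(tip_def, dtype=float)
    along = rel @ d
    across = rel @ rot90(d)        # = cross(tip_dir, rel)
    ang = np.arctan2(across, along)
    return ang, np.asarray(sed, dtype=float)
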