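"""Planar geometry primitives and the needle / substrate parametrisations.

Coordinate convention: the origin sits at the needle entry point on the
top surface of the substrate, the insertion axis is vertical and the
needle advances in -y.  Lateral steering deflection is measured along +x,
toward the side of the withdrawn (shorter) segment of a programmable
bevel-tip needle.  All lengths in metres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString


# ---------------------------------------------------------------------------
# basic vector helpers (2D, float64)

def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.hypot(v[0], v[1]))
    if n == 0.0:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def rot90(v: np.ndarray) -> np.ndarray:
    """Rotate a 2-vector by +90 degrees (counter-clockwise)."""
    return np.array([-v[1], v[0]], dtype=float)


def rotate(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]], dtype=float)


def angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Signed angle from a to b, in (-pi, pi]."""
    return math.atan2(a[0] * b[1] - a[1] * b[0], a[0] * b[0] + a[1] * b[1])


# ---------------------------------------------------------------------------
# polyline utilities

def polyline_lengths(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    return np.hypot(*(pts[1:] - pts[:-1]).T)


def polyline_arclength(points: np.ndarray) -> float:
    return float(polyline_lengths(points).sum())


def point_at_arclength(points: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Point, unit tangent, segment index and local coordinate at arclength s.

    Arclength is measured from the first point.  s is clamped to the
    polyline extent.
    """
    pts = np.asarray(points, dtype=float)
    seg = polyline_lengths(pts)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = min(max(s, 0.0), float(cum[-1]))
    i = int(np.searchsorted(cum[1:], s, side="left"))
    i = min(i, len(seg) - 1)
    t = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    p = pts[i] + t * (pts[i + 1] - pts[i])
    tang = unit(pts[i + 1] - pts[i])
    return p, tang, i, t


def is_simple_polyline(points: np.ndarray) -> bool:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return True
    return LineString(pts).is_simple


# ---------------------------------------------------------------------------
# needle parametrisation

@dataclass(frozen=True)
class NeedleSpec:
    """Programmable bevel-tip needle (PBN), reduced to the steering plane.

    Two interlocked segment pairs of width b/2 slide axially; the
    programmable offset c is the lead of one pair over the other, which
    sets the unsupported tip length and hence the steering curvature.

    Parameters
    ----------
    b : outer diameter (m)
    alpha : half bevel angle (rad); the total tip wedge spans 2*alpha
    c : programmable offset (m); c = 0 is the symmetric needle
    rho_tip : tip radius (m), a measure of tip sharpness
    E : Young's modulus of the needle material (Pa)
    nu : Poisson ratio
    length : shaft length above the tip (m)
    """

    b: float
    alpha: float
    c: float = 0.0
    rho_tip: float = 0.5e-3
    E: float = 236.8e3
    nu: float = 0.475
    length: float = 0.12

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("needle diameter b must be positive")
        if not 0 < self.alpha < math.pi / 2:
            raise ValueError("half bevel angle alpha must lie in (0, pi/2)")
        if self.c < 0:
            raise ValueError("programmable offset c must be non-negative")
        if not 0 < self.rho_tip < self.b / 2:
            raise ValueError("tip radius must satisfy 0 < rho_tip < b/2")

    @property
    def wedge_half_angle(self) -> float:
        """Half opening angle of the tip wedge: alpha for the symmetric
        tip (full wedge 2*alpha), alpha/2 for the PBN (wedge between the
        inner vertical face and the bevel face)."""
        return self.alpha if self.c == 0.0 else 0.5 * self.alpha

    @property
    def fillet_center_distance(self) -> float:
        """Distance from the theoretical wedge apex to the centre of the
        tangent tip fillet, rho_tip / sin(half wedge angle)."""
        return self.rho_tip / math.sin(self.wedge_half_angle)

    @property
    def tip_bottom_offset(self) -> np.ndarray:
        """Vector from the theoretical apex to the lowest material point
        of the filleted tip.  A tangent fillet on a slender wedge
        truncates the tip substantially (~2.4 mm for the standard
        geometry), so the distinction matters everywhere."""
        if self.c == 0.0:
            bis = np.array([0.0, 1.0])
        else:
            half = self.alpha / 2.0
            bis = np.array([-math.sin(half), math.cos(half)])
        centre = self.fillet_center_distance * bis
        return centre - np.array([0.0, self.rho_tip])

    def apex_for_bottom(self, bottom: np.ndarray) -> np.ndarray:
        """Theoretical apex position placing the material bottom of the
        tip at `bottom`."""
        return np.asarray(bottom, dtype=float) - self.tip_bottom_offset

    @property
    def bevel_bisector(self) -> np.ndarray:
        """Unit direction of the bevel-angle bisector at the tip.

        For the symmetric tip the wedge spans +-alpha about -y and the
        bisector is vertical.  For the PBN the leading-segment wedge is
        bounded by the inner vertical face and the bevel face; its
        bisector is tilted by alpha/2 toward the steering side (+x).
        """
        if self.c == 0.0:
            return np.array([0.0, -1.0])
        half = self.alpha / 2.0
        return np.array([math.sin(half), -math.cos(half)])

    def tip_apex(self, insertion_depth: float = 0.0) -> np.ndarray:
        """Reference position of the tip apex for a straight, undeformed
        needle whose apex has advanced `insertion_depth` below the surface."""
        return np.array([0.0, -insertion_depth])

    def outline(self, tip_y: float, n_arc: int = 6) -> np.ndarray:
        """Closed outline polygon (CCW) of the undeformed needle.

        The apex sits at (x_apex, tip_y).  The leading segment occupies
        x in [-b/2, 0] (its bevel face slopes up-left at angle alpha from
        the vertical axis); the withdrawn segment occupies x in [0, b/2]
        and its bevel starts c higher.  The apex is filleted with a
        circular arc of radius rho_tip.
        """
        b, a, c = self.b, self.alpha, self.c
        top = tip_y + self.length
        if c == 0.0:
            # symmetric V tip: faces at +-alpha about vertical
            fil = _fillet_wedge(np.array([0.0, tip_y]),
                                np.array([math.sin(a), math.cos(a)]),
                                np.array([-math.sin(a), math.cos(a)]),
                                self.rho_tip, n_arc)
            rise = (b / 2) / math.tan(a)
            # fil runs from the +x bevel face to the -x bevel face
            return ensure_ccw(np.array(list(fil) +
                              [np.array([-b / 2, tip_y + rise]),
                               np.array([-b / 2, top]),
                               np.array([b / 2, top]),
                               np.array([b / 2, tip_y + rise])]))
        # PBN: apex at x=0 on the leading (left) segment; bevel face slopes
        # up-left; the withdrawn (right) segment tip starts c above.
        rise_lead = (b / 2) / math.tan(a)
        fil = _fillet_wedge(np.array([0.0, tip_y]),
                            np.array([0.0, 1.0]),
                            np.array([-math.sin(a), math.cos(a)]),
                            self.rho_tip, n_arc)
        y_right_tip = tip_y + c
        outline = list(fil)  # starts on inner (vertical) face side, ends on bevel face side
        outline += [np.array([-b / 2, tip_y + rise_lead]),
                    np.array([-b / 2, top])]
        outline += [np.array([b / 2, top]),
                    np.array([b / 2, y_right_tip + rise_lead]),
                    np.array([0.0, y_right_tip])]
        return ensure_ccw(np.array(outline))


def signed_area(poly: np.ndarray) -> float:
    x, y = np.asarray(poly, dtype=float).T
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(poly: np.ndarray) -> np.ndarray:
    return poly if signed_area(poly) > 0 else poly[::-1].copy()


def _fillet_wedge(apex: np.ndarray, d1: np.ndarray, d2: np.ndarray,
                  rho: float, n_arc: int) -> list[np.ndarray]:
    """Fillet the wedge with apex `apex` and upward face directions d1, d2
    (unit vectors pointing away from the apex) with a circular arc of
    radius rho.  Returns points running from the d1 face to the d2 face,
    ordered CCW for a downward-pointing wedge with d1 on the +x side."""
    d1, d2 = unit(d1), unit(d2)
    half = 0.5 * abs(angle_between(d1, d2))
    if half <= 0 or half >= math.pi / 2:
        raise ValueError("degenerate wedge for fillet")
    bis = unit(d1 + d2)
    dist = rho / math.sin(half)      # apex -> fillet centre
    centre = apex + dist * bis
    t1 = apex + (dist * math.cos(half)) * d1   # tangency on face 1
    t2 = apex + (dist * math.cos(half)) * d2
    a1 = math.atan2(t1[1] - centre[1], t1[0] - centre[0])
    a2 = math.atan2(t2[1] - centre[1], t2[0] - centre[0])
    # sweep the short way round
    da = (a2 - a1 + math.pi) % (2 * math.pi) - math.pi
    angles = a1 + da * np.linspace(0.0, 1.0, n_arc + 1)
    # snap the nearest sample to the exact arc bottom so the material
    # tip has a vertex at its lowest point (it nests into the notch)
    bottom = -math.pi / 2
    rel = (bottom - a1) / da if da != 0 else -1.0
    if 0.0 < rel < 1.0:
        k = int(np.argmin(np.abs(angles - (a1 + rel * da))))
        if 0 < k < len(angles) - 1:
            angles[k] = a1 + rel * da
    return [centre + rho * np.array([math.cos(t), math.sin(t)]) for t in angles]


# ---------------------------------------------------------------------------
# substrate domain

@dataclass(frozen=True)
class DomainSpec:
    """Rectangular substrate block with a refined inner meshing corridor.

    The block occupies x in [-half_width, half_width], y in [-height, 0].
    The inner rectangle must contain the planned insertion corridor; the
    crack-tip ring lives inside it.  h_tip defaults to 0.5 * rho_tip.
    """

    half_width: float = 0.1175
    height: float = 0.245
    inner_half_width: float = 0.03
    inner_depth: float = 0.08
    h_tip: float = 0.25e-3
    h_inner: float = 2.0e-3
    h_outer: float = 0.02
    ring_radius_factor: float = 2.0   # ring radius = factor * h_tip
    ring_sectors: int = 16
    notch_depth_factor: float = 2.0   # notch depth = factor * rho_tip

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.height <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.inner_half_width > self.half_width or self.inner_depth > self.height:
            raise ValueError("inner region must lie inside the domain")
        if not (0 < self.h_tip <= self.h_inner <= self.h_outer):
            raise ValueError("element sizes must satisfy 0 < h_tip <= h_inner <= h_outer")

    @property
    def ring_radius(self) -> float:
        return self.ring_radius_factor * self.h_tip

    @classmethod
    def for_needle(cls, needle: NeedleSpec, **overrides) -> "DomainSpec":
        """Default domain sized for the standard gelatine block, with
        h_tip = 0.5 * rho_tip."""
        defaults = dict(h_tip=0.5 * needle.rho_tip)
        defaults.update(overrides)
        return cls(**defaults)
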