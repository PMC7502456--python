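"""Trajectory metrics: circle fits, curvature and tip angle.

The steering performance of a bevel-tip needle is summarised by the
radius of curvature R of the tip-node path and the tip angle theta_tip
(between the local path tangent and the vertical insertion axis).  R is
estimated with the hyper-accurate algebraic circle fit ("Hyper" fit of
Al-Sharadqah & Chernov): the algebraic distance is minimised under a
bias-cancelling normalisation, which removes the leading-order
essential bias of plain algebraic (Kasa/Pratt/Taubin) fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .geometry import rot90, unit


@dataclass(frozen=True)
class CurvatureEstimate:
    """Circle-fit summary of a (portion of a) penetration path.

    R is the fitted radius (m), infinite for a straight path; curvature
    is 1/R with the sign convention: positive when the path bends toward
    +x (centre on the -x side).  theta_tip is the signed angle (rad)
    between the forward tangent at the deepest fitted point and the
    vertical insertion axis, positive toward +x.
    """

    R: float
    center: tuple[float, float] | None
    theta_tip: float
    residual: float
    signed_curvature: float = 0.0

    @property
    def is_straight(self) -> bool:
        return not math.isfinite(self.R)

    @property
    def curvature(self) -> float:
        return 0.0 if self.is_straight else 1.0 / self.R


def fit_hyper_circle(points: np.ndarray,
                     collinear_rtol: float = 1e-9) -> CurvatureEstimate:
    """Hyper-accurate algebraic circle fit.

    Solves the generalized eigenproblem M A = eta H A for the algebraic
    circle A1 (x^2+y^2) + A2 x + A3 y + A4 = 0, where M is the moment
    matrix of [z, x, y, 1] and H the hyper (bias-cancelling) constraint
    matrix; the solution is the eigenvector of the smallest non-negative
    eigenvalue.  Data are centred and scaled first for conditioning.

    Collinear input returns an infinite-radius estimate (curvature 0)
    rather than raising.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 planar points")
    mean = pts.mean(axis=0)
    xy = pts - mean
    scale = float(np.sqrt((xy ** 2).sum(axis=1).mean()))
    if scale == 0:
        raise ValueError("all points coincide")
    xy = xy / scale

    # collinearity check on the centred covariance
    sv = np.linalg.svd(xy, compute_uv=False)
    if sv[-1] <= collinear_rtol * sv[0]:
        return _line_estimate(pts)

    x, y = xy.T
    z = x * x + y * y
    Z = np.column_stack([z, x, y, np.ones_like(x)])
    M = Z.T @ Z / len(pts)
    zm, xm, ym = z.mean(), x.mean(), y.mean()
    H = np.array([[8 * zm, 4 * xm, 4 * ym, 2.0],
                  [4 * xm, 1.0, 0.0, 0.0],
                  [4 * ym, 0.0, 1.0, 0.0],
                  [2.0, 0.0, 0.0, 0.0]])
    eigvals, eigvecs = scipy.linalg.eig(M, H)
    eigvals = np.real_if_close(eigvals, tol=1e6)
    real = np.isfinite(eigvals.real) & (np.abs(eigvals.imag) <=
                                        1e-8 * np.maximum(1.0, np.abs(eigvals.real)))
    candidates = np.where(real & (eigvals.real > -1e-12))[0]
    if candidates.size == 0:
        return _line_estimate(pts)
    best = candidates[np.argmin(eigvals.real[candidates])]
    A = np.real(eigvecs[:, best])
    if abs(A[0]) < 1e-14:
        return _line_estimate(pts)

    cx = -A[1] / (2 * A[0])
    cy = -A[2] / (2 * A[0])
    rad2 = cx * cx + cy * cy - A[3] / A[0]
    if rad2 <= 0:
        return _line_estimate(pts)
    R = math.sqrt(rad2) * scale
    center = mean + scale * np.array([cx, cy])
    r = np.hypot(*(pts - center).T)
    residual = float(np.sqrt(np.mean((r - R) ** 2)))
    theta_tip, sign = _tip_angle_circle(pts, center)
    return CurvatureEstimate(R=R, center=(float(center[0]), float(center[1])),
                             theta_tip=theta_tip, residual=residual,
                             signed_curvature=sign / R)


def _line_estimate(pts: np.ndarray) -> CurvatureEstimate:
    mean = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - mean)
    d = vt[0]
    if d[1] > 0:           # forward = downward (-y)
        d = -d
    theta = math.atan2(d[0], -d[1])
    resid = float(np.sqrt(np.mean(((pts - mean) @ rot90(d)) ** 2)))
    return CurvatureEstimate(R=math.inf, center=None, theta_tip=theta,
                             residual=resid, signed_curvature=0.0)


def _tip_angle_circle(pts: np.ndarray, center: np.ndarray) -> tuple[float, float]:
    """Signed tangent angle at the deepest fitted point, plus the
    curvature sign (+1 when the path bends toward +x)."""
    tip = pts[np.argmin(pts[:, 1])]
    radial = unit(tip - center)
    tang = rot90(radial)
    if tang[1] > 0:        # forward tangent points downward
        tang = -tang
    theta = math.atan2(tang[0], -tang[1])
    # centre on the -x side of the forward tangent => bending toward +x
    # the path always bends toward the circle centre
    v = center - tip
    side = float(np.sign(tang[0] * v[1] - tang[1] * v[0]))
    return theta, side if side != 0 else 1.0


@dataclass
class PenetrationPath:
    """Tip-node trajectory versus imposed needle displacement.

    Attributes
    ----------
    D_e : (N,) imposed displacement history (m), non-decreasing
    tip : (N, 2) tip-node positions (m)
    """

    D_e: np.ndarray
    tip: np.ndarray

    def __post_init__(self) -> None:
        self.D_e = np.asarray(self.D_e, dtype=float)
        self.tip = np.asarray(self.tip, dtype=float)
        if self.D_e.ndim != 1 or self.tip.shape != (self.D_e.size, 2):
            raise ValueError("D_e must be (N,), tip must be (N, 2)")
        if np.any(np.diff(self.D_e) < -1e-15):
            raise ValueError("D_e must be non-decreasing")

    @property
    def depth(self) -> np.ndarray:
        """Tip penetration depth D (m, positive downward)."""
        return self.tip[0, 1] - self.tip[:, 1]

    @property
    def deflection(self) -> np.ndarray:
        """Lateral tip deflection Delta (m, positive toward +x)."""
        return self.tip[:, 0] - self.tip[0, 0]

    def relative(self, c: float) -> np.ndarray:
        """(D/c, Delta/c) pairs for offset c."""
        if c <= 0:
            raise ValueError("relative coordinates require a positive offset c")
        return np.column_stack([self.depth / c, self.deflection / c])


def curvature_at_depth(path: PenetrationPath, c: float) -> CurvatureEstimate:
    """Constant-curvature hyper-circle fit of the tip path up to D_e = 2c.

    The curvature the steering law is characterised by: fitted over the
    whole trajectory from entry until the imposed displacement reaches
    twice the programmable offset.
    """
    if c <= 0:
        raise ValueError("offset c must be positive")
    target = 2.0 * c
    if path.D_e[-1] + 1e-15 < target:
        raise ValueError(
            f"path reaches D_e = {path.D_e[-1]:.6g} m but D_e = 2c = "
            f"{target:.6g} m is required")
    mask = path.D_e <= target * (1 + 1e-12)
    return fit_hyper_circle(path.tip[mask])


def curvature_vs_depth(path: PenetrationPath, span: float = 5e-3,
                       min_points: int = 3) -> np.ndarray:
    """Sliding-window curvature evolution.

    For each sample with D_e >= span, the hyper circle is fitted to the
    tip positions inside the trailing window [D_e - span, D_e].  Windows
    with fewer than `min_points` points are skipped with a warning.

    Returns an (M, 2) array of (D_e, curvature 1/R).
    """
    out = []
    skipped = 0
    for i, de in enumerate(path.D_e):
        if de < span:
            continue
        mask = (path.D_e >= de - span) & (path.D_e <= de)
        if mask.sum() < min_points:
            skipped += 1
            continue
        est = fit_hyper_circle(path.tip[mask])
        out.append((de, est.curvature))
    if skipped:
        warnings.warn(f"{skipped} window(s) had fewer than {min_points} "
                      "points and were skipped", stacklevel=2)
    return np.array(out).reshape(-1, 2)
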