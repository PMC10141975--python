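"""Conic-form ellipse representation and algebraic-distance least squares.

An ellipse is represented implicitly by the conic

    A x^2 + B x y + C y^2 + D x + E y + F = 0,   B^2 - 4AC < 0,

with the coefficient vector ``s = (A, B, C, D, E, F)`` defined up to scale.
The algebraic distance of a point ``(x, y)`` to the conic is the value of the
left-hand side, i.e. ``H . s`` with ``H = (x^2, xy, y^2, x, y, 1)``.  Fitting
minimizes the sum of squared algebraic distances over a point set subject to
the ellipse-specific constraint ``4AC - B^2 = 1``, which guarantees that the
minimizer is an ellipse (a pure norm constraint can return a hyperbola and
the unconstrained problem collapses to ``s = 0``).  The solver is the
numerically stable partitioned form of the direct least-squares fit; input
points are centered and scaled to unit RMS radius before the scatter matrix
is built, and coefficients are mapped back afterwards, so raw pixel
coordinates in the thousands remain well conditioned.

Coordinates are continuous and 0-based with ``x`` = column and ``y`` = row;
pixel centers sit at integer coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateConicError, EllipseFitError, InvalidConicError

__all__ = [
    "PlanePoint",
    "ConicCoefficients",
    "EllipseParams",
    "algebraic_distance",
    "fit_ellipse",
    "conic_to_params",
    "params_to_conic",
    "long_axis_endpoints",
]


@dataclass(frozen=True)
class PlanePoint:
    """A continuous 2-D point in pixel units (x = column, y = row)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"point coordinates must be finite, got {(self.x, self.y)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class ConicCoefficients:
    """The six implicit-conic coefficients ``(A, B, C, D, E, F)``.

    Scale invariant: ``c * s`` denotes the same conic for any ``c != 0``.
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float

    def __post_init__(self) -> None:
        vec = self.as_array()
        if not np.all(np.isfinite(vec)):
            raise InvalidConicError("conic coefficients must be finite")
        if np.all(vec == 0.0):
            raise InvalidConicError("all six conic coefficients are zero")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D, self.E, self.F], dtype=float)

    @property
    def discriminant(self) -> float:
        """``B^2 - 4AC``; negative for ellipses."""
        return self.B * self.B - 4.0 * self.A * self.C

    def is_ellipse(self) -> bool:
        return self.discriminant < 0.0

    def normalized(self) -> "ConicCoefficients":
        """Unit-norm representative with ``A + C > 0`` (sign convention)."""
        vec = self.as_array()
        vec = vec / np.linalg.norm(vec)
        if vec[0] + vec[2] < 0:
            vec = -vec
        return ConicCoefficients(*vec)


@dataclass(frozen=True)
class EllipseParams:
    """Parametric ellipse: center ``(cx, cy)``, semi-axes ``a >= b > 0``
    (pixels), and major-axis rotation ``theta`` in radians within ``[0, pi)``.
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.cx, self.cy, self.a, self.b, self.theta))):
            raise ValueError("ellipse parameters must be finite")
        if not self.a >= self.b > 0:
            raise ValueError(f"require a >= b > 0, got a={self.a}, b={self.b}")
        if not 0.0 <= self.theta < math.pi:
            raise ValueError(f"theta must lie in [0, pi), got {self.theta}")

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    def translated(self, dx: float, dy: float) -> "EllipseParams":
        return EllipseParams(self.cx + dx, self.cy + dy, self.a, self.b, self.theta)


def _design_row(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])


def algebraic_distance(p: PlanePoint | Sequence[float], c: ConicCoefficients) -> float:
    """Value of the implicit conic polynomial at ``p`` (``H . s``).

    Zero exactly when the point lies on the conic; the sign tells interior
    from exterior once the coefficient sign convention is fixed.
    """
    if isinstance(p, PlanePoint):
        x, y = p.x, p.y
    else:
        x, y = float(p[0]), float(p[1])
    s = c.as_array()
    return float(x * x * s[0] + x * y * s[1] + y * y * s[2] + x * s[3] + y * s[4] + s[5])


def _as_xy(points: Iterable) -> np.ndarray:
    rows = []
    for p in points:
        if isinstance(p, PlanePoint):
            rows.append((p.x, p.y))
        else:
            rows.append((float(p[0]), float(p[1])))
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise EllipseFitError("points must be a sequence of (x, y) pairs")
    return arr


def fit_ellipse(points: Iterable) -> ConicCoefficients:
    """Direct least-squares ellipse fit by algebraic-distance minimization.

    Solves ``min_s sum_i (H_i . s)^2`` subject to ``4AC - B^2 = 1`` using the
    partitioned (Halíř–Flusser) reduction of the constrained generalized
    eigenproblem, after centering and scaling the points to unit RMS radius.

    Parameters
    ----------
    points : sequence of PlanePoint or (x, y) pairs
        At least 6 points, not all collinear.

    Returns
    -------
    ConicCoefficients
        Unit-norm coefficients with ``B^2 - 4AC < 0``.

    Raises
    ------
    EllipseFitError
        Fewer than 6 points, rank-deficient design (e.g. collinear points),
        or no real elliptical solution.
    """
    xy = _as_xy(points)
    n = xy.shape[0]
    if n < 6:
        raise EllipseFitError(f"need at least 6 points to constrain a conic, got {n}")

    mean = xy.mean(axis=0)
    centered = xy - mean
    rms = float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
    if rms <= 0:
        raise EllipseFitError("degenerate point set: all points coincide")
    u = centered / rms

    d1 = np.column_stack([u[:, 0] ** 2, u[:, 0] * u[:, 1], u[:, 1] ** 2])
    d2 = np.column_stack([u[:, 0], u[:, 1], np.ones(n)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("rank-deficient design matrix (collinear points?)") from exc
    m = s1 + s2 @ t
    # Apply inv(C1) for the constraint block C1 = [[0,0,2],[0,-1,0],[2,0,0]].
    m_red = np.vstack([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m_red)

    design = _design_row(u[:, 0], u[:, 1])
    scatter = design.T @ design
    best = None
    for k in range(3):
        if abs(eigval[k].imag) > 1e-8 * (1.0 + abs(eigval[k].real)):
            continue
        v = np.real(eigvec[:, k])
        cond = 4.0 * v[0] * v[2] - v[1] ** 2
        if cond <= 0:
            continue
        v = v / math.sqrt(cond)  # enforce 4AC - B^2 = 1 in normalized frame
        full = np.concatenate([v, t @ v])
        cost = float(full @ scatter @ full)
        if best is None or cost < best[0]:
            best = (cost, full)
    if best is None:
        raise EllipseFitError("constrained solution is not an ellipse")

    a_, b_, c_, d_, e_, f_ = best[1]
    # Undo u = (p - mean)/rms: substitute and collect original-frame terms.
    mx, my = mean
    s = rms
    A = a_
    B = b_
    C = c_
    D = -2.0 * a_ * mx - b_ * my + d_ * s
    E = -b_ * mx - 2.0 * c_ * my + e_ * s
    F = (
        a_ * mx * mx
        + b_ * mx * my
        + c_ * my * my
        - d_ * s * mx
        - e_ * s * my
        + f_ * s * s
    )
    conic = ConicCoefficients(A, B, C, D, E, F).normalized()
    if not conic.is_ellipse():
        raise EllipseFitError("fit produced a non-elliptical conic")
    return conic


def conic_to_params(c: ConicCoefficients) -> EllipseParams:
    """Closed-form conversion of an elliptical conic to parametric form.

    Raises
    ------
    DegenerateConicError
        ``B^2 - 4AC >= 0`` or the locus is a point / imaginary ellipse.
    """
    if not c.is_ellipse():
        raise DegenerateConicError(
            f"discriminant B^2-4AC = {c.discriminant:.3g} is not negative"
        )
    A, B, C, D, E, F = c.as_array()
    quad = np.array([[A, B / 2.0], [B / 2.0, C]])
    try:
        center = np.linalg.solve(quad, [-D / 2.0, -E / 2.0])
    except np.linalg.LinAlgError as exc:  # pragma: no cover - disc<0 implies invertible
        raise DegenerateConicError("singular quadratic part") from exc
    cx, cy = center
    # Constant term after translating the center to the origin.
    f0 = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    w, v = np.linalg.eigh(quad)  # ascending eigenvalues
    radii_sq = -f0 / w
    if np.any(radii_sq <= 0) or not np.all(np.isfinite(radii_sq)):
        raise DegenerateConicError("point or imaginary ellipse: no real semi-axes")
    radii = np.sqrt(radii_sq)
    # Smaller eigenvalue of the quadratic form -> larger radius -> major axis.
    order = np.argsort(radii)[::-1]
    a, b = radii[order[0]], radii[order[1]]
    major = v[:, order[0]]
    theta = math.atan2(major[1], major[0]) % math.pi
    if a == b:
        theta = 0.0  # circle: rotation is arbitrary, pick the canonical one
    return EllipseParams(float(cx), float(cy), float(a), float(b), float(theta))


def params_to_conic(e: EllipseParams) -> ConicCoefficients:
    """Inverse of :func:`conic_to_params`; returns the unit-norm conic."""
    ct, st = math.cos(e.theta), math.sin(e.theta)
    ia2, ib2 = 1.0 / (e.a * e.a), 1.0 / (e.b * e.b)
    A = ct * ct * ia2 + st * st * ib2
    B = 2.0 * ct * st * (ia2 - ib2)
    C = st * st * ia2 + ct * ct * ib2
    D = -2.0 * A * e.cx - B * e.cy
    E = -B * e.cx - 2.0 * C * e.cy
    F = A * e.cx * e.cx + B * e.cx * e.cy + C * e.cy * e.cy - 1.0
    return ConicCoefficients(A, B, C, D, E, F).normalized()


def long_axis_endpoints(e: EllipseParams) -> tuple[PlanePoint, PlanePoint]:
    """The two points where the major axis meets the ellipse.

    Ordered deterministically: the first endpoint has the smaller ``y``
    coordinate, ties broken by the smaller ``x``.
    """
    dx, dy = e.a * math.cos(e.theta), e.a * math.sin(e.theta)
    p1 = PlanePoint(e.cx - dx, e.cy - dy)
    p2 = PlanePoint(e.cx + dx, e.cy + dy)
    if (p1.y, p1.x) <= (p2.y, p2.x):
        return p1, p2
    return p2, p1
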