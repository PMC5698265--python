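"""Planar geometry primitives shared by the virtual microtome and the probes.

All coordinates are float64 and expressed in micrometres. Ellipses and
convex polygons are *closed* regions: boundary contact counts as inside,
consistently with the tie rule used by every counting operation. A small
relative tolerance ``EPS_TIE`` absorbs floating-point noise on those ties.

Both :class:`Ellipse` and :class:`ConvexPolygon` implement the informal
"planar field" protocol used by the probe layer:

* ``area``                      -- exact area of the region
* ``bbox()``                    -- axis-aligned bounding box
* ``contains(points)``          -- vectorised membership test
* ``clip_line(p0, direction)``  -- parameter interval of the line inside
                                   the region (or ``None``)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPS_TIE",
    "Ellipse",
    "ConvexPolygon",
    "rotation_matrix",
    "segment_min_distance",
]

#: relative slack on quadratic-form / half-plane boundary ties
EPS_TIE = 1e-9


def rotation_matrix(angle: float) -> np.ndarray:
    """2x2 counter-clockwise rotation matrix."""
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class Ellipse:
    """A (possibly rotated) closed ellipse in the section plane.

    Parameters
    ----------
    center : (2,) array-like
        Centre in in-plane micrometres.
    a : float
        Semi-major axis (μm); ``a >= b > 0``.
    b : float
        Semi-minor axis (μm).
    angle : float
        Orientation of the major axis, radians CCW from the +x axis.
    """

    center: np.ndarray
    a: float
    b: float
    angle: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not (self.a > 0 and self.b > 0):
            raise ValueError("ellipse semi-axes must be positive")
        if self.b > self.a * (1 + EPS_TIE):
            raise ValueError("semi-minor axis exceeds semi-major axis")

    # -- unit axes ---------------------------------------------------------
    @property
    def _axes(self) -> tuple[np.ndarray, np.ndarray]:
        c, s = math.cos(self.angle), math.sin(self.angle)
        return np.array([c, s]), np.array([-s, c])

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    @property
    def perimeter(self) -> float:
        """Exact circumference via the complete elliptic integral."""
        from scipy.special import ellipe

        m = 1.0 - (self.b / self.a) ** 2
        return 4.0 * self.a * float(ellipe(m))

    def bbox(self) -> np.ndarray:
        """((xmin, xmax), (ymin, ymax)) of the tight axis-aligned box."""
        c, s = math.cos(self.angle), math.sin(self.angle)
        ex = math.hypot(self.a * c, self.b * s)
        ey = math.hypot(self.a * s, self.b * c)
        cx, cy = self.center
        return np.array([[cx - ex, cx + ex], [cy - ey, cy + ey]])

    def quadratic_value(self, points: np.ndarray) -> np.ndarray:
        """Quadratic form value; <= 1 inside, == 1 on the boundary."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        u, v = self._axes
        return (pts @ u / self.a) ** 2 + (pts @ v / self.b) ** 2

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorised closed-region membership (boundary counts)."""
        val = self.quadratic_value(points)
        out = val <= 1.0 + EPS_TIE
        if np.asarray(points).ndim == 1:
            return out[0]
        return out

    # -- line interactions -------------------------------------------------
    def line_coefficients(self, p0, direction) -> tuple[float, float, float]:
        """Coefficients (A, B, C) of f(t) = A t^2 + B t + C with
        f(t) = Q(p0 + t d) - 1, so f(t) <= 0 inside the ellipse."""
        p0 = np.asarray(p0, dtype=float)
        d = np.asarray(direction, dtype=float)
        u, v = self._axes
        w = p0 - self.center
        au, bu = w @ u, d @ u
        av, bv = w @ v, d @ v
        A = (bu / self.a) ** 2 + (bv / self.b) ** 2
        B = 2.0 * (au * bu / self.a**2 + av * bv / self.b**2)
        C = (au / self.a) ** 2 + (av / self.b) ** 2 - 1.0
        return A, B, C

    def line_roots(self, p0, direction):
        """Parameters where the line crosses the boundary, or None.

        Returns ``(t_lo, t_hi)`` with ``t_lo <= t_hi``; equal on tangency.
        """
        A, B, C = self.line_coefficients(p0, direction)
        if A <= 0.0:  # degenerate direction
            return None
        disc = B * B - 4.0 * A * C
        if disc < 0.0:
            # grazing tangency may round below zero; ties count as touching
            if disc > -1e-12 * max(B * B, abs(4.0 * A * C)):
                t = -B / (2 * A)
                return (t, t)
            return None
        sq = math.sqrt(disc)
        return ((-B - sq) / (2 * A), (-B + sq) / (2 * A))

    def clip_line(self, p0, direction):
        """Interval of line parameters inside the closed ellipse (or None)."""
        return self.line_roots(p0, direction)

    def clip_lines_batch(self, offsets: np.ndarray, m: np.ndarray,
                         d: np.ndarray):
        """Vectorised :meth:`clip_line` for the family offsets[i]*m + t d;
        returns (t_lo, t_hi, valid)."""
        c = np.asarray(offsets, dtype=float)
        u, v = self._axes
        au = (c * (m @ u) - self.center @ u) / self.a
        av = (c * (m @ v) - self.center @ v) / self.b
        bu = (d @ u) / self.a
        bv = (d @ v) / self.b
        A = bu * bu + bv * bv
        B = 2.0 * (au * bu + av * bv)
        C = au * au + av * av - 1.0
        disc = B * B - 4.0 * A * C
        valid = (disc >= 0.0) & (A > 0)
        sq = np.sqrt(np.where(valid, disc, 0.0))
        t_lo = np.where(valid, (-B - sq) / (2 * A), 0.0)
        t_hi = np.where(valid, (-B + sq) / (2 * A), 0.0)
        return t_lo, t_hi, valid

    def boundary_crossings(self, p0, direction, t_lo: float, t_hi: float,
                           tol: float = 1e-9) -> int:
        """Number of boundary crossings with parameter in [t_lo, t_hi].

        Tangency (double root) counts once.
        """
        roots = self.line_roots(p0, direction)
        if roots is None:
            return 0
        r1, r2 = roots
        scale = max(1.0, abs(r1), abs(r2))
        if (r2 - r1) <= tol * scale:  # tangency
            return 1 if t_lo - tol * scale <= r1 <= t_hi + tol * scale else 0
        n = 0
        for r in (r1, r2):
            if t_lo - tol * scale <= r <= t_hi + tol * scale:
                n += 1
        return n

    def touches_segment(self, p, q) -> bool:
        """True iff the closed segment pq meets the closed ellipse."""
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        if self.contains(p) or self.contains(q):
            return True
        roots = self.line_roots(p, q - p)
        if roots is None:
            return False
        r1, r2 = roots
        return r1 <= 1.0 + EPS_TIE and r2 >= -EPS_TIE

    def touches_ray(self, p, direction) -> bool:
        """True iff the ray p + t d (t >= 0) meets the closed ellipse."""
        p = np.asarray(p, dtype=float)
        if self.contains(p):
            return True
        roots = self.line_roots(p, direction)
        if roots is None:
            return False
        return roots[1] >= -EPS_TIE

    def intersects_rect(self, x0: float, y0: float, w: float, h: float) -> bool:
        """True iff the closed ellipse meets the closed axis-aligned
        rectangle [x0, x0+w] x [y0, y0+h]."""
        cx, cy = self.center
        if x0 - EPS_TIE <= cx <= x0 + w + EPS_TIE and \
           y0 - EPS_TIE <= cy <= y0 + h + EPS_TIE:
            return True
        corners = [(x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h)]
        for i in range(4):
            if self.touches_segment(corners[i], corners[(i + 1) % 4]):
                return True
        return False

    def inside_rect(self, x0: float, y0: float, w: float, h: float) -> bool:
        """True iff the ellipse lies entirely within the closed rectangle."""
        (xmin, xmax), (ymin, ymax) = self.bbox()
        return (xmin >= x0 - EPS_TIE and xmax <= x0 + w + EPS_TIE and
                ymin >= y0 - EPS_TIE and ymax <= y0 + h + EPS_TIE)


@dataclass(frozen=True)
class ConvexPolygon:
    """Closed convex polygon with CCW-ordered vertices."""

    vertices: np.ndarray = field()

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("need >= 3 two-dimensional vertices")
        # enforce CCW orientation
        if _signed_area(v) < 0:
            v = v[::-1]
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        return _signed_area(self.vertices)

    def bbox(self) -> np.ndarray:
        v = self.vertices
        return np.array([[v[:, 0].min(), v[:, 0].max()],
                         [v[:, 1].min(), v[:, 1].max()]])

    def _edges(self):
        v = self.vertices
        return zip(v, np.roll(v, -1, axis=0))

    @property
    def edge_normals(self) -> tuple[np.ndarray, np.ndarray]:
        """(anchors, outward normals) as (E, 2) arrays, cached."""
        cached = self.__dict__.get("_edge_normals")
        if cached is None:
            v = self.vertices
            e = np.roll(v, -1, axis=0) - v
            n = np.column_stack([e[:, 1], -e[:, 0]])
            cached = (v.copy(), n)
            self.__dict__["_edge_normals"] = cached
        return cached

    def clip_lines_batch(self, offsets: np.ndarray, m: np.ndarray,
                         d: np.ndarray):
        """Clip the line family {offsets[i] * m + t d} against the polygon.

        Returns (t_lo, t_hi, valid) arrays over the family.
        """
        a, n = self.edge_normals
        c = np.asarray(offsets, dtype=float)
        denom = n @ d                                  # (E,)
        num = (n * a).sum(axis=1)[:, None] - np.outer(n @ m, c)  # (E, M)
        t_lo = np.full(len(c), -np.inf)
        t_hi = np.full(len(c), np.inf)
        valid = np.ones(len(c), dtype=bool)
        for e in range(len(denom)):
            if abs(denom[e]) < 1e-300:
                valid &= num[e] >= 0
                continue
            t = num[e] / denom[e]
            if denom[e] > 0:
                t_hi = np.minimum(t_hi, t)
            else:
                t_lo = np.maximum(t_lo, t)
        valid &= t_hi > t_lo
        return t_lo, t_hi, valid

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        scale = max(1.0, float(np.abs(self.vertices).max()))
        ok = np.ones(len(pts), dtype=bool)
        for a, b in self._edges():
            e = b - a
            cross = e[0] * (pts[:, 1] - a[1]) - e[1] * (pts[:, 0] - a[0])
            ok &= cross >= -EPS_TIE * scale
        if np.asarray(points).ndim == 1:
            return ok[0]
        return ok

    def clip_line(self, p0, direction):
        """Cyrus-Beck clip of the full line against the polygon."""
        p0 = np.asarray(p0, dtype=float)
        d = np.asarray(direction, dtype=float)
        t_lo, t_hi = -np.inf, np.inf
        for a, b in self._edges():
            e = b - a
            n = np.array([e[1], -e[0]])        # outward normal (CCW polygon)
            denom = n @ d
            num = n @ (a - p0)
            if abs(denom) < 1e-300:
                if n @ (p0 - a) > 0:           # line outside this half-plane
                    return None
                continue
            t = num / denom
            if denom > 0:
                t_hi = min(t_hi, t)
            else:
                t_lo = max(t_lo, t)
            if t_lo > t_hi:
                return None
        return (t_lo, t_hi)


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def segment_min_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3D segments (for overlap rejection)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    q0 = np.asarray(q0, float)
    q1 = np.asarray(q1, float)
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-14 * max(a * c, 1.0):
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:  # nearly parallel
        s = 0.0
    t = (b * s + e) / c if c > 0 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 0 else 0.0
    return float(np.linalg.norm(w + s * u - t * v))
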