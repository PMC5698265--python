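"""Virtual microtome: Cavalieri slab stacks, isotropic uniform random (IUR)
section planes, and the elliptical capillary profiles a plane produces.

Sections are idealised zero-thickness planes; overprojection through a
physically thick section is deliberately not modelled (documented
limitation). A segment crossing the plane within its length yields one
elliptical profile with semi-axes (r, r/|cos θ|), θ being the angle between
the segment axis and the plane normal; segments lying in the plane
(|cos θ| < 1e-9) are skipped and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ConvexPolygon, Ellipse
from .phantom import CapillaryNetwork, ReferenceRegion

__all__ = [
    "SlabStack",
    "SectionPlane",
    "Profile",
    "cut_slabs",
    "iur_plane",
    "axial_plane",
    "section_network",
    "filter_capillary_profiles",
    "section_field",
    "rasterize",
    "profiles_to_frame",
    "profiles_from_frame",
    "PARALLEL_EPS",
]

log = logging.getLogger(__name__)

#: |cos θ| below which a segment counts as lying in the section plane
PARALLEL_EPS = 1e-9


# ---------------------------------------------------------------------------
# slabs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlabStack:
    """Exhaustive stack of parallel slabs with a random phase.

    ``faces`` holds the position (along ``axis``) of the counted face of
    each slab; slab k occupies [faces[k], faces[k] + thickness).
    """

    axis: np.ndarray
    thickness: float
    offset: float
    faces: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        object.__setattr__(self, "faces", np.asarray(self.faces, dtype=float))

    @property
    def n_slabs(self) -> int:
        return len(self.faces)


def cut_slabs(region: ReferenceRegion, thickness: float, axis=(0.0, 0.0, 1.0),
              offset_seed: int | None = 0,
              rng: np.random.Generator | None = None) -> SlabStack:
    """Cut the region into consecutive slabs along ``axis`` with a uniform
    random phase in [0, thickness)."""
    if thickness <= 0:
        raise ValueError("slab thickness must be positive")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if rng is None:
        rng = np.random.default_rng(offset_seed)
    lo = -region.support(-axis)
    hi = region.support(axis)
    extent = hi - lo
    if thickness >= extent:
        log.warning("slab thickness %.3g >= region extent %.3g: single slab",
                    thickness, extent)
    offset = float(rng.uniform(0.0, thickness))
    n = max(1, math.ceil((extent + offset) / thickness))
    faces = lo - offset + thickness * np.arange(n)
    return SlabStack(axis=axis, thickness=thickness, offset=offset, faces=faces)


# ---------------------------------------------------------------------------
# planes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectionPlane:
    """A section plane with an orthonormal in-plane frame (e1, e2)."""

    normal: np.ndarray
    point: np.ndarray
    e1: np.ndarray
    e2: np.ndarray

    def __post_init__(self):
        for name in ("normal", "point", "e1", "e2"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("plane normal must be a unit vector")

    def to_plane(self, points: np.ndarray) -> np.ndarray:
        """3D -> in-plane 2D coordinates (origin at ``point``)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.point
        return np.column_stack([pts @ self.e1, pts @ self.e2])

    def to_world(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        return self.point + uv[:, :1] * self.e1 + uv[:, 1:2] * self.e2


def _perp_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def iur_plane(region: ReferenceRegion, seed: int | None = None,
              rng: np.random.Generator | None = None,
              span: str = "support") -> SectionPlane:
    """Draw an IUR plane: normal uniform on the unit sphere (area-uniform),
    position uniform over the region's projection onto the normal, and the
    in-plane frame rotated by an extra uniform angle.

    ``span="support"`` (default) positions the plane uniformly over the
    orientation-dependent support interval, so it always hits the region.
    ``span="bounding"`` uses the fixed bounding-sphere interval instead:
    planes may then miss the region, but the interval width no longer
    depends on orientation, which is what ratio-of-totals density
    estimation over non-spherical regions requires.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    while True:
        v = rng.standard_normal(3)
        nv = np.linalg.norm(v)
        if nv > 1e-12:
            normal = v / nv
            break
    if span == "support":
        s = float(rng.uniform(-region.support(-normal),
                              region.support(normal)))
    elif span == "bounding":
        r_b = float(np.linalg.norm(region.semi_axes)
                    if region.shape == "box" else region.semi_axes.max())
        s = float(rng.uniform(-r_b, r_b))
    else:
        raise ValueError("span must be 'support' or 'bounding'")
    e1, e2 = _perp_frame(normal)
    phi = float(rng.uniform(0.0, 2.0 * math.pi))
    c, sn = math.cos(phi), math.sin(phi)
    return SectionPlane(normal=normal, point=s * normal,
                        e1=c * e1 + sn * e2, e2=-sn * e1 + c * e2)


def axial_plane(position: float, axis=(0.0, 0.0, 1.0)) -> SectionPlane:
    """Plane perpendicular to ``axis`` at the given signed position."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    e1, e2 = _perp_frame(axis)
    return SectionPlane(normal=axis, point=position * axis, e1=e1, e2=e2)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Profile:
    """Elliptical transect of one capillary segment in plane coordinates."""

    center: np.ndarray
    semi_minor: float
    semi_major: float
    angle: float
    segment_id: int

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not (0 < self.semi_minor <= self.semi_major * (1 + 1e-12)):
            raise ValueError("need 0 < semi_minor <= semi_major")

    @property
    def ellipse(self) -> Ellipse:
        return Ellipse(center=self.center, a=self.semi_major,
                       b=self.semi_minor, angle=self.angle)

    @property
    def diameter(self) -> float:
        """True vessel diameter = the minor axis of the transect."""
        return 2.0 * self.semi_minor


def section_network(network: CapillaryNetwork,
                    plane: SectionPlane) -> list[Profile]:
    """Intersect every segment with the plane.

    A segment whose axis crosses the plane at parameter s in [0, 1]
    contributes an ellipse centred at the crossing with semi-axes
    (r, r / |cos θ|) and major axis along the in-plane projection of the
    segment direction.
    """
    profiles: list[Profile] = []
    if not network.segments:
        return profiles
    n = plane.normal
    d_plane = float(n @ plane.point)

    p0 = np.array([s.p0 for s in network.segments])
    dvec = np.array([s.p1 for s in network.segments]) - p0
    radii = np.array([s.radius for s in network.segments])
    seg_len = np.linalg.norm(dvec, axis=1)
    cos_t = (dvec @ n) / seg_len
    parallel = np.abs(cos_t) < PARALLEL_EPS
    skipped = int(np.count_nonzero(
        parallel & (np.abs(p0 @ n - d_plane) <= radii)))
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (d_plane - p0 @ n) / (dvec @ n)
    crossing = np.flatnonzero(~parallel & (s >= 0.0) & (s <= 1.0))
    if crossing.size:
        x = p0[crossing] + s[crossing, None] * dvec[crossing]
        centers = plane.to_plane(x)
        u = dvec[crossing] / seg_len[crossing, None]
        proj = u - cos_t[crossing, None] * n
        ang = np.arctan2(proj @ plane.e2, proj @ plane.e1)
        ang[np.linalg.norm(proj, axis=1) < 1e-12] = 0.0
        for row, idx in enumerate(crossing):
            profiles.append(Profile(
                center=centers[row], semi_minor=radii[idx],
                semi_major=radii[idx] / abs(cos_t[idx]),
                angle=float(ang[row]), segment_id=int(idx)))
    if skipped:
        log.info("section_network: skipped %d segment(s) parallel to plane",
                 skipped)
    return profiles


def filter_capillary_profiles(profiles: list[Profile],
                              max_diameter: float = 10.0) -> list[Profile]:
    """Keep profiles whose vessel diameter (minor axis) is strictly below
    ``max_diameter``; order preserved."""
    if max_diameter <= 0:
        raise ValueError("max_diameter must be positive")
    return [p for p in profiles if p.diameter < max_diameter]


# ---------------------------------------------------------------------------
# section field (the region's own transect)
# ---------------------------------------------------------------------------

def section_field(region: ReferenceRegion, plane: SectionPlane):
    """The 2D region cut out of the reference region by the plane.

    Returns an :class:`Ellipse` (sphere/ellipsoid) or a
    :class:`ConvexPolygon` (box) in plane coordinates, or ``None`` if the
    plane misses the region.
    """
    if region.shape == "box":
        return _box_section(region, plane)
    return _quadric_section(region, plane)


def _quadric_section(region: ReferenceRegion, plane: SectionPlane):
    h = region.semi_axes
    D = 1.0 / h**2
    p, e1, e2 = plane.point, plane.e1, plane.e2
    M = np.array([[float(e1 * D @ e1), float(e1 * D @ e2)],
                  [float(e1 * D @ e2), float(e2 * D @ e2)]])
    Lvec = 2.0 * np.array([float(p * D @ e1), float(p * D @ e2)])
    c0 = float(p * D @ p) - 1.0
    v0 = np.linalg.solve(M, -0.5 * Lvec)
    k = float(v0 @ M @ v0) - c0
    if k <= 0:
        return None
    evals, evecs = np.linalg.eigh(M / k)
    a = 1.0 / math.sqrt(evals[0])   # largest axis from smallest eigenvalue
    b = 1.0 / math.sqrt(evals[1])
    angle = math.atan2(evecs[1, 0], evecs[0, 0])
    return Ellipse(center=v0, a=a, b=b, angle=angle)


_BOX_EDGES = [(i, j) for i in range(8) for j in range(i + 1, 8)
              if bin(i ^ j).count("1") == 1]


def _box_section(region: ReferenceRegion, plane: SectionPlane):
    h = region.semi_axes
    corners = np.array([[sx * h[0], sy * h[1], sz * h[2]]
                        for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    n, d0 = plane.normal, float(plane.normal @ plane.point)
    sd = corners @ n - d0
    pts = []
    for i, j in _BOX_EDGES:
        a, b = sd[i], sd[j]
        if a == b:
            continue
        t = a / (a - b)
        if 0.0 <= t <= 1.0:
            pts.append(corners[i] + t * (corners[j] - corners[i]))
    if len(pts) < 3:
        return None
    uv = plane.to_plane(np.array(pts))
    centroid = uv.mean(axis=0)
    order = np.argsort(np.arctan2(uv[:, 1] - centroid[1], uv[:, 0] - centroid[0]))
    uv = uv[order]
    # drop duplicates from corner-touching edges
    keep = [0]
    for i in range(1, len(uv)):
        if np.linalg.norm(uv[i] - uv[keep[-1]]) > 1e-9 * max(1.0, h.max()):
            keep.append(i)
    uv = uv[keep]
    if len(uv) < 3:
        return None
    return ConvexPolygon(uv)


# ---------------------------------------------------------------------------
# raster & tables
# ---------------------------------------------------------------------------

def rasterize(profiles: list[Profile], field_size: tuple[float, float],
              resolution: float) -> np.ndarray:
    """Binary label image of the profiles over a centred field.

    Pixel-centre sampling, row-major, origin top-left: pixel (i, j) has
    in-plane coordinates x = -w/2 + (j + 0.5) res, y = h/2 - (i + 0.5) res.
    A pixel is set iff its centre falls inside any profile ellipse.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    w, h = float(field_size[0]), float(field_size[1])
    if w <= 0 or h <= 0:
        raise ValueError("field size must be positive")
    ncol = max(1, int(round(w / resolution)))
    nrow = max(1, int(round(h / resolution)))
    img = np.zeros((nrow, ncol), dtype=np.uint8)
    xs = -w / 2.0 + (np.arange(ncol) + 0.5) * resolution
    ys = h / 2.0 - (np.arange(nrow) + 0.5) * resolution
    for prof in profiles:
        ell = prof.ellipse
        (xmin, xmax), (ymin, ymax) = ell.bbox()
        j0 = max(0, int(np.searchsorted(xs, xmin)) - 1)
        j1 = min(ncol, int(np.searchsorted(xs, xmax)) + 1)
        i0 = max(0, int(np.searchsorted(-ys, -ymax)) - 1)
        i1 = min(nrow, int(np.searchsorted(-ys, -ymin)) + 1)
        if j1 <= j0 or i1 <= i0:
            continue
        gx, gy = np.meshgrid(xs[j0:j1], ys[i0:i1])
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        mask = ell.contains(pts).reshape(i1 - i0, j1 - j0)
        img[i0:i1, j0:j1] |= mask.astype(np.uint8)
    return img


PROFILE_COLUMNS = ["section_id", "profile_id", "cx_um", "cy_um",
                   "semi_minor_um", "semi_major_um", "angle_rad", "segment_id"]


def profiles_to_frame(profiles: list[Profile], section_id: int = 0) -> pd.DataFrame:
    rows = [(section_id, i, p.center[0], p.center[1], p.semi_minor,
             p.semi_major, p.angle, p.segment_id)
            for i, p in enumerate(profiles)]
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def profiles_from_frame(df: pd.DataFrame) -> list[Profile]:
    return [Profile(center=np.array([r.cx_um, r.cy_um]),
                    semi_minor=r.semi_minor_um, semi_major=r.semi_major_um,
                    angle=r.angle_rad, segment_id=int(r.segment_id))
            for r in df.itertuples()]
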