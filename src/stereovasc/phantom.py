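"""Synthetic capillary phantoms with exact, closed-form ground truth.

A phantom is a convex reference region of known volume filled with straight
cylindrical segments (no end caps). Because every segment is an explicit
cylinder, total length, volume and lateral surface are exact sums — the
phantom is the oracle against which the section-based estimators are
validated.

Internal unit is the micrometre throughout; the reporting layer converts to
mm^3 / m / cm^2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import segment_min_distance

__all__ = [
    "ReferenceRegion",
    "Segment",
    "CapillaryNetwork",
    "GroundTruth",
    "GroupSpec",
    "CohortSpec",
    "Animal",
    "PackingError",
    "generate_network",
    "ground_truth",
    "generate_cohort",
    "make_radius_sampler",
    "NETWORK_FORMAT",
]

NETWORK_FORMAT = "stereovasc-network/1"

#: default segment length range, μm (uniform draw)
DEFAULT_LENGTH_RANGE = (50.0, 200.0)
#: default capillary radius, μm (diameter 4 μm)
DEFAULT_RADIUS = 2.0


class PackingError(RuntimeError):
    """Raised when the generator cannot reach the requested density."""


@dataclass(frozen=True)
class ReferenceRegion:
    """Convex reference region centred at the origin.

    shape:
        ``box``       dimensions = (lx, ly, lz) edge lengths
        ``ellipsoid`` dimensions = (a, b, c) semi-axes
        ``sphere``    dimensions = (R,)
    """

    shape: str
    dimensions: tuple[float, ...]

    def __post_init__(self):
        dims = tuple(float(d) for d in np.atleast_1d(self.dimensions))
        object.__setattr__(self, "dimensions", dims)
        n_expected = {"box": 3, "ellipsoid": 3, "sphere": 1}
        if self.shape not in n_expected:
            raise ValueError(f"unknown region shape {self.shape!r}")
        if len(dims) != n_expected[self.shape]:
            raise ValueError(f"{self.shape} needs {n_expected[self.shape]} dimensions")
        if any(d <= 0 for d in dims):
            raise ValueError("region dimensions must be positive")

    @property
    def volume(self) -> float:
        if self.shape == "box":
            return math.prod(self.dimensions)
        if self.shape == "sphere":
            return 4.0 / 3.0 * math.pi * self.dimensions[0] ** 3
        a, b, c = self.dimensions
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def semi_axes(self) -> np.ndarray:
        """Semi-axis lengths along x, y, z (half-edges for a box)."""
        if self.shape == "box":
            return np.asarray(self.dimensions) / 2.0
        if self.shape == "sphere":
            return np.full(3, self.dimensions[0])
        return np.asarray(self.dimensions)

    def support(self, direction: np.ndarray) -> float:
        """Support function: max over the region of x . direction
        for a unit direction."""
        n = np.asarray(direction, dtype=float)
        h = self.semi_axes
        if self.shape == "box":
            return float(np.abs(n) @ h)
        return float(math.sqrt(float((h * n) @ (h * n))))

    def bbox(self) -> np.ndarray:
        h = self.semi_axes
        return np.column_stack([-h, h])

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Membership test; ``margin > 0`` shrinks the region by that much."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = self.semi_axes - margin
        if np.any(h <= 0):
            out = np.zeros(len(pts), dtype=bool)
        elif self.shape == "box":
            out = np.all(np.abs(pts) <= h, axis=1)
        else:
            out = np.sum((pts / h) ** 2, axis=1) <= 1.0
        if np.asarray(points).ndim == 1:
            return out[0]
        return out


@dataclass(frozen=True)
class Segment:
    """Straight cylindrical capillary segment (centreline + radius)."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "p0", np.asarray(self.p0, dtype=float))
        object.__setattr__(self, "p1", np.asarray(self.p1, dtype=float))
        if self.radius <= 0:
            raise ValueError("segment radius must be positive")
        if np.array_equal(self.p0, self.p1):
            raise ValueError("degenerate segment: p0 == p1")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def direction(self) -> np.ndarray:
        d = self.p1 - self.p0
        return d / np.linalg.norm(d)


@dataclass
class CapillaryNetwork:
    region: ReferenceRegion
    segments: list[Segment]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.segments)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": NETWORK_FORMAT,
            "region": {"shape": self.region.shape,
                       "dimensions_um": list(self.region.dimensions)},
            "segments": [
                {"p0": s.p0.tolist(), "p1": s.p1.tolist(), "radius_um": s.radius}
                for s in self.segments
            ],
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "CapillaryNetwork":
        if d.get("format") != NETWORK_FORMAT:
            raise ValueError(f"unsupported network format {d.get('format')!r}")
        region = ReferenceRegion(d["region"]["shape"],
                                 tuple(d["region"]["dimensions_um"]))
        segs = [Segment(np.array(s["p0"]), np.array(s["p1"]), s["radius_um"])
                for s in d["segments"]]
        return cls(region=region, segments=segs, seed=d.get("seed"))

    @classmethod
    def load(cls, path) -> "CapillaryNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class GroundTruth:
    """Exact totals and per-unit-reference densities of a network."""

    total_length: float      # μm
    total_volume: float      # μm^3
    total_surface: float     # μm^2  (lateral cylinder area only)
    length_density: float    # μm^-2
    volume_fraction: float   # dimensionless
    surface_density: float   # μm^-1


def ground_truth(network: CapillaryNetwork) -> GroundTruth:
    """Closed-form totals: L = Σ|p1-p0|, V = Σ πr²ℓ, S = Σ 2πrℓ."""
    L = V = S = 0.0
    for s in network.segments:
        ell = s.length
        L += ell
        V += math.pi * s.radius**2 * ell
        S += 2.0 * math.pi * s.radius * ell
    vref = network.region.volume
    return GroundTruth(L, V, S, L / vref, V / vref, S / vref)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def make_radius_sampler(spec) -> "callable":
    """Build a radius sampler from a number or a small spec dict.

    Accepted: a positive number (constant), ``{"constant": r}``,
    ``{"uniform": [lo, hi]}`` or ``{"lognormal": {"mean": m, "sigma": s}}``
    (mean/sigma of the underlying normal, μm).
    """
    if spec is None:
        spec = DEFAULT_RADIUS
    if isinstance(spec, (int, float)):
        r = float(spec)
        if r <= 0:
            raise ValueError("radius must be positive")
        return lambda rng: r
    if "constant" in spec:
        return make_radius_sampler(spec["constant"])
    if "uniform" in spec:
        lo, hi = map(float, spec["uniform"])
        if not 0 < lo <= hi:
            raise ValueError("invalid uniform radius bounds")
        return lambda rng: float(rng.uniform(lo, hi))
    if "lognormal" in spec:
        m = float(spec["lognormal"]["mean"])
        s = float(spec["lognormal"]["sigma"])
        return lambda rng: float(rng.lognormal(m, s))
    raise ValueError(f"unrecognized radius sampler spec {spec!r}")


def _isotropic_direction(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the unit sphere."""
    while True:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def _uniform_point(region: ReferenceRegion, rng: np.random.Generator) -> np.ndarray:
    h = region.semi_axes
    while True:
        p = rng.uniform(-h, h)
        if region.contains(p):
            return p


def generate_network(
    region: ReferenceRegion,
    target_length_density: float,
    radius_sampler=None,
    orientation: str = "isotropic",
    seed: int | None = 0,
    *,
    length_range: tuple[float, float] = DEFAULT_LENGTH_RANGE,
    no_overlap: bool = False,
    max_retries: int = 20000,
    rng: np.random.Generator | None = None,
) -> CapillaryNetwork:
    """Fill ``region`` with straight segments up to a target length density.

    Candidate segments start at a uniform point with an isotropic (or +z
    axial) direction and a uniform length in ``length_range``; candidates
    leaving the region are rejected. The final segment is truncated so the
    summed length hits ``target_length_density * region.volume`` exactly.
    """
    if target_length_density < 0:
        raise ValueError("target_length_density must be >= 0")
    if orientation not in ("isotropic", "axial"):
        raise ValueError("orientation must be 'isotropic' or 'axial'")
    sampler = make_radius_sampler(radius_sampler)
    if rng is None:
        rng = np.random.default_rng(seed)

    target_total = target_length_density * region.volume
    segments: list[Segment] = []
    achieved = 0.0
    failures = 0
    min_len = 1e-6  # μm; below this the residual is ignored

    while target_total - achieved > min_len:
        length = rng.uniform(*length_range)
        length = min(length, target_total - achieved)
        if length < min_len:
            break
        p0 = _uniform_point(region, rng)
        d = (_isotropic_direction(rng) if orientation == "isotropic"
             else np.array([0.0, 0.0, 1.0]))
        p1 = p0 + length * d
        if not region.contains(p1):
            failures += 1
            if failures > max_retries:
                raise PackingError(
                    f"could not reach target density "
                    f"{target_length_density:g} μm^-2; achieved "
                    f"{achieved / region.volume:g} μm^-2 after "
                    f"{max_retries} rejected candidates")
            continue
        radius = sampler(rng)
        cand = Segment(p0, p1, radius)
        if no_overlap and any(
            segment_min_distance(cand.p0, cand.p1, s.p0, s.p1)
            <= cand.radius + s.radius
            for s in segments
        ):
            failures += 1
            if failures > max_retries:
                raise PackingError(
                    f"overlap rejection exhausted after {max_retries} tries; "
                    f"achieved density {achieved / region.volume:g} μm^-2")
            continue
        failures = 0
        segments.append(cand)
        achieved += cand.length

    return CapillaryNetwork(region=region, segments=segments, seed=seed)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Distribution of true per-animal parameters within one study group.

    Length density is in μm^-2 and region volume in μm^3 (phantom scale);
    per-animal values are drawn from independent normals, negatives redrawn.
    """

    label: str
    n_animals: int
    lv_mean: float
    lv_sd: float
    vol_mean: float
    vol_sd: float
    radius: object = None  # radius sampler spec, see make_radius_sampler

    def __post_init__(self):
        if self.n_animals < 2:
            raise ValueError("each group needs at least 2 animals")
        if self.lv_mean <= 0 or self.vol_mean <= 0:
            raise ValueError("group means must be positive")
        if self.lv_sd < 0 or self.vol_sd < 0:
            raise ValueError("group SDs must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0
    shape: str = "box"
    length_range: tuple[float, float] = DEFAULT_LENGTH_RANGE

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))


@dataclass
class Animal:
    animal_id: str
    group: str
    network: CapillaryNetwork
    true_volume: float       # μm^3
    true_length_density: float  # μm^-2


def _region_for_volume(shape: str, volume: float) -> ReferenceRegion:
    if shape == "box":
        side = volume ** (1.0 / 3.0)
        return ReferenceRegion("box", (side, side, side))
    if shape == "sphere":
        r = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
        return ReferenceRegion("sphere", (r,))
    raise ValueError("cohort regions must be 'box' or 'sphere'")


def _positive_normal(rng, mean, sd) -> float:
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError("could not draw a positive value; check mean/SD")


def generate_cohort(spec: CohortSpec) -> list[Animal]:
    """Materialise every animal of a cohort: draw its true parameters from
    the group normals and build the matching phantom network."""
    root = np.random.SeedSequence(spec.seed)
    animals: list[Animal] = []
    for g_idx, grp in enumerate(spec.groups):
        for a_idx in range(grp.n_animals):
            child = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(g_idx, a_idx))
            rng = np.random.default_rng(child)
            vol = _positive_normal(rng, grp.vol_mean, grp.vol_sd)
            lv = _positive_normal(rng, grp.lv_mean, grp.lv_sd)
            region = _region_for_volume(spec.shape, vol)
            net = generate_network(
                region, lv, radius_sampler=grp.radius,
                orientation="isotropic", seed=None,
                length_range=spec.length_range, rng=rng)
            animals.append(Animal(
                animal_id=f"{grp.label}-{a_idx + 1:02d}",
                group=grp.label, network=net,
                true_volume=vol, true_length_density=lv))
    return animals
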