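"""Density and total estimators: pure arithmetic from raw tallies.

* Cavalieri region volume:  V = t * a(p) * ΣP * hemisphere_factor
* length density:           L_V = 2 ΣQ / ΣA
* volume fraction:          V_V = ΣP_cap / ΣP_ref
* surface density:          S_V = 2 ΣI / ΣL

Internal units are μm; :meth:`StereoEstimates.report_units` converts region
and capillary volumes to mm^3, length to m and surface to cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CavalieriSpec",
    "StereoEstimates",
    "cavalieri_volume",
    "length_density",
    "volume_fraction",
    "surface_density",
    "totals",
    "UM3_PER_MM3",
    "UM_PER_M",
    "UM2_PER_CM2",
]

UM3_PER_MM3 = 1e9
UM_PER_M = 1e6
UM2_PER_CM2 = 1e8


@dataclass(frozen=True)
class CavalieriSpec:
    """Slab thickness t (μm), area per point a(p) (μm^2), and the
    hemisphere factor (2 when slabs sample one hemisphere of a paired
    structure, 1 for a single simulated region)."""

    t: float
    area_per_point: float
    hemisphere_factor: int = 2

    def __post_init__(self):
        if self.t <= 0 or self.area_per_point <= 0:
            raise ValueError("t and a(p) must be positive")
        if self.hemisphere_factor not in (1, 2):
            raise ValueError("hemisphere_factor must be 1 or 2")


def cavalieri_volume(point_counts_per_slab, spec: CavalieriSpec) -> float:
    """Region volume (μm^3) from per-slab point counts."""
    counts = list(point_counts_per_slab)
    if not counts:
        raise ValueError("point count list is empty")
    if any(c < 0 for c in counts):
        raise ValueError("point counts must be nonnegative")
    return spec.t * spec.area_per_point * sum(counts) * spec.hemisphere_factor


def length_density(q: int, area_um2: float) -> float:
    """L_V (μm^-2) from transect count and sampled frame area."""
    if area_um2 <= 0:
        raise ValueError("sampled area must be positive")
    if q < 0:
        raise ValueError("transect count must be nonnegative")
    return 2.0 * q / area_um2


def volume_fraction(p_cap: int, p_ref: int) -> float:
    """V_V (dimensionless) from nested point counts."""
    if p_ref <= 0:
        raise ValueError("reference point count must be positive")
    if p_cap < 0:
        raise ValueError("capillary point count must be nonnegative")
    if p_cap > p_ref:
        raise ValueError("capillary phase not nested: ΣP_cap > ΣP_ref")
    return p_cap / p_ref


def surface_density(i: int, l_um: float) -> float:
    """S_V (μm^-1) from intersection count and test-line length."""
    if l_um <= 0:
        raise ValueError("test line length must be positive")
    if i < 0:
        raise ValueError("intersection count must be nonnegative")
    return 2.0 * i / l_um


@dataclass(frozen=True)
class StereoEstimates:
    """Per-animal densities and totals, μm internally."""

    v_region: float   # μm^3
    l_v: float        # μm^-2
    v_v: float        # dimensionless
    s_v: float        # μm^-1
    l_total: float    # μm
    v_cap_total: float  # μm^3
    s_total: float    # μm^2

    def __post_init__(self):
        vals = (self.v_region, self.l_v, self.v_v, self.s_v,
                self.l_total, self.v_cap_total, self.s_total)
        if any(v < 0 for v in vals):
            raise ValueError("estimates must be nonnegative")
        if self.v_v > 1.0:
            raise ValueError("volume fraction exceeds 1")

    def report_units(self, scale: float = 1.0) -> dict:
        """Totals in reporting units (mm^3, m, cm^2); ``scale`` multiplies
        all totals (volume upscaling from a desk-scale phantom)."""
        return {
            "V_region_mm3": self.v_region * scale / UM3_PER_MM3,
            "L_total_m": self.l_total * scale / UM_PER_M,
            "Vcap_total_mm3": self.v_cap_total * scale / UM3_PER_MM3,
            "S_total_cm2": self.s_total * scale / UM2_PER_CM2,
            "Lv_um-2": self.l_v,
            "Vv": self.v_v,
            "Sv_um-1": self.s_v,
        }


def totals(l_v: float, v_v: float, s_v: float, v_region: float) -> StereoEstimates:
    """Scale densities by the region volume to obtain totals."""
    if min(l_v, v_v, s_v, v_region) < 0:
        raise ValueError("densities and region volume must be nonnegative")
    return StereoEstimates(
        v_region=v_region, l_v=l_v, v_v=v_v, s_v=s_v,
        l_total=l_v * v_region, v_cap_total=v_v * v_region,
        s_total=s_v * v_region)
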