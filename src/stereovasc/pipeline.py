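"""End-to-end synthetic study: cohort phantoms -> virtual sectioning ->
probe counting -> density estimators -> group statistics -> report.

The study is configured by a single mapping (YAML/JSON on disk). Group
effect sizes are stated at full scale (total capillary length in metres,
region volume in mm^3); the pipeline maps them onto a desk-scale phantom
region and scales the reported totals back up, so a whole 3 x 10 study runs
in minutes on one CPU.

``reanalyze_summaries`` runs only the statistics stage on a table of
printed group summaries (mean, SD, n per metric); the packaged
``data/paper_summaries.csv`` fixture carries the published group summary
statistics of the motivating study.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators, phantom, probes, sectioning, stats
from .estimators import UM3_PER_MM3, UM_PER_M, CavalieriSpec, StereoEstimates

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "run_animal",
    "reanalyze_summaries",
    "default_config",
    "paper_summaries_path",
    "load_summaries",
]

log = logging.getLogger(__name__)

METRICS = ["V_region_mm3", "L_total_m", "Vcap_total_mm3", "S_total_cm2"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupEffect:
    """Full-scale group effect: total capillary length (m) and region
    volume (mm^3) as mean/SD normals, n animals."""

    label: str
    n_animals: int
    length_total_m: tuple[float, float]
    region_volume_mm3: tuple[float, float]

    def __post_init__(self):
        if self.n_animals < 2:
            raise ValueError(f"group {self.label!r}: n_animals must be >= 2")
        for name in ("length_total_m", "region_volume_mm3"):
            m, sd = getattr(self, name)
            if m <= 0 or sd < 0:
                raise ValueError(f"group {self.label!r}: bad {name}")


@dataclass(frozen=True)
class StudyConfig:
    regions: dict[str, tuple[GroupEffect, ...]]
    seed: int
    # phantom: sphere by default — its projection interval has the same
    # width for every orientation, so support-span IUR sampling keeps the
    # ratio-of-totals density estimators free of 1/H(n) weighting bias.
    shape: str = "sphere"
    base_volume_um3: float = 500.0**3
    radius_um: float = phantom.DEFAULT_RADIUS
    segment_length_um: tuple[float, float] = phantom.DEFAULT_LENGTH_RANGE
    # sampling design
    slab_thickness_um: float = 25.0
    cavalieri_point_spacing_um: float = 20.0
    sections_per_animal: int = 48
    fields_per_section: int | None = None  # None = exhaustive frame tiling
    frame_um: tuple[float, float] = (60.0, 60.0)
    point_spacing_um: float = 12.0
    line_spacing_um: float = 15.0
    max_diameter_um: float = 10.0
    counting_rule: str = "unbiased"
    # statistics
    alpha: float = 0.05
    pairwise: str = "pooled"

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("an explicit integer seed is required")
        positives = dict(
            base_volume_um3=self.base_volume_um3, radius_um=self.radius_um,
            slab_thickness_um=self.slab_thickness_um,
            cavalieri_point_spacing_um=self.cavalieri_point_spacing_um,
            sections_per_animal=self.sections_per_animal,
            point_spacing_um=self.point_spacing_um,
            line_spacing_um=self.line_spacing_um,
            max_diameter_um=self.max_diameter_um, alpha=self.alpha)
        for name, val in positives.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if any(f <= 0 for f in self.frame_um):
            raise ValueError("frame_um must be positive")
        if self.fields_per_section is not None and self.fields_per_section < 1:
            raise ValueError("fields_per_section must be >= 1 or null")
        if self.counting_rule not in ("unbiased", "naive"):
            raise ValueError("counting_rule must be 'unbiased' or 'naive'")
        norm = {}
        for rname, groups in self.regions.items():
            gs = tuple(g if isinstance(g, GroupEffect) else GroupEffect(**g)
                       for g in groups)
            if len(gs) < 1:
                raise ValueError(f"region {rname!r} has no groups")
            norm[rname] = gs
        object.__setattr__(self, "regions", norm)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "phantom": {
                "shape": self.shape,
                "base_volume_um3": self.base_volume_um3,
                "radius_um": self.radius_um,
                "segment_length_um": list(self.segment_length_um),
            },
            "sampling": {
                "slab_thickness_um": self.slab_thickness_um,
                "cavalieri_point_spacing_um": self.cavalieri_point_spacing_um,
                "sections_per_animal": self.sections_per_animal,
                "fields_per_section": self.fields_per_section,
                "frame_um": list(self.frame_um),
                "point_spacing_um": self.point_spacing_um,
                "line_spacing_um": self.line_spacing_um,
                "max_diameter_um": self.max_diameter_um,
                "counting_rule": self.counting_rule,
            },
            "stats": {"alpha": self.alpha, "pairwise": self.pairwise},
            "regions": {
                rname: [
                    {"label": g.label, "n_animals": g.n_animals,
                     "length_total_m": list(g.length_total_m),
                     "region_volume_mm3": list(g.region_volume_mm3)}
                    for g in groups
                ]
                for rname, groups in self.regions.items()
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        ph = d.get("phantom", {})
        sa = d.get("sampling", {})
        st = d.get("stats", {})
        regions = {
            rname: tuple(
                GroupEffect(label=g["label"], n_animals=g["n_animals"],
                            length_total_m=tuple(g["length_total_m"]),
                            region_volume_mm3=tuple(g["region_volume_mm3"]))
                for g in groups)
            for rname, groups in d["regions"].items()
        }
        kwargs = dict(regions=regions, seed=d["seed"])
        mapping = {
            "shape": ph.get("shape"),
            "base_volume_um3": ph.get("base_volume_um3"),
            "radius_um": ph.get("radius_um"),
            "segment_length_um": (tuple(ph["segment_length_um"])
                                  if "segment_length_um" in ph else None),
            "slab_thickness_um": sa.get("slab_thickness_um"),
            "cavalieri_point_spacing_um": sa.get("cavalieri_point_spacing_um"),
            "sections_per_animal": sa.get("sections_per_animal"),
            "fields_per_section": sa.get("fields_per_section", "absent"),
            "frame_um": tuple(sa["frame_um"]) if "frame_um" in sa else None,
            "point_spacing_um": sa.get("point_spacing_um"),
            "line_spacing_um": sa.get("line_spacing_um"),
            "max_diameter_um": sa.get("max_diameter_um"),
            "counting_rule": sa.get("counting_rule"),
            "alpha": st.get("alpha"),
            "pairwise": st.get("pairwise"),
        }
        for k, v in mapping.items():
            if k == "fields_per_section":
                if v != "absent":
                    kwargs[k] = v
            elif v is not None:
                kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


#: printed full-scale group summaries used by the default configuration
_DEFAULT_EFFECTS = {
    "ca1": [
        ("control", (11.7, 1.15), (33.9, 3.01)),
        ("CUS/Standard", (9.67, 0.92), (29.2, 2.27)),
        ("CUS/Running", (10.8, 0.976), (32.0, 2.66)),
    ],
    "dg": [
        ("control", (10.9, 1.03), (24.9, 2.52)),
        ("CUS/Standard", (9.38, 0.688), (21.0, 1.62)),
        ("CUS/Running", (10.4, 0.979), (23.3, 2.84)),
    ],
}


def default_config(seed: int = 0, regions=("ca1", "dg"), n_animals: int = 10,
                   **overrides) -> StudyConfig:
    """Study configuration calibrated to the published group effects."""
    region_map = {
        r: tuple(GroupEffect(label=lab, n_animals=n_animals,
                             length_total_m=lt, region_volume_mm3=rv)
                 for lab, lt, rv in _DEFAULT_EFFECTS[r])
        for r in regions
    }
    return StudyConfig(regions=region_map, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# calibration: full scale -> phantom scale
# ---------------------------------------------------------------------------

def _phantom_group_specs(groups: tuple[GroupEffect, ...],
                         cfg: StudyConfig) -> tuple[list[phantom.GroupSpec], float]:
    """Convert full-scale group effects into phantom-scale cohort specs.

    Returns (specs, K) where K is the fixed volume scale factor mapping
    phantom totals back to full scale. Length density is preserved exactly
    (it is scale-free); the per-animal region volume is divided by K. The
    length-density CV is chosen so that, with independent draws, the CV of
    the resulting total length matches the published one:
    CV_L^2 ~= CV_lv^2 + CV_V^2.
    """
    mean_vol_um3 = np.mean([g.region_volume_mm3[0] for g in groups]) * UM3_PER_MM3
    K = mean_vol_um3 / cfg.base_volume_um3
    specs = []
    for g in groups:
        l_mean, l_sd = g.length_total_m
        v_mean, v_sd = g.region_volume_mm3
        lv_mean = (l_mean * UM_PER_M) / (v_mean * UM3_PER_MM3)  # μm^-2
        cv_l = l_sd / l_mean
        cv_v = v_sd / v_mean
        cv_lv = math.sqrt(max(cv_l**2 - cv_v**2, 0.0))
        specs.append(phantom.GroupSpec(
            label=g.label, n_animals=g.n_animals,
            lv_mean=lv_mean, lv_sd=lv_mean * cv_lv,
            vol_mean=v_mean * UM3_PER_MM3 / K, vol_sd=v_sd * UM3_PER_MM3 / K,
            radius=cfg.radius_um))
    return specs, K


# ---------------------------------------------------------------------------
# per-animal measurement
# ---------------------------------------------------------------------------

def _cavalieri_counts(region, cfg: StudyConfig, rng) -> list[int]:
    stack = sectioning.cut_slabs(region, cfg.slab_thickness_um, rng=rng)
    counts = []
    for pos in stack.faces:
        plane = sectioning.axial_plane(pos, stack.axis)
        fld = sectioning.section_field(region, plane)
        if fld is None:
            counts.append(0)
            continue
        grid = probes.PointGrid.random(cfg.cavalieri_point_spacing_um, rng)
        counts.append(probes.count_point_hits(fld, grid, fld.bbox()))
    return counts


def _frame_counts_tiled(batch: probes.EllipseBatch, fld,
                        cfg: StudyConfig) -> tuple[int, float]:
    q = batch.count_in_tiling(fld.bbox(), *cfg.frame_um, rule=cfg.counting_rule)
    return q, fld.area


def _frame_counts_fields(batch: probes.EllipseBatch, fld, cfg: StudyConfig,
                         rng) -> tuple[int, float]:
    fw, fh = cfg.frame_um
    placements = probes.sample_fields(fld.bbox(), cfg.fields_per_section,
                                      (fw, fh), rng=rng)
    q, area = 0, 0.0
    for x0, y0, _rot in placements:
        corners = np.array([[x0, y0], [x0 + fw, y0],
                            [x0 + fw, y0 + fh], [x0, y0 + fh]])
        if not np.all(fld.contains(corners)):
            continue  # frame must lie inside the reference transect
        frame = probes.CountingFrame(x0, y0, fw, fh)
        ells = batch._ells if batch.n else []
        q += probes.count_profiles_in_frame(ells, frame, rule=cfg.counting_rule)
        area += frame.area
    return q, area


def run_animal(animal: phantom.Animal, cfg: StudyConfig,
               rng: np.random.Generator) -> tuple[StereoEstimates, probes.CountSummary]:
    """Measure one animal: Cavalieri volume plus IUR capillary counts."""
    region = animal.network.region
    t0 = time.perf_counter()

    cav_counts = _cavalieri_counts(region, cfg, rng)
    v_region = estimators.cavalieri_volume(
        cav_counts, CavalieriSpec(cfg.slab_thickness_um,
                                  cfg.cavalieri_point_spacing_um**2,
                                  hemisphere_factor=1))

    tally = probes.CountSummary()
    for _ in range(cfg.sections_per_animal):
        plane = sectioning.iur_plane(region, rng=rng)
        fld = sectioning.section_field(region, plane)
        if fld is None or fld.area <= 0:
            continue
        profiles = sectioning.filter_capillary_profiles(
            sectioning.section_network(animal.network, plane),
            cfg.max_diameter_um)
        batch = probes.EllipseBatch(profiles)
        if cfg.fields_per_section is None:
            q, area = _frame_counts_tiled(batch, fld, cfg)
        else:
            q, area = _frame_counts_fields(batch, fld, cfg, rng)
        grid = probes.PointGrid.random(cfg.point_spacing_um, rng)
        pts = grid.points_in_bbox(fld.bbox())
        in_ref = fld.contains(pts) if len(pts) else np.zeros(0, dtype=bool)
        p_ref = int(in_ref.sum())
        p_cap = int((in_ref & batch.contains_any(pts)).sum()) if len(pts) else 0
        lines = probes.LineGrid.random(cfg.line_spacing_um, rng)
        n_i, l_um = batch.line_grid_counts(lines, fld)
        tally += probes.CountSummary(p_ref=p_ref, p_cap=p_cap, q=q,
                                     a_um2=area, i=n_i, l_um=l_um)

    lv = estimators.length_density(tally.q, tally.a_um2)
    vv = estimators.volume_fraction(tally.p_cap, tally.p_ref)
    sv = estimators.surface_density(tally.i, tally.l_um)
    est = estimators.totals(lv, vv, sv, v_region)
    log.info("animal=%s group=%s elapsed=%.2fs", animal.animal_id,
             animal.group, time.perf_counter() - t0)
    return est, tally


# ---------------------------------------------------------------------------
# study report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    animals: pd.DataFrame | None
    summaries: pd.DataFrame
    tests: pd.DataFrame
    manifest: dict = dc_field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.animals is not None:
            self.animals.to_csv(out / "animals.csv", index=False)
        self.summaries.to_csv(out / "group_summaries.csv", index=False)
        self.tests.to_csv(out / "comparisons.csv", index=False)
        payload = {
            "manifest": self.manifest,
            "summaries": self.summaries.to_dict(orient="records"),
            "comparisons": self.tests.to_dict(orient="records"),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _stats_tables(values: pd.DataFrame, alpha: float,
                  pairwise: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group summaries + comparison table from tidy per-animal values
    (columns: metric, group, value; group order preserved)."""
    sum_rows, test_rows = [], []
    for metric in values["metric"].unique():
        sub = values[values["metric"] == metric]
        groups = []
        for gname in sub["group"].unique():
            gvals = sub.loc[sub["group"] == gname, "value"].to_numpy()
            groups.append(stats.summarize(gvals, label=gname))
        for g in groups:
            sum_rows.append({"metric": metric, "group": g.label, "n": g.n,
                             "mean": g.mean, "sd": g.sd})
        results = []
        if len(groups) >= 2:
            results.append(stats.one_way_anova(groups))
            results.extend(stats.pairwise_tests(groups, method=pairwise))
        table = stats.significance_pattern(results, alpha=alpha)
        table.insert(0, "metric", metric)
        test_rows.append(table)
    summaries = pd.DataFrame(sum_rows,
                             columns=["metric", "group", "n", "mean", "sd"])
    tests = (pd.concat(test_rows, ignore_index=True) if test_rows
             else pd.DataFrame())
    return summaries, tests


def _summary_stats_tables(df: pd.DataFrame, alpha: float,
                          pairwise: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Same, but starting from (metric, group, n, mean, sd) summaries."""
    sum_rows, test_rows = [], []
    for metric in df["metric"].unique():
        sub = df[df["metric"] == metric]
        groups = []
        for row in sub.itertuples():
            try:
                groups.append(stats.GroupSummary(label=str(row.group),
                                                 n=int(row.n),
                                                 mean=float(row.mean),
                                                 sd=float(row.sd)))
            except ValueError as exc:
                raise ValueError(
                    f"bad summary row (metric={metric!r}, "
                    f"group={row.group!r}): {exc}") from exc
        for g in groups:
            sum_rows.append({"metric": metric, "group": g.label, "n": g.n,
                             "mean": g.mean, "sd": g.sd})
        results = []
        if len(groups) >= 2:
            results.append(stats.one_way_anova(groups))
            results.extend(stats.pairwise_tests(groups, method=pairwise))
        table = stats.significance_pattern(results, alpha=alpha)
        table.insert(0, "metric", metric)
        test_rows.append(table)
    summaries = pd.DataFrame(sum_rows,
                             columns=["metric", "group", "n", "mean", "sd"])
    tests = (pd.concat(test_rows, ignore_index=True) if test_rows
             else pd.DataFrame())
    return summaries, tests


def run_study(cfg: StudyConfig) -> StudyReport:
    """Run the full synthetic study described by ``cfg``.

    Deterministic under the configured seed: every animal gets its own
    child random stream derived from it.
    """
    animal_rows = []
    value_rows = []
    root = np.random.SeedSequence(cfg.seed)
    for r_idx, (rname, groups) in enumerate(sorted(cfg.regions.items())):
        specs, K = _phantom_group_specs(groups, cfg)
        cohort_spec = phantom.CohortSpec(
            groups=tuple(specs), seed=int(root.entropy % (2**31)) + r_idx,
            shape=cfg.shape, length_range=cfg.segment_length_um)
        try:
            animals = phantom.generate_cohort(cohort_spec)
        except Exception as exc:
            raise RuntimeError(f"stage=phantom region={rname}: {exc}") from exc
        for a_idx, animal in enumerate(animals):
            child = np.random.SeedSequence(entropy=root.entropy,
                                           spawn_key=(100 + r_idx, a_idx))
            rng = np.random.default_rng(child)
            try:
                est, tally = run_animal(animal, cfg, rng)
            except Exception as exc:
                raise RuntimeError(
                    f"stage=measure region={rname} "
                    f"animal={animal.animal_id}: {exc}") from exc
            rep = est.report_units(scale=K)
            row = {"region": rname, "animal_id": animal.animal_id,
                   "group": animal.group, **rep,
                   "true_V_region_mm3": animal.true_volume * K / UM3_PER_MM3,
                   "true_L_total_m": (animal.true_length_density *
                                      animal.true_volume * K / UM_PER_M),
                   "sum_p_ref": tally.p_ref, "sum_p_cap": tally.p_cap,
                   "sum_q": tally.q, "sum_a_um2": tally.a_um2,
                   "sum_i": tally.i, "sum_l_um": tally.l_um}
            animal_rows.append(row)
            metric_map = {
                f"{rname}_volume_mm3": rep["V_region_mm3"],
                f"{rname}_capillary_length_m": rep["L_total_m"],
                f"{rname}_capillary_volume_mm3": rep["Vcap_total_mm3"],
                f"{rname}_capillary_surface_cm2": rep["S_total_cm2"],
            }
            for metric, value in metric_map.items():
                value_rows.append({"metric": metric, "group": animal.group,
                                   "value": value})
    animals_df = pd.DataFrame(animal_rows)
    values_df = pd.DataFrame(value_rows)
    summaries, tests = _stats_tables(values_df, cfg.alpha, cfg.pairwise)
    manifest = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                "seed": cfg.seed, "n_animals": len(animals_df)}
    return StudyReport(animals=animals_df, summaries=summaries, tests=tests,
                       manifest=manifest)


# ---------------------------------------------------------------------------
# reconstruction from printed summaries
# ---------------------------------------------------------------------------

def paper_summaries_path() -> Path:
    """Path of the packaged published-summary fixture."""
    return Path(resources.files("stereovasc") / "data" / "paper_summaries.csv")


def load_summaries(path=None) -> pd.DataFrame:
    """Load a (metric, group, n, mean, sd) summary table."""
    path = paper_summaries_path() if path is None else path
    df = pd.read_csv(path, comment="#")
    required = {"metric", "group", "n", "mean", "sd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary CSV missing columns: {sorted(missing)}")
    return df


def reanalyze_summaries(summaries, alpha: float = 0.05,
                        pairwise: str = "pooled") -> StudyReport:
    """Statistics-only report from printed summary statistics.

    ``summaries`` is a DataFrame or a CSV path with columns
    metric, group, n, mean, sd. No phantom stages are run.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = load_summaries(summaries)
    sums, tests = _summary_stats_tables(summaries, alpha, pairwise)
    manifest = {"mode": "reanalyze", "alpha": alpha, "pairwise": pairwise}
    return StudyReport(animals=None, summaries=sums, tests=tests,
                       manifest=manifest)
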