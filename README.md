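# stereovasc

Design-based stereology of capillary networks, validated end to end on
synthetic 3D phantoms with exact ground truth.

The package implements the classic estimator chain used to quantify
microvasculature from tissue sections:

* **Cavalieri region volume** from point counts on equidistant slab faces:
  `V = t · a(p) · ΣP · hemisphere_factor`
* **length density** from capillary transect counts in unbiased counting
  frames on isotropic uniform random (IUR) sections: `L_V = 2ΣQ / ΣA`
* **volume fraction** from nested point counts: `V_V = ΣP_cap / ΣP_ref`
* **surface density** from test-line intersections: `S_V = 2ΣI / ΣL`

Totals are densities × region volume, reported in mm³ / m / cm².

Because the original measurements require tissue, validation is synthetic:
the `phantom` module generates isotropic networks of cylindrical segments
inside a convex reference region with closed-form length/volume/surface
ground truth; the `sectioning` module is a virtual microtome (slab stacks,
IUR planes, elliptical transect profiles); the `probes` module applies
point grids, unbiased counting frames (two forbidden edges with their
extensions — a frame tiling counts every profile exactly once) and line
grids; `estimators` turns tallies into densities and totals; `stats`
replays the group comparison (summaries, one-way ANOVA, pooled/Welch/Tukey
pairwise tests); `pipeline` orchestrates whole synthetic cohorts and can
also re-analyse printed summary statistics (mean, SD, n) directly.

## CLI

```sh
# generate a phantom network (JSON segment list)
stereovasc phantom --shape box --size-um 500 --lv-mm-per-mm3 300 --seed 1 --out net.json

# cut IUR sections -> profile table (optionally PNG label images)
stereovasc section --network net.json --n-sections 20 --seed 2 --out profiles.csv

# probe counting per section -> tally CSV (ΣP, ΣQ, ΣA, ΣI, ΣL)
stereovasc count --network net.json --n-sections 20 --seed 3 --out counts.csv

# densities and totals from a tally CSV
stereovasc estimate --counts counts.csv --region-volume-um3 1.25e8

# full synthetic 3-group study from a YAML config
stereovasc run --config examples/study.yaml --out out/

# statistics from printed summary statistics (packaged table by default)
stereovasc reanalyze
stereovasc reanalyze --summaries my_summaries.csv --method welch
```

`examples/study.yaml` is the default desk-scale configuration: a
(500 μm)³-equivalent spherical phantom per animal, calibrated so that each
group's true totals match the published full-scale group means ± SDs, with
totals scaled back up for reporting.

## Design notes and limitations

* Internal unit is μm everywhere; only the reporting layer converts.
* Segments are straight cylinders without end caps; ground truth is exact
  sums. Candidate segments protruding from the region are rejected
  (documented edge-effect limitation of the phantom, not of the
  estimators).
* Sections are idealised zero-thickness planes; overprojection through a
  physically thick section is deliberately not modelled.
* The default phantom region is a sphere: its projection width is the same
  for every orientation, which keeps ratio-of-totals density estimation
  free of orientation-weighting bias; for non-spherical regions use
  `iur_plane(..., span="bounding")` (see docstrings).
* The counting-frame default is the unbiased two-forbidden-edge rule; a
  `naive` rule (inclusion edges only) is available for comparison and is
  demonstrably biased in the tests.
* No coefficient-of-error prediction is computed; empirical Monte-Carlo
  SEs are used throughout the validation suite.
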