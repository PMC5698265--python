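seed: 1
phantom:
  shape: sphere
  base_volume_um3: 125000000.0
  radius_um: 2.0
  segment_length_um:
  - 50.0
  - 200.0
sampling:
  slab_thickness_um: 25.0
  cavalieri_point_spacing_um: 20.0
  sections_per_animal: 48
  fields_per_section: null
  frame_um:
  - 60.0
  - 60.0
  point_spacing_um: 12.0
  line_spacing_um: 15.0
  max_diameter_um: 10.0
  counting_rule: unbiased
stats:
  alpha: 0.05
  pairwise: pooled
regions:
  ca1:
  - label: control
    n_animals: 10
    length_total_m:
    - 11.7
    - 1.15
    region_volume_mm3:
    - 33.9
    - 3.01
  - label: CUS/Standard
    n_animals: 10
    length_total_m:
    - 9.67
    - 0.92
    region_volume_mm3:
    - 29.2
    - 2.27
  - label: CUS/Running
    n_animals: 10
    length_total_m:
    - 10.8
    - 0.976
    region_volume_mm3:
    - 32.0
    - 2.66
  dg:
  - label: control
    n_animals: 10
    length_total_m:
    - 10.9
    - 1.03
    region_volume_mm3:
    - 24.9
    - 2.52
  - label: CUS/Standard
    n_animals: 10
    length_total_m:
    - 9.38
    - 0.688
    region_volume_mm3:
    - 21.0
    - 1.62
  - label: CUS/Running
    n_animals: 10
    length_total_m:
    - 10.4
    - 0.979
    region_volume_mm3:
    - 23.3
    - 2.84
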