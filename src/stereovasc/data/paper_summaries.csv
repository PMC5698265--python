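# Published group summary statistics (mean, sample SD, n per group) of the
# motivating study's results section; the only data file shipped with the
# package. Units are encoded in the metric name.
metric,group,n,mean,sd
sucrose_consumption_pct,CUS/Standard,10,79.7,13.3
sucrose_consumption_pct,CUS/Running,10,91.5,4.83
ca1_volume_mm3,control,10,33.9,3.01
ca1_volume_mm3,CUS/Standard,10,29.2,2.27
ca1_volume_mm3,CUS/Running,10,32.0,2.66
dg_volume_mm3,control,10,24.9,2.52
dg_volume_mm3,CUS/Standard,10,21.0,1.62
dg_volume_mm3,CUS/Running,10,23.3,2.84
ca1_capillary_length_m,control,10,11.7,1.15
ca1_capillary_length_m,CUS/Standard,10,9.67,0.92
ca1_capillary_length_m,CUS/Running,10,10.8,0.976
ca1_capillary_volume_mm3,control,10,0.157,0.0130
ca1_capillary_volume_mm3,CUS/Standard,10,0.111,0.0180
ca1_capillary_volume_mm3,CUS/Running,10,0.144,0.0160
ca1_capillary_surface_cm2,control,10,1.40,0.204
ca1_capillary_surface_cm2,CUS/Standard,10,1.06,0.117
ca1_capillary_surface_cm2,CUS/Running,10,1.29,0.184
dg_capillary_length_m,control,10,10.9,1.03
dg_capillary_length_m,CUS/Standard,10,9.38,0.688
dg_capillary_length_m,CUS/Running,10,10.4,0.979
dg_capillary_volume_mm3,control,10,0.155,0.0110
dg_capillary_volume_mm3,CUS/Standard,10,0.115,0.0300
dg_capillary_volume_mm3,CUS/Running,10,0.143,0.0180
dg_capillary_surface_cm2,control,10,1.40,0.151
dg_capillary_surface_cm2,CUS/Standard,10,1.11,0.135
dg_capillary_surface_cm2,CUS/Running,10,1.25,0.177
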