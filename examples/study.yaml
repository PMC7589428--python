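# One dosimetry study, end to end.  `dosekit run study.yaml` or
# StudyConfig.from_yaml("study.yaml") + run_pipeline(...).
nuclide:
  name: Lu-177                 # half-life read from the packaged registry
  energy_per_decay_j: 2.37e-14 # local (electron) energy per decay, user-supplied
a0_MBq: 7200.0
acquisition:                   # patient scans: 60 projections x 45 s
  n_projections: 60
  seconds_per_projection: 45
calibration:                   # sphere factor, measured over the same duration
  magnitude: 38.3e-6
  unit_kind: MBq_per_count
  context: {n_projections: 60, seconds_per_projection: 45}
phantom:                       # synthetic input instead of volume paths
  preset: default_abdominal
  noise: none
  sensitivity_cps_per_MBq: 9.670244657189826   # = 1/(38.3e-6 * 2700)
fit:
  model: monoexp               # monoexp | biexp | powerexp | trapezoid_tail | auto
dose:
  engines: [led, dvk]
  kernel_radius_voxels: 3
  kernel_scale_mm: 0.3
output_dir: dosekit_out
seed: 7
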