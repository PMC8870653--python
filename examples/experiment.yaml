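background:
  ball_height_rad: 0.65
  ball_radius_px: 80
  downscale: auto
  light_background: false
conditions:
- concentration_ug_per_ml: 0.0
  is_control: true
  name: medium
  scenario:
    debris_mass_fraction: 0.25
    decline_rate_per_h: 0.15
    doubling_time_h: 24.0
    kind: control-exponential
    linear_slope_ng_per_h: 0.05
    n_debris: 60
    onset_h: 10.0
    seed: 0
- concentration_ug_per_ml: 500.0
  is_control: false
  name: digitonin
  scenario:
    debris_mass_fraction: 0.25
    decline_rate_per_h: 0.05
    doubling_time_h: 12.0
    kind: lysis
    linear_slope_ng_per_h: 0.05
    n_debris: 60
    onset_h: 10.0
    seed: 0
drymass:
  alpha_ml_per_g: 0.19
  fov_area_um2: null
  wavelength_nm: 532.0
fovs_per_condition: 4
make_plots: true
master_seed: 1
n_experiments: 1
optical:
  aberration_coeff_rad_per_px2: 0.0
  carrier_cyc_per_px:
  - 0.25
  - 0.25
  coherent_corr_px: 8.0
  coherent_sigma_rad: 0.05
  defocus_um: 0.0
  detector_sigma: 0.02
  frames_per_timepoint: 3
  object_amplitude: 1.0
  pixel_pitch_um: 0.879
  quantize_8bit: false
  reference_amplitude: 1.0
  shape:
  - 192
  - 256
  wavelength_nm: 532.0
recon:
  compensate_aberration: true
  dc_exclude_cyc: 0.1
  mask_radius_frac: 0.55
  mask_shape: raised-cosine
  pixel_pitch_um: 0.879
  refocus_z_um: 0.0
  support_fraction: 0.01
  unwrap_method: reliability
  wavelength_nm: 532.0
save_holograms: false
save_phase_maps: true
scene_kwargs:
  margin_um: 12.0
  n_cells: 12
  radius_range_um:
  - 7.0
  - 10.0
timepoints_h:
- 0.0
- 12.0
- 24.0
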