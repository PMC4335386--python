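seed: 0
log_level: INFO
output_dir: runs/default
geometry:
  follicle_radius: 100.0
  medulla_outer_radius: 36.26
  medulla_anterior_offset: null
  medulla_lobe_half_angle: 0.8377580409572782
  medulla_bite_depth: 0.4
  cortex_eccentricity: 3.5
  irs_thickness: 6.0
  protrusion_depth: 8.0
  protrusion_half_width: 0.5235987755982988
  ring_thickness: 4.0
  base_cortex_fraction: 0.67
  n_vertices: 256
materials:
  medulla:
    E: 1.0
    nu: 0.3
  cortex_posterior:
    E: 1.0
    nu: 0.3
  cortex_anterior:
    E: 1.0
    nu: 0.3
  irs_posterior:
    E: 0.5
    nu: 0.3
  irs_anterior:
    E: 0.5
    nu: 0.3
  outer_ring:
    E: 20.0
    nu: 0.3
schedule:
  n_steps: 50
  irs_growth_start: 0.0
  irs_growth_end: 0.85
  irs_growth_total_strain: 0.18
  irs_growing_modulus: 3.0
  keratinization_onset_posterior: 0.3
  keratinization_onset_anterior: 0.45
  keratinization_full: 0.85
  lambda_z_max: 3.2
  cortex_keratinized_modulus: 50.0
  medulla_stiffen_start: 0.2
  medulla_stiffen_end: 0.5
  medulla_keratinized_modulus: 35.0
  collapse_start: 0.7
  collapse_end: 1.0
  relative_density: 0.1
  foam_exponent: 2.0
  collapse_strain: -0.75
simulation:
  mesh_size: 3.5
  bc: fixed_outer
generator:
  geometry:
    follicle_radius: 100.0
    medulla_outer_radius: 36.26
    medulla_anterior_offset: null
    medulla_lobe_half_angle: 0.8377580409572782
    medulla_bite_depth: 0.4
    cortex_eccentricity: 3.5
    irs_thickness: 6.0
    protrusion_depth: 8.0
    protrusion_half_width: 0.5235987755982988
    ring_thickness: 4.0
    base_cortex_fraction: 0.67
    n_vertices: 256
  mean_counts:
    dp: 1093.0
    medulla: 80.0
    posterior_with_brdu: 260.0
    posterior_without_brdu: 160.0
    anterior_with_brdu: 90.0
    anterior_without_brdu: 30.0
    irs_posterior: 60.0
    irs_anterior: 80.0
  marker_probs:
    dp: {}
    medulla:
      tunel: 0.0
    posterior_with_brdu:
      brdu: 0.2
      ph3: 0.03
      tunel: 0.0
    posterior_without_brdu:
      brdu: 0.0
      ph3: 0.01
      tunel: 0.0
    anterior_with_brdu:
      brdu: 0.2
      ph3: 0.03
      tunel: 0.0
    anterior_without_brdu:
      brdu: 0.0
      ph3: 0.01
      tunel: 0.0
    irs_posterior:
      k71: 0.8
      brdu: 0.02
    irs_anterior:
      k71: 0.8
      brdu: 0.1
  signaling_range_posterior: 25.0
  signaling_range_anterior: 35.0
  dp_scale: 0.75
  n_sections: 24
  thickness: 7.0
  brdu_fade:
  - 0.3
  - 0.9
  tunel_rise:
  - 0.4
  - 0.95
  tunel_max: 0.25
  seed: 0
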