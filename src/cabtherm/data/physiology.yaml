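# 14-segment, 4-layer (core/muscle/fat/skin) thermophysiology parameter set.
#
# The node-level quantities (heat capacities, conductances, basal blood
# flows, metabolic distribution) are derived from these per-segment
# primitives by the loader; see docs/methods.md for the calibration
# rationale.  Layer order everywhere: [core, muscle, fat, skin].
#
# version: 1

body:
  mass_kg: 65.0
  height_m: 1.70
  specific_heat_j_per_kgk: 3490.0
  blood_mass_kg: 2.5
  blood_specific_heat_j_per_kgk: 3850.0
  metabolic_rate_w_per_m2: 75.4      # seated light work (~1.3 met)
  core_setpoint_c: 36.95             # head-core (hypothalamic) set-point
  emissivity: 0.95
  lewis_ratio_k_per_kpa: 16.5
  clothing_vapour_permeation: 0.34   # i_cl, Woodcock permeation efficiency
  skin_diffusion_fraction: 0.10      # fraction of E_max lost without sweating
  bf_l_per_h_per_w: 1.6              # basal perfusion per watt of node metabolism
  fat_bf_l_per_h_per_w: 0.8

controls:
  # drive signal sig = core_gain*(T_head_core - T_core_set) + skin_gain*(WRM - CLD)
  sig_core_gain: 10.0
  sig_skin_gain: 1.0
  sweat_gain_w: 25.0
  sweat_max_w: 500.0
  shiver_gain_w: 15.0
  shiver_max_w: 350.0
  vaso_core_gain: 5.0
  vaso_skin_gain: 0.5
  dilation_gain: 0.8
  constriction_gain: 0.4
  bf_mult_min: 0.05
  bf_mult_max: 15.0

# Per-segment primitives.  Areas sum to the whole-body DuBois area that
# scales the areal metabolic rate; mass fractions sum to 1 (normalised by
# the loader); met_weights are the per-node shares of whole-body heat
# production (normalised); conductances are per unit area across the
# core-muscle, muscle-fat and fat-skin interfaces.
segments:
  head:
    area_m2: 0.140
    mass_fraction: 0.080
    layer_mass_fractions: [0.70, 0.14, 0.10, 0.06]
    met_weights: [0.160, 0.005, 0.002, 0.003]
    conductance_w_per_m2k: [6.0, 10.0, 50.0]
    skin_basal_bf_l_per_h: 16.0
    clothing_m2k_per_w: 0.0
    skin_setpoint_c: 36.0
    receptor_weight: 0.077
    sweat_weight: 0.08
    shiver_weight: 0.02
  chest:
    area_m2: 0.620
    mass_fraction: 0.468
    layer_mass_fractions: [0.40, 0.42, 0.12, 0.06]
    met_weights: [0.420, 0.120, 0.004, 0.006]
    conductance_w_per_m2k: [4.0, 6.0, 14.0]
    skin_basal_bf_l_per_h: 18.0
    clothing_m2k_per_w: 0.078
    skin_setpoint_c: 35.0
    receptor_weight: 0.340
    sweat_weight: 0.35
    shiver_weight: 0.60
  l_upper_arm: &upper_arm
    area_m2: 0.080
    mass_fraction: 0.033
    layer_mass_fractions: [0.30, 0.50, 0.12, 0.08]
    met_weights: [0.004, 0.016, 0.001, 0.002]
    conductance_w_per_m2k: [8.0, 10.0, 14.0]
    skin_basal_bf_l_per_h: 2.0
    clothing_m2k_per_w: 0.078
    skin_setpoint_c: 35.0
    receptor_weight: 0.044
    sweat_weight: 0.05
    shiver_weight: 0.02
  r_upper_arm: *upper_arm
  l_lower_arm: &lower_arm
    area_m2: 0.062
    mass_fraction: 0.021
    layer_mass_fractions: [0.30, 0.50, 0.12, 0.08]
    met_weights: [0.003, 0.012, 0.001, 0.002]
    conductance_w_per_m2k: [8.0, 10.0, 14.0]
    skin_basal_bf_l_per_h: 1.8
    clothing_m2k_per_w: 0.078
    skin_setpoint_c: 35.0
    receptor_weight: 0.034
    sweat_weight: 0.04
    shiver_weight: 0.01
  r_lower_arm: *lower_arm
  l_hand: &hand
    area_m2: 0.050
    mass_fraction: 0.006
    layer_mass_fractions: [0.40, 0.30, 0.15, 0.15]
    met_weights: [0.002, 0.003, 0.0005, 0.002]
    conductance_w_per_m2k: [15.0, 18.0, 25.0]
    skin_basal_bf_l_per_h: 2.5
    clothing_m2k_per_w: 0.0
    skin_setpoint_c: 35.0
    receptor_weight: 0.027
    sweat_weight: 0.02
    shiver_weight: 0.002
  r_hand: *hand
  l_upper_leg: &upper_leg
    area_m2: 0.160
    mass_fraction: 0.105
    layer_mass_fractions: [0.30, 0.50, 0.12, 0.08]
    met_weights: [0.006, 0.036, 0.002, 0.003]
    conductance_w_per_m2k: [8.0, 10.0, 14.0]
    skin_basal_bf_l_per_h: 4.0
    clothing_m2k_per_w: 0.078
    skin_setpoint_c: 35.0
    receptor_weight: 0.088
    sweat_weight: 0.09
    shiver_weight: 0.10
  r_upper_leg: *upper_leg
  l_lower_leg: &lower_leg
    area_m2: 0.125
    mass_fraction: 0.047
    layer_mass_fractions: [0.30, 0.50, 0.12, 0.08]
    met_weights: [0.004, 0.022, 0.001, 0.002]
    conductance_w_per_m2k: [8.0, 10.0, 12.0]
    skin_basal_bf_l_per_h: 1.6
    clothing_m2k_per_w: 0.078
    skin_setpoint_c: 34.0
    receptor_weight: 0.068
    sweat_weight: 0.06
    shiver_weight: 0.04
  r_lower_leg: *lower_leg
  l_foot: &foot
    area_m2: 0.056
    mass_fraction: 0.014
    layer_mass_fractions: [0.40, 0.30, 0.15, 0.15]
    met_weights: [0.002, 0.003, 0.0005, 0.002]
    conductance_w_per_m2k: [15.0, 18.0, 30.0]
    skin_basal_bf_l_per_h: 8.0
    clothing_m2k_per_w: 0.124
    skin_setpoint_c: 36.0
    receptor_weight: 0.031
    sweat_weight: 0.015
    shiver_weight: 0.003
  r_foot: *foot
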