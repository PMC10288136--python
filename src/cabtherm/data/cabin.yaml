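# Lumped-parameter cab microclimate model (synthetic stand-in for the
# resolved flow field).  Envelope/glazing properties follow the reference
# operating scenario (35 degC / 75% RH outdoors, 50% RH indoors, body
# shell U 1.2 W/m2K, window U 1.4 W/m2K); the geometry, jet-exposure and
# solar-view tables are fixed model constants chosen to reproduce the
# qualitative spatial structure of a console-vented cab: the console jets
# hit head, hands and chest hardest at a 45-degree supply angle and are
# uniformly weaker at 90 degrees, the windshield irradiates the upper
# body, and the under-console region traps warm air around the calves.
#
# version: 1

outdoor_temp_c: 35.0
outdoor_rh: 0.75
indoor_rh: 0.50
u_body_w_per_m2k: 1.2
u_window_w_per_m2k: 1.4
area_envelope_m2: 28.0
area_window_m2: 3.5
transmissivity: 0.6
windshield_tilt_rad: 0.5
internal_gain_w: 300.0
vent_area_m2: 0.07
air_density_kg_per_m3: 1.15
air_cp_j_per_kgk: 1006.0
min_air_speed_m_per_s: 0.05
#: converts absorbed solar flux (W/m2) to a mean-radiant elevation (K)
h_rad_norm_w_per_m2k: 50.0

# jet exposure d_i by supply angle (fraction of the supply/cab contrast
# felt at the segment; also scales the local air speed)
jet_exposure:
  "45": {head: 0.45, chest: 0.40, l_upper_arm: 0.30, r_upper_arm: 0.30,
         l_lower_arm: 0.35, r_lower_arm: 0.35, l_hand: 0.50, r_hand: 0.50,
         l_upper_leg: 0.20, r_upper_leg: 0.20, l_lower_leg: 0.08, r_lower_leg: 0.08,
         l_foot: 0.10, r_foot: 0.10}
  "90": {head: 0.22, chest: 0.20, l_upper_arm: 0.15, r_upper_arm: 0.15,
         l_lower_arm: 0.17, r_lower_arm: 0.17, l_hand: 0.25, r_hand: 0.25,
         l_upper_leg: 0.10, r_upper_leg: 0.10, l_lower_leg: 0.05, r_lower_leg: 0.05,
         l_foot: 0.06, r_foot: 0.06}

# windshield view factors for the transmitted solar load
solar_view:
  head: 0.90
  chest: 0.80
  l_upper_arm: 0.55
  r_upper_arm: 0.55
  l_lower_arm: 0.60
  r_lower_arm: 0.60
  l_hand: 0.70
  r_hand: 0.70
  l_upper_leg: 0.35
  r_upper_leg: 0.35
  l_lower_leg: 0.0
  r_lower_leg: 0.0
  l_foot: 0.05
  r_foot: 0.05

# warm-floor/under-console radiant term (solar-driven), mainly the calves
floor_heat:
  l_lower_leg: 0.25
  r_lower_leg: 0.25
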