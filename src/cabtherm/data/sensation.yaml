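# Local/overall thermal-sensation coefficients (Berkeley-style model),
# folded onto the 14-segment body used by the thermoregulation solver.
#
# c1: static sensitivity (1/degC) of the local-sensation sigmoid, with
#     separate cold-side (skin below set-point) and warm-side values.
# k1: whole-body coupling of the local deviation to the mean-skin
#     deviation (dimensionless, shared by all parts).
# c2/c3: dynamic gains on dT_skin/dt and dT_core/dt (degC^-1 s); c2 is
#     selected cold/warm by the sign of the skin-temperature derivative.
# a:  overall-sensation weighting slope, cold/warm by the sign of the
#     local deviation from the mean sensation.
#
# Set-points are the tabulated reference skin temperatures (see
# physiology.yaml); their seven-site mean is computed at load time.
#
# version: 1

k1: 0.2

parts:
  head:        {c1_cold: 0.40, c1_warm: 0.70, c2_cold: 543.0, c2_warm: 90.0, c3: -2135.0, a_cold: 0.75, a_warm: 0.15}
  chest:       {c1_cold: 0.35, c1_warm: 0.60, c2_cold: 39.0,  c2_warm: 90.0, c3: -2289.0, a_cold: 0.80, a_warm: 0.18}
  l_upper_arm: {c1_cold: 0.30, c1_warm: 0.40, c2_cold: 75.0,  c2_warm: 75.0, c3: -1000.0, a_cold: 0.70, a_warm: 0.12}
  r_upper_arm: {c1_cold: 0.30, c1_warm: 0.40, c2_cold: 75.0,  c2_warm: 75.0, c3: -1000.0, a_cold: 0.70, a_warm: 0.12}
  l_lower_arm: {c1_cold: 0.30, c1_warm: 0.55, c2_cold: 75.0,  c2_warm: 75.0, c3: -1000.0, a_cold: 0.70, a_warm: 0.12}
  r_lower_arm: {c1_cold: 0.30, c1_warm: 0.55, c2_cold: 75.0,  c2_warm: 75.0, c3: -1000.0, a_cold: 0.70, a_warm: 0.12}
  l_hand:      {c1_cold: 0.25, c1_warm: 0.45, c2_cold: 180.0, c2_warm: 90.0, c3: -500.0,  a_cold: 0.70, a_warm: 0.10}
  r_hand:      {c1_cold: 0.25, c1_warm: 0.45, c2_cold: 180.0, c2_warm: 90.0, c3: -500.0,  a_cold: 0.70, a_warm: 0.10}
  l_upper_leg: {c1_cold: 0.28, c1_warm: 0.40, c2_cold: 60.0,  c2_warm: 60.0, c3: -1000.0, a_cold: 0.72, a_warm: 0.15}
  r_upper_leg: {c1_cold: 0.28, c1_warm: 0.40, c2_cold: 60.0,  c2_warm: 60.0, c3: -1000.0, a_cold: 0.72, a_warm: 0.15}
  l_lower_leg: {c1_cold: 0.30, c1_warm: 0.43, c2_cold: 60.0,  c2_warm: 60.0, c3: -1000.0, a_cold: 0.78, a_warm: 0.15}
  r_lower_leg: {c1_cold: 0.30, c1_warm: 0.43, c2_cold: 60.0,  c2_warm: 60.0, c3: -1000.0, a_cold: 0.78, a_warm: 0.15}
  l_foot:      {c1_cold: 0.25, c1_warm: 0.35, c2_cold: 100.0, c2_warm: 60.0, c3: -500.0,  a_cold: 0.70, a_warm: 0.10}
  r_foot:      {c1_cold: 0.25, c1_warm: 0.35, c2_cold: 100.0, c2_warm: 60.0, c3: -500.0,  a_cold: 0.70, a_warm: 0.10}
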