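# Methods

`cabtherm` models the thermal sensation of a seated train driver under a
console-vented HVAC system and summer solar load, and searches the
air-supply settings for a neutral overall sensation. The chain has three
physical stages — cab microclimate, human thermoregulation, thermal
sensation — wrapped in a surrogate-based design-optimization study.
This note records the models, their assumptions, the parameter choices
that matter, and what the synthetic stages do and do not capture.

## Cab microclimate (`cabin`)

The resolved air flow of a real cab is replaced by a deterministic
lumped model. A steady-state mixed-air balance gives one bulk cab
temperature:

    m_cp (T_cab − T_sup) = UA (T_out − T_cab) + τ A_win I cos(α − β) + Q_int

with supply mass flow `m_cp = ρ Q_sup c_p / 3600`, envelope/window
transmission `UA = U_body A_env + U_win A_win` (U-values 1.2 and
1.4 W/m²K, outdoor 35 °C / 75 % RH), transmitted solar load through the
windshield (transmissivity τ = 0.6, tilt β = 0.5 rad) and an internal
equipment gain Q_int = 300 W. The geometry constants (A_env = 28 m²,
A_win = 3.5 m², vent area 0.07 m²) are fixed model constants, versioned
in `data/cabin.yaml`.

Spatial structure comes from two fixed per-segment tables:

- **Jet exposure d_i(θ)** — the fraction of the supply/cab temperature
  contrast each segment feels, and the same factor scales its local air
  speed. The console jets aim at the upper body, so d is largest for
  hands, head and chest at the 45° supply angle and uniformly about half
  as large at 90°.
- **Solar view s_i** — windshield view factors convert the transmitted
  flux into a mean-radiant elevation `s_i τ I cos(α−β) / h_norm`
  (h_norm = 50 W/m²K); the upper body sees the windshield, the calves
  and feet are shaded under the console, and a small warm-floor term for
  the lower legs keeps the calves on the warm side, as observed in
  console-vented cabs.

The module is smooth in the continuous factors, treats the supply angle
as a two-level categorical factor, and contains no randomness. The
driver's own metabolic heat is not added to the cab balance (second
order at these air-change rates). Not captured: turbulence, transient
pull-down, window surface temperatures, humidity transport, and any
flow-reversal effects a real jet can produce — which is why the
reference study's occasional negative local correlations at 45° are out
of scope here.

## Thermoregulation (`body_thermal`)

A multi-node model of the Stolwijk type: 14 segments × 4 tissue layers
(core, muscle, fat, skin) plus a central blood pool — 57 nodes. Each
node carries a heat capacity, a basal metabolic rate and a perfusion to
the blood pool; adjacent layers exchange by conduction; the skin loses
heat by convection and linearised radiation through the clothing
(`h_c = max(8.3 v^0.6, 3.1)` W/m²K, emissivity 0.95) and by evaporation
(passive diffusion at 10 % of the evaporative capacity plus sweat,
capped at the capacity, Lewis ratio 16.5 K/kPa, clothing permeation
i_cl = 0.34). Respiratory loss, proportional to the metabolic rate, is
charged to the chest core. The capacity-weighted sum of the node
derivatives equals production minus environmental loss exactly, because
perfusion and conduction cancel pairwise — the solver conserves energy
by construction.

The active system maps the head-core error and the receptor-weighted
skin warm/cold signals into one drive signal; its positive part commands
sweating and vasodilation, its negative part shivering and
vasoconstriction, so the two effectors are mutually exclusive and all
controls vanish exactly at the set-points.

**Parameter set.** The source study names the model but prints no
coefficients beyond anthropometry (1.70 m, 75.4 W/m² metabolic rate,
per-part initial skin temperatures) — so `data/physiology.yaml` is an
authored, self-consistent set: a 65 kg body split by standard segment
mass/area fractions, layer masses by tissue composition, basal perfusion
proportional to node metabolism (1.6 L/h per W), and per-area interface
conductances. Skin perfusion and fat–skin conductances were calibrated
once so that the clothed thermoneutral steady state (25 °C, 0.1 m/s,
50 % RH) settles near the tabulated set-points: MST 34.7 °C, overall
sensation −0.37, core ≈ 37 °C, energy closure < 1 %. The tabulated
initial skin temperatures double as the control and sensation
set-points; they are warm for head and feet (36 °C), which the
calibration honours with high head/foot skin perfusion.

**Clothing.** The printed clothing resistance of 0.775 m²·K/W equals
5 clo — implausible for a summer cab, and the printed conversion note
(1 clo = 0.155 m²·K/W) suggests a dropped decimal. The default is a
summer ensemble of ≈ 0.5 clo distributed per segment (bare head and
hands, 0.8 clo shoes); the printed value remains reachable through
`StudyConfig.clothing_override` / `PhysioParams.with_clothing`.

**Integration.** Fixed-step RK4 with dt = 2 s, controls re-evaluated at
every stage; deterministic and bit-reproducible. Steady state is
declared when the largest node derivative falls below 0.001 °C/min
(checked every 120 s of simulated time), with a 2 h cap. The strong
control feedback makes the slowest whole-body mode converge within
minutes of simulated time; typical solves take ~1–3 s of wall time.
Any node leaving 20–45 °C aborts the solve with the node and time named.

## Thermal sensation (`sensation`)

Berkeley-style local sensation on the 9-point ASHRAE scale:

    S_i = 4 (2 / (1 + exp(−C1 ΔT_i − K1 [(T_sk,i − T̄_sk) − (T_set,i − T̄_set)])) − 1)
          + C2_i dT_sk,i/dt + C3_i dT_core/dt

with cold/warm C1 chosen by the sign of ΔT_i and every vote clamped to
[−4, 4]. At steady state the dynamic terms vanish. The whole-body
coupling temperature T̄_sk is a left/right-symmetrised 7-site mean so
that mirrored environments give mirrored votes; the *reported* MST is
the standard left-sided Hardy/DuBois 7-site weighted average
(0.07 head, 0.35 chest, 0.14 lower arm, 0.05 hand, 0.19 upper leg,
0.13 lower leg, 0.07 foot — weights summing to 1).

Overall sensation is the deviation-weighted average

    S0 = Σ w_i S_i / Σ w_i,   w_i = a_i (S_i − S_m)

with S_m the arithmetic mean of the locals and cold/warm slopes a_i
chosen by the sign of the deviation; uniform locals (vanishing weight
sum) fall back to S_m. This form is singular wherever Σw crosses zero,
so the bundled slopes are chosen **cold-dominant with a uniform margin**
(every a_cold ≥ 0.70 exceeds every a_warm ≤ 0.18): the weight sum then
keeps one sign for any non-uniform vote pattern, the vote stays bounded
and piecewise smooth, and — matching the comfort literature — cold local
deviations (a draught on the head or hands) pull the overall vote down
more than warm ones pull it up. The C1/C2/C3 magnitudes follow the
published Berkeley-model ranges; all values live in
`data/sensation.yaml` with the back/pelvis parts of the original model
folded into the chest.

## Design of experiments (`doe`)

Maximin Latin hypercube: continuous factors stratified one point per
equal-width bin (bin midpoints), the supply angle assigned in balanced
blocks, then a 10,000-iteration random column-entry swap search that
accepts a swap only when the minimum pairwise distance (range-normalised
space, angle coded 0/1) strictly improves — so the projection property
is preserved and the criterion is non-decreasing by construction.
Everything is seeded; the study default is 60 points (30 per angle
level) with a 10 % holdout (6 points).

## Surrogate (`surrogate`)

One exact RBF interpolant per response (14 local votes, overall vote,
MST) over the unit-normalised box. Kernel selection was done by
cross-validated holdout error over several design seeds among the
polyharmonic family and the Gaussian: the quintic kernel with its
quadratic tail was uniformly the most accurate for the overall vote
(holdout RMS 0.03–0.07 sensation units) and is the study default;
thin-plate spline and cubic remain available (and are the right choice
below ~22 training rows, where the quadratic tail is under-determined).
"RMS" is the root-mean-square *error* in response units — the only
reading under which an accuracy bound of 0.2 on a ±4 scale is
meaningful. Validation is a single seeded 10 % holdout; R² is reported
as undefined (NaN) when the holdout response has zero variance.

## Optimization (`optimize`, pipeline stage)

The hybrid "pointer-style" controller chains the four classic method
families with a fixed schedule per supply-angle level: seeded real-coded
GA (population 20, 30 generations, tournament selection, SBX crossover
η=15, polynomial mutation η=20), downhill simplex from the GA best, SQP
polish, and — as a safeguard that makes the hybrid dominate the plain
comparator by construction — a second SQP start from the box centre.
All stages share one evaluation budget and a best-so-far record. The
SQP-only comparator (one SLSQP run per level from the box centre with
numerical gradients) mirrors an NLPQLP-style single-strategy run.

For the neutral-sensation study the objective is |OTSV| from the
surrogate, with the solar factors fixed at the extreme condition
(altitude 1.4 rad, radiation 1300 W/m²). Because the surrogate's
holdout error (~0.03–0.07) is commensurate with the ±0.05 neutrality
band, the pipeline adds a short downhill-simplex **refinement on the
full chain** (default budget 40 chain evaluations) after the surrogate
search, per angle level, and selects the level whose refined optimum
*verifies* closest to neutral through the full chain — surrogate for
global search, direct model for final refinement, the standard division
of labour in surrogate-based optimization. The reported optimum always
carries its full-chain verification (OTSV, MST, all 14 local votes).

## Sensitivity (`sensitivity`)

Spearman correlation is Pearson on mid-ranks (tie-corrected); the
p-value uses the t approximation for n > 8 and exact two-sided
permutation enumeration for n ≤ 8. One-factor sweeps hold the remaining
factors at the reference setting (45°, 15 °C, 600 m³/h, 1100 W/m²,
1 rad); the solar correlation tables use 9-point even grids per factor
at both angle levels and star entries with p ≥ 0.05. Because the
chain is deterministic and monotone in each solar factor, these
correlations are sign/significance diagnostics, not estimates with
sampling error.

## Problem sizes and determinism

The default study — 60 chain evaluations, 16 surrogates, two optimizer
runs with chain refinement, two sweeps and four correlation tables —
completes in a few minutes on one CPU. Every random stage (design,
holdout, GA) takes an explicit seed from `StudyConfig`; identical
configurations produce byte-identical `summary.json` files (wall-clock
timing is kept separately in `run_info.json`).

## Known limitations

- The microclimate is a calibrated emulation, not a flow solution: it
  reproduces the qualitative spatial pattern (cool head/hands, warm
  calves, warmer at 90° supply) and smooth monotone factor responses,
  so passing tests demonstrate the pipeline's correctness on such
  fields, not fidelity to any particular cab.
- The physiology and sensation coefficient sets are authored and
  calibrated to a plausible thermoneutral state, not fitted to subject
  data; absolute vote levels should be read comparatively.
- The deviation-weighted overall vote is used exactly as specified; its
  known instability is avoided by the cold-dominant slope margin, not
  removed.
- Steady-state only: cab entry transients and the dynamic sensation
  terms are modelled but not exercised by the study.
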