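# Methods

## Model

`evacsi` treats the decision to evacuate as an irreversible two-state
("unevacuated" → "evacuated") contagion over a metapopulation: N
communities, each partitioned into three behavioural types. The state is
the 3×N matrix of evacuated counts I_jk(t); unevacuated counts are
*derived* as S_jk = Q_jk − I_jk, so conservation S + I = Q holds by
construction at every instant. Counts are continuous (the ODE is a
continuum model); "people" numbers are rounded only when printed.

The rate of new decisions in group (j, k) is the per-type responsiveness
γ_k times the sum of four influences (see README for the equation):

1. **Within-community contagion.** Each evacuee makes λ0 contacts per
   hour inside the community; contacts with the unevacuated fraction
   S_jk/Q_j convert. The per-person contact count is treated as the mean
   of its (Poisson) distribution — only λ0 enters the model.
2. **Between-community contagion.** Contacts across communities fall off
   with separation as a Gaussian density λ(d) = λ0·α/(√(2π)σ)·exp(−d²/2σ²),
   and a message from community i is weighted by the sender's location
   weight h(d_i0) = a1·d_i0 + b1: evacuees from *distant* (low-risk)
   communities are more persuasive, which is what produces shadow
   evacuation of low-risk areas. h is unbounded in d; a configurable
   ceiling (`h_cap`) exists and is off by default, since the source form
   gives none and realistic extents (≤ ~10 km) keep h modest.
3. **Geographic pressure.** f(d, t) = a2/(d² + b2·t + 10): direct,
   contact-free pressure from living near the risk source, fading with
   time. The printed source form is typographically ambiguous; this
   coupled form is the default because it is monotone non-increasing in
   both arguments as the framework requires, and a separable reading
   (a2/d²)·1/(b2·t + 10) is available as `f_mode="separable"` (undefined
   at d = 0).
4. **Warning forcing.** w(t) is piecewise over warning degrees issued at
   t1 < t2 < …. Default `hyperbolic_reset`: a_i/((t − t_i) + 10) + b_i —
   the decay clock restarts at each issuance, since each stronger order
   injects a fresh effect that then wanes "injection-like".
   `hyperbolic_global` (one global clock) and `linear` (a_i·t + b_i with
   the slope/issuance-value orderings checked by
   `validate_linear_schedule`) are provided because the source material
   presents both shapes without reconciling them. Hyperbolic schedules
   are validated at construction: each degree must start strictly above
   the outgoing degree's value at the issuance time. The offset 10 h in
   the hyperbolic denominators is part of the functional form.

Warning dissemination channels (sirens, door-knocking, …) are not
modelled separately; they are folded into the shape of w(t). The hazard
field is static in time; type assignment (who is "Impressionable") is an
input proportion, not a model output.

## Parameters

| name | meaning | unit | default |
|---|---|---|---|
| γ1, γ2, γ3 | per-type effective transformation rates, γ1>γ2>γ3>0 | h⁻¹ scale | 0.5, 0.3, 0.2 |
| λ0 | within-community contact frequency | contacts·h⁻¹ | 0.25 (one contact per 4 h) |
| α | between-community contact scaling | — | 0.01 |
| σ | contact-kernel width | km | 1 |
| a1, b1 | location weight h(d) = a1·d + b1 | km⁻¹, — | 1, 0.1 |
| a2, b2 | geographic pressure coefficients | —, h⁻¹ | 0.01, 0.01 |
| (a3, b3), (a4, b4) | warning degrees at t = 0 and t = 60 h | — | (0.01, 0.001), (0.2, 0.01) |

These defaults (`params_table1()`) are the case-study values; the
sensitivity-analysis reference set (`params_table3()`) differs in α, a1,
a2, b2, a3, b3 and ships as a second preset.

## Initial conditions

One anchor observation seeds the system (the case: 150 evacuees of type 1
in community 1 before the first order). Every other group scales from it
by three ratios: γ_k/γ_1 (type responsiveness), (d_anchor/d_j)^p
(closer communities start with a larger evacuated fraction; p ∈ {1,2,3},
default 3), and Q_jk/Q_anchor (group size). Results are clamped to
[0, Q_jk]. The distance factor is implemented as *inversely* proportional
to the p-th power of distance; the typeset source formula reads as
directly proportional, which contradicts its own prose and would exceed
community populations at 6 km — the prose reading is used.

## Integration

Forward Euler, I ← clip(I + dt·RHS, 0, Q), dt = 1 h by default (the
source method's hourly iteration). Every warning issuance inside the
horizon must lie on the grid so the jump in w is seen exactly at the
issuance; `integrate` rejects incompatible dt values rather than silently
shifting the jump. Clamping guards overshoot at coarse steps; at dt ≤ 1 h
with the default parameters it never triggers before saturation (verified
in tests by re-running without the clamp). In the reduced
one-community/one-type limit the trajectory converges to the logistic
closed form at first order in dt (max relative error ≈ 1.5×10⁻⁴ at
dt = 0.01 h over 50 h, halving as dt halves).

## Synthetic scenarios

The case geometry is unpublished, so `tianjin_like_scenario(seed)`
emulates its published facts: 61 communities labelled by increasing
source distance over 0.67–6.10 km, five labels pinned to reported
distances (1→0.67, 10→2.06, 27→4.12, 31→4.21, 61→6.10 km), 115,350
residents split equally across the three types and (by default) equally
across communities — the true per-community split is unstated; a seeded
Dirichlet mode exists. Communities sit at polar coordinates around the
source: radii drawn uniformly *between* consecutive pinned distances (so
pinned labels keep their rank exactly), angles seeded uniform. Pairwise
distances are Euclidean. Community 27 is reported to have a single
neighbour; the generator places it (with community 41 beside it) on the
far side of the plane from the 3/4-arc holding the rest. Reported
adjacency lists are treated as qualitative placement guidance only — the
model uses continuous distances, not an adjacency graph.

What the generator does *not* emulate: the real street-map geometry,
heterogeneous community sizes, type proportions varying by community, or
any time-varying hazard. Passing tests on these fixtures therefore
validate the model mechanics and the qualitative case phenomenology
(S-shape, warning kink, type and distance orderings, isolation penalty),
not the case's exact printed numbers, which depend on the unpublished
map. On the synthetic geometry the computed analogues nevertheless land
close to the reported ones (initial demand under 1%, hourly increments
peaking near 0.02 of the population, λ0 sensitivity max ≈ 2.2–2.4).

## Sensitivity analysis

SF is local and single-factor: perturb one parameter by a relative step
(default 10⁻³, forward difference; central available), re-simulate, and
take the Euclidean norm of the five componentwise relative output changes
divided by the relative parameter change. Output instants default to
(24, 48, 72, 96, 120) h — the source never states them; these span the
120-h case horizon evenly. Calibration identities used as tests: a model
with all five outputs proportional to β gives SF = √5 exactly; a
parameter absent from the dynamics gives SF = 0; uniform (1+x) inflation
of the outputs gives norm √5·|x|. Scans evaluate SF on an even grid and
report max and mean; grid values must respect the model's constraints
(e.g. a γ1 grid may not dip below γ2 — scanning γ1 moves γ1 only), and
must be strictly positive for the relative step to be defined. Global
(variance-based) sensitivity is out of scope by design.

## Numerical and design notes

- t = 0 is the first order's issuance; earlier evacuation enters only
  through the anchor-based initial conditions.
- Q_j (community population), not the whole-area Q, divides both social
  terms, following the printed system.
- Zero-population communities contribute nothing (their shares are set to
  0 rather than 0/0).
- Trajectories export to tidy CSV (t, community, type, I, S, fraction)
  and a JSON summary embedding the full config echo; a run is
  reproducible from its summary alone.
- Problem sizes used in the shipped checks: 61 communities × 3 types ×
  120 hourly steps for case runs; dt = 0.01 h over 50 h for the logistic
  oracle; 25-point grids for sensitivity scans. All complete in seconds.

## Known limitations

Deterministic continuum model — no stochastic or agent-based variant, no
explicit social network; everyone eventually evacuates (demand saturates
at Q), so "non-evacuation" can only be represented by slow dynamics; the
linear warning mode's orderings (rising within a piece) sit uneasily with
the decay assumption of the hyperbolic modes and are kept only for
completeness; parameter values are illustrative, not calibrated to
observed departure-time data.
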