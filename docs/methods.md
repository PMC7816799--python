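# Methods

This note documents the model implemented by `whalecost`, the defaults it
ships with and why, the design choices made where the design was genuinely
open, and what the synthetic-data generator does and does not emulate.

## Behavioral states and the activity model

An hour is **not feeding (NF)** exactly when its lunge count is zero; feeding
hours are split into **shallow (SF)** and **deep feeding (DF)** by the
posterior component of the hour's mean lunge depth under a two-component
Gaussian mixture fitted by EM (scikit-learn, tolerance 1e-6, at most 500
iterations, components sorted by mean, seed fixed in configuration). Hard
maximum-posterior assignment is used; with the shipped reference components
(33 ± 20 m shallow, 157 ± 75 m deep) the decision boundary falls near 70 m.
A feeding hour with a missing depth is classified, by default, by a
lunge-rate-weighted prior (Poisson likelihood of the hour's lunge count under
each state's typical rate, weighted by the mixture weights) and flagged in
the log; a strict mode raises instead.

Hourly states form a first-order Markov chain. The transition matrix is the
maximum-likelihood row-normalized count matrix, with sequences broken at any
missing hour so no transition is counted across a recording gap; a state with
no observed departures leaves its row undefined and raises an error naming
the state. The stationary distribution solves πP = π, π·1 = 1 by linear
least squares and is the daily activity budget. Spatial (latitude-band) and
temporal (month) subsets re-fit the chain, areas and gaps on the subset while
sharing the pooled depth mixture and the pooled state-typical lunge rates,
since lunge rates do not vary across subsets in the source data.

**Bout gaps** are maximal runs of NF hours strictly between feeding hours
within a contiguous recording stretch; non-foraging time at the start or end
of a deployment is excluded. These gaps proxy the time needed to find a new
krill patch after a disturbance response — a deliberately generous
(precautionary) proxy.

**Daily ranging areas** are Minimum Convex Polygon (convex hull) areas of a
complete feeding day's 24 hourly fixes. Fixes are projected with an
equirectangular projection about the midpoint of the day's latitude span
(x = R·cos φ₀·Δλ, y = R·Δφ, R = 6371 km); at daily ranging scales of tens of
km the projection error is far below the sampling noise of 24 fixes, and the
midpoint (unlike the mean) makes the area invariant to duplicated or interior
fixes. Days qualify if they have 24 hourly records in the local calendar day
(time-zone offset configurable, default UTC), at least one lunge, and a
non-degenerate hull; day-specific lunge rates are the day's mean lunges/h per
feeding state, falling back to the dataset-wide medians when a day lacks a
state.

## Exposure geometry

Received level follows spherical spreading only, RL = SL − 20·log₁₀(r), with
the source level defined at 1 m (ranges clamp there). No absorption or
bathymetry-dependent term is included; the footprint of a real source in a
real sound-speed field would differ.

A day's movement is idealized as a circle of the day's MCP area. Its center
is placed uniformly at random over the 100 km × 100 km study square; circles
may extend beyond the square edge and overlaps are computed in the unbounded
plane, because the square is a modeling unit rather than a physical barrier
and clipping would bias exposure downward for near-edge placements. The
source sits at the center, a corner, or the middle of one side (or any
explicit coordinate).

Distance bands around the source are induced by the doses of interest: for
discrete ER functions, the ranges at which each anchor RL is reached, always
including a 1 km edge so every band is unambiguously "near" (≤ 1 km) or
"far"; for the continuous received-level curve, 10-dB level bins; for the
continuous range curve, 1-km bins to 5 km and an open-ended band beyond. The
fraction of the daily circle in each band is the exact two-circle lens
overlap difference of consecutive discs, divided by the daily-circle area;
these fractions (plus an unexposed remainder) are a partition of unity and
are validated against Monte-Carlo point sampling in the test suite.

## Exposure-response functions

ER functions enter as configuration, not as fits. Three exposure contexts
are ordered by decreasing sensitivity: deep feeding near the source (≤ 1 km);
deep feeding far, or any other state near; other states far. Discrete step
functions anchor response probabilities (1, 10, 50, 90, 99)% at increasing
RLs: the 1% anchor at the ambient noise level in the 3–4 kHz band (sea state
3), the 99% anchor at the TTS-onset level for low-frequency cetaceans, the
90% anchor 10 dB below TTS onset, and context/variant-specific 10% and 50%
anchors. Four variants are shipped (median / upper CI for moderate / high
response severity). Below the ambient floor no response is simulated. A bin
of RLs responds with the probability at its **upper** extreme — an explicit
precautionary convention that inflates predicted effects.

The shipped anchor values and the continuous curves' per-bin posterior means
and SDs are **reconstructed placeholders**: the published values live in
supplementary material not transcribed here. The fixture files say so
prominently, every structural property (monotonicity in dose, context
ordering, floor and ceiling behavior) is enforced by validation and tested
anchor-agnostically, and the files are plain YAML intended to be replaced by
the published tables. Quantities that depend on the anchor placement — most
visibly the fraction of simulations with no change in net intake and the
fraction of sign flips — should be expected to shift when real anchors are
substituted.

Continuous curves are evaluated by drawing one response probability per dose
bin per simulated day from Normal(mean, sd) truncated to [0, 1] (inverse-CDF
sampling; a zero SD returns the mean). A per-interval redraw is available as
an option; the per-day draw is the default because the curve uncertainty is
epistemic within a day, not interval-to-interval noise.

## Bioenergetics

Per-lunge assimilated energy is E = V(L)·ρ·e_k·ε. Defaults (all overridable
in `config/bioenergetics.yaml`, each value provenance-tagged there as a
reconstructed placeholder):

| parameter | default | units | rationale |
|---|---|---|---|
| V(L) | 1.03·10⁻³·L³·⁵⁶ | m³ | engulfment allometry with exponent > 3; V(22 m) ≈ 62 m³ |
| e_k | 4.2 | MJ/kg | krill wet-mass energy density, California Current order |
| ε | 0.84 | – | assimilation efficiency for baleen whales |
| c_NF, c_SF, c_DF | 106, 410, 515 | MJ/h at 22 m | activity-specific cost rates, scaled by (L/22)²·²⁵ |
| gestation | 430 | MJ/d | mid-pregnancy daily cost |
| lactation | 4700 | MJ/d | maximum daily milk delivery |

The placeholder constants were calibrated once, jointly, so that the model's
undisturbed daily quantities fall in the published ranges (mean intake near
27.7 GJ/d, mean expenditure near 6.6 GJ/d with the pooled budget inside the
2.6–10.6 GJ/d daily range, gestation ≈ 7% and lactation ≈ 77% mean increases
in expenditure); they are not a mechanistic parameterization and should be
replaced when the published equations are transcribed.

Krill density is lognormal with geometric mean/SD (0.513, 1.917) kg/m³ for
the lower ("randomly foraging") and (0.757, 1.468) kg/m³ for the upper
("efficiency-maximizing") pooled distribution. Per-lunge draws are
independent — no within-day patch autocorrelation — the simplest reading of
drawing a density per lunge.

Net intake applies a foraging floor: maintenance is the all-day NF cost
(24·c_NF, plus any reproduction cost), foraging cost is the increment of
feeding hours over the NF rate, and net = max(gross − foraging cost, 0) −
maintenance. The floor applies to total foraging, not per state. Lost
feeding time is re-costed at the NF rate when computing disturbed
expenditure.

## The simulated day

1. Sample a qualifying deployment day uniformly; place its circle; compute
   band occupancy.
2. Partition the day into 1440/Δ intervals (Δ = 6 min for discrete ER,
   matching the response opportunity scale the step functions assume; Δ =
   30 min for continuous ER, the typical experimental-exposure duration
   behind those curves). Each interval independently receives an exposure
   band (by band occupancy) and a behavioral state (by the sampled day's own
   24-hour budget).
3. The source is active for its duration starting at a uniform time in
   [0, 1440 − duration] minutes (no wrap across midnight); an interval is
   active when its midpoint falls in the window, which preserves the expected
   exposed time for sources shorter than the grid step.
4. Sequentially, each active, exposed, not-already-lost interval responds
   with the ER probability for its band and context; a response marks the
   interval plus ⌈gap·60/Δ⌉ following intervals as lost, where the gap is
   drawn from the empirical bout-gap distribution and truncated at the day's
   end (no carry-over to the next day; this is a daily model). No interval
   is lost twice and no response occurs inside an ongoing lost period.
   Intervals in the NF state can respond (context "other") — their lost time
   contributes no lunges but still runs the patch-finding clock; this is the
   conservative choice for an ambiguous case.
5. Lost lunges are lost feeding hours × the day's state-specific rates,
   exactly. Gross intake and losses draw from one shared sequence of
   per-lunge krill densities per state, so lost ≤ gross holds structurally,
   the proportional energy loss lies in [0, 1] (0/0 defined as 0), and a
   replicate with no response reproduces the undisturbed budget bit-exactly.
   Undisturbed gross intake is computed from the same resampled grid (grid
   feeding hours × day rates), not from the day's raw lunge total, so
   disturbed and undisturbed quantities are common-random-number paired.

The factorial runner crosses source level × duration × position × body
length × krill distribution × ER function, giving every scenario an
independent child random stream spawned from the master seed, so results are
bit-reproducible and scenarios are order-independent. Summaries report
per-scenario means, 2.5/25/50/75/97.5% quantiles, and the fractions of
replicates with unchanged net intake, decreased net intake, and a
positive-to-negative sign flip.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, so
every stage is testable without field data:

* **States**: default is a semi-Markov construction — NF bout durations
  drawn from a lognormal with mean 10 h and SD 20 h, rounded and truncated
  to [1, 226] h (the observed gap range); feeding bouts of geometric length
  balanced against the *exact* mean of the rounded, truncated gap law so the
  long-run occupancy equals the target budget (61% NF, 10% SF, 29% DF);
  SF/DF dynamics within a bout follow a two-state chain started from its
  stationary distribution. A pure first-order Markov mode (`gap_model=
  "markov"`) is provided for transition-matrix recovery benchmarks, since a
  Markov chain's geometric dwell times cannot reproduce heavy-tailed gaps.
  The default transition matrix is built by detailed balance around the
  target budget, making its stationary distribution exact by construction.
* **Lunge counts**: negative binomial per feeding state (mean 19, SD 8
  lunges/h deep; mean 15, SD 10 shallow), clamped to ≥ 1 so feeding hours
  always contain a lunge.
* **Depths**: normals (33 ± 20 m shallow, 157 ± 75 m deep) truncated at 1 m.
  Truncation and component overlap mean the pipeline's fitted mixture means
  sit a few meters above the generating centers (≈35 and ≈164 m) — an
  inherent property of EM on overlapping components, not an estimator bug.
* **Movement**: an Ornstein–Uhlenbeck-style hourly walk (pull 0.05 toward
  the deployment anchor) whose per-day step scale is lognormal (median
  2.9 km, log-SD 0.5), calibrated once by simulation so daily hull areas
  average ≈294 km² and span the observed ~12–1650 km² range.
* **Deployments**: gamma-distributed lengths (mean 8 days, capped at 32),
  random start hours, anchors spread over 31–39°N in May–November, with an
  optional per-month transition-matrix override for subset benchmarks.

What the generator does **not** emulate: real tracks' habitat structure and
shelf-following movement; any correlation between daily area and activity
budget (feeding-heavy days covering smaller areas); depth-dependent krill
structure; individual heterogeneity beyond the month override. Passing tests
therefore demonstrate that the estimators and the simulation machinery are
correct and calibrated under the assumed statistical structure — not that
predictions transfer to any particular real population.

Two known censoring effects are worth naming. Gaps extracted from generated
deployments average below the 10 h sampler mean because runs touching a
deployment edge are excluded, and occupancy of the not-feeding state runs
~1–2 percentage points below target at the 8-day deployment scale because
in-progress long gaps are cut at deployment end. Both effects are present in
any real dataset processed the same way.

## Numerical choices

* Two-circle lens overlap is computed in closed form; an infinite radius
  means the whole plane. Degenerate radii are rejected at construction.
* Stationary distributions come from a least-squares solve of πP = π with
  the normalization row appended; validated against power iteration.
* Truncated-normal probability draws use inverse-CDF sampling via the normal
  CDF/quantile, exact to floating point and fast enough for per-day draws.
* Tolerances: row-stochasticity 1e-12; stationarity 1e-10; bin partition
  1e-9; EM tolerance 1e-6 with 500 iterations and 3 restarts.
* Degenerate inputs raise informative errors: identical depths (zero-variance
  mixture), < 3 distinct or collinear daily fixes (day excluded, logged),
  empty subsets, unvisited Markov states, activity models without days or
  gaps.

## Problem sizes used in checks

The shipped acceptance checks run at desk scale on one CPU: 10⁶-draw krill
and geometry Monte-Carlo oracles, ~10⁵ synthetic hours for budget recovery
(~2×10⁵ for transition-matrix recovery), 100 paired replicates per level for
the source-level and duration monotonicity sweeps, and 60 replicates per
scenario for the 105-scenario reference sweep in `scripts/acceptance.py`
(the published study used 1000 replicates per scenario; the runner accepts
any replicate count and scales linearly, ~1 ms per simulated day).
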